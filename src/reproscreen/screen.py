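"""Screen core: QC filtering, GFP+ ratios, Z-scores and hit classification.

The screen's readout per well is the fraction of worms carrying at least one
GFP-positive embryo. Per chemical and concentration the pipeline averages
technical replicates within each biological repeat, then averages the repeat
means (unweighted) into x. Within each concentration group it standardises
across chemicals, z = (x - mu) / sigma, and labels a chemical *high* when
any non-missing z exceeds the threshold (default 1) and *low* when all
non-missing z fall below it.

Missing cells carry one of two markers: ``NT`` (not tested at that
concentration) or ``NDA`` (tested, but no well survived QC).

The module-level functions are the primitive operations;
:class:`ZScoreScreen` is the model object tying them together.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import DegenerateGroupError, InvalidRecordError
from .simulate import WELL_COLUMNS

NT = "NT"
NDA = "NDA"


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def validate_wells(wells: pd.DataFrame) -> None:
    """Check structural invariants of a well table; raise on violation."""
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise InvalidRecordError(f"well table missing columns {missing}")
    bad = wells[wells["n_total"] <= 0]
    if len(bad):
        raise InvalidRecordError(
            f"n_total = 0 in well {_well_name(bad.iloc[0])}")
    bad = wells[(wells["n_dead"] < 0) | (wells["n_dead"] > wells["n_total"])]
    if len(bad):
        raise InvalidRecordError(
            f"n_dead outside [0, n_total] in well {_well_name(bad.iloc[0])}")
    bad = wells[(wells["n_gfp_pos"] < 0) | (wells["n_gfp_pos"] > wells["n_total"])]
    if len(bad):
        raise InvalidRecordError(
            f"n_gfp_pos outside [0, n_total] in well {_well_name(bad.iloc[0])}")


def qc_filter(
    wells: pd.DataFrame, dead_threshold: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude wells with > ``dead_threshold`` dead worms or ectopic expression.

    Returns ``(kept, exclusion_log)``; the log holds one row per excluded
    well with a ``reason`` of ``"dead_fraction"`` or ``"ectopic"``
    (dead-fraction takes precedence when both apply).
    """
    if wells.empty:
        raise InvalidRecordError("well table is empty")
    validate_wells(wells)
    dead_frac = wells["n_dead"] / wells["n_total"]
    dead_excl = dead_frac > dead_threshold
    ectopic_excl = wells["ectopic"].astype(bool) & ~dead_excl
    excluded = dead_excl | ectopic_excl

    log = wells.loc[excluded].copy()
    log["dead_fraction"] = dead_frac[excluded]
    log["reason"] = np.where(dead_excl[excluded], "dead_fraction", "ectopic")
    return wells.loc[~excluded].copy(), log.reset_index(drop=True)


def well_ratio(well: Mapping | pd.Series) -> float:
    """GFP+ worm ratio of one well: n_gfp_pos / n_total."""
    n_total, n_gfp = int(well["n_total"]), int(well["n_gfp_pos"])
    if n_total <= 0:
        raise InvalidRecordError(f"n_total = 0 in well {_well_name(well)}")
    if not 0 <= n_gfp <= n_total:
        raise InvalidRecordError(
            f"n_gfp_pos outside [0, n_total] in well {_well_name(well)}")
    return n_gfp / n_total


def summarize(wells: pd.DataFrame) -> pd.DataFrame:
    """Average QC-kept wells into per-(chemical, concentration) ratios.

    Technical replicates are averaged within each biological repeat first,
    then the repeat means are averaged unweighted. Returns columns
    ``chemical_id, concentration_um, x, n_repeats_used``. Pairs without any
    surviving well are simply absent (they become NDA downstream).
    """
    if wells.empty:
        return pd.DataFrame(
            columns=["chemical_id", "concentration_um", "x", "n_repeats_used"])
    wells = wells.copy()
    wells["ratio"] = wells["n_gfp_pos"] / wells["n_total"]
    rep_means = (
        wells.groupby(["chemical_id", "concentration_um", "bio_repeat"],
                      sort=True)["ratio"].mean())
    out = (
        rep_means.groupby(level=["chemical_id", "concentration_um"])
        .agg(x="mean", n_repeats_used="size").reset_index())
    out["n_repeats_used"] = out["n_repeats_used"].astype(int)
    return out


@dataclass
class ZScoreMatrix:
    """Chemical x concentration Z-scores with NT/NDA missing markers.

    ``z`` is a float DataFrame (chemicals as index, concentration labels as
    columns, NaN where missing); ``status`` holds "OK"/"NT"/"NDA" per cell;
    ``mu``/``sigma`` are the per-concentration mean and standard deviation of
    x over chemicals used for standardisation (NaN columns when the matrix
    was built directly from published z values).
    """

    z: pd.DataFrame
    status: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    ddof: int = 1

    @property
    def chemicals(self) -> list:
        return list(self.z.index)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ZScoreMatrix":
        """Build from a table of pre-computed z values.

        ``table`` is indexed by chemical with one column per concentration;
        cells hold numbers or the strings "NT"/"NDA".
        """
        status = table.map(
            lambda v: v if isinstance(v, str) and v in (NT, NDA) else "OK")
        z = table.map(
            lambda v: np.nan if isinstance(v, str) and v in (NT, NDA) else float(v))
        nan_cols = pd.Series(np.nan, index=table.columns)
        return cls(z=z, status=status, mu=nan_cols.copy(), sigma=nan_cols.copy())

    def to_frame(self) -> pd.DataFrame:
        """Mixed-type export with NT/NDA strings in missing cells."""
        out = self.z.astype(object)
        mask = self.status != "OK"
        out[mask] = self.status[mask]
        return out


def zscores(
    summaries: pd.DataFrame,
    tested: Optional[Iterable[tuple[str, float]]] = None,
    ddof: int = 1,
) -> ZScoreMatrix:
    """Standardise x within each concentration group across chemicals.

    ``tested`` optionally lists every (chemical, concentration) pair that
    was physically tested (pre-QC); pairs tested but absent from
    ``summaries`` become NDA, untested pairs NT. Without it, all absent
    pairs are NT.

    ``ddof`` selects the standard-deviation convention: 1 (sample, default)
    or 0 (population).
    """
    x = summaries.pivot(index="chemical_id", columns="concentration_um", values="x")
    if tested is not None:
        tested = set(tested)
        chems = sorted({c for c, _ in tested} | set(x.index))
        concs = sorted({k for _, k in tested} | set(x.columns))
        x = x.reindex(index=chems, columns=concs)

    counts = x.notna().sum(axis=0)
    thin = counts[counts < 3]
    if len(thin):
        raise DegenerateGroupError(
            f"concentration group(s) {list(thin.index)} have < 3 chemicals with data")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=ddof)
    # treat numerically-zero spread (identical x up to rounding) as degenerate
    degenerate = sigma[sigma < 1e-12 * (mu.abs() + 1.0)]
    if len(degenerate):
        raise DegenerateGroupError(
            f"zero standard deviation in concentration group(s) "
            f"{list(degenerate.index)}")
    z = (x - mu) / sigma

    status = pd.DataFrame("OK", index=x.index, columns=x.columns)
    if tested is None:
        status[x.isna()] = NT
    else:
        for chem in x.index:
            for conc in x.columns:
                if pd.isna(x.at[chem, conc]):
                    status.at[chem, conc] = NDA if (chem, conc) in tested else NT
    return ZScoreMatrix(z=z, status=status, mu=mu, sigma=sigma, ddof=ddof)


def classify(zmatrix: ZScoreMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Label each chemical high / low / unclassified by the Z threshold rule.

    high: any non-missing z strictly above ``threshold``;
    low: all non-missing z strictly below; a maximum exactly equal to the
    threshold (or no data at all) leaves the chemical unclassified.
    """
    z = zmatrix.z
    rows = []
    for chem, zrow in z.iterrows():
        vals = zrow.dropna()
        n_above = int((vals > threshold).sum())
        if vals.empty:
            warnings.warn(f"chemical {chem!r} has no non-missing z; unclassified",
                          stacklevel=2)
            rows.append((chem, "unclassified", np.nan, 0))
            continue
        max_z = float(vals.max())
        if n_above > 0:
            label = "high"
        elif max_z < threshold:
            label = "low"
        else:
            label = "unclassified"
        rows.append((chem, label, max_z, n_above))
    return pd.DataFrame(
        rows, columns=["chemical_id", "label", "max_z", "n_concs_above_threshold"])


def count_above(
    zmatrix: ZScoreMatrix, threshold: float = 1.0, min_concentrations: int = 1
) -> int:
    """Chemicals with z > ``threshold`` at >= ``min_concentrations`` groups."""
    above = (zmatrix.z > threshold).sum(axis=1)
    return int((above >= min_concentrations).sum())


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ZScoreScreen:
    """Aneuploidy-screen model: wells in, Z-score ranking and labels out.

    Parameters
    ----------
    wells
        Well-level table with columns ``chemical_id, concentration_um,
        bio_repeat, tech_replicate, plate_id, well_position, n_total,
        n_dead, n_gfp_pos, ectopic``.
    dead_threshold
        QC cut on the dead-worm fraction (wells above it are excluded).
    z_threshold
        Classification threshold on z.
    sigma_convention
        "sample" (n-1 denominator, default) or "population".
    excluded_chemicals
        Chemicals removed before Z-scoring (e.g. assay-interfering
        fluorescence observed at the bench).
    """

    def __init__(
        self,
        wells: pd.DataFrame,
        dead_threshold: float = 0.10,
        z_threshold: float = 1.0,
        sigma_convention: str = "sample",
        excluded_chemicals: Iterable[str] = (),
    ):
        validate_wells(wells)
        self.wells = wells
        self.dead_threshold = dead_threshold
        self.z_threshold = z_threshold
        if sigma_convention not in {"sample", "population"}:
            raise ValueError(f"unknown sigma convention {sigma_convention!r}")
        self.ddof = 1 if sigma_convention == "sample" else 0
        self.excluded_chemicals = set(excluded_chemicals)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ZScoreScreen":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "ZScoreScreenResults":
        wells = self.wells
        if self.excluded_chemicals:
            wells = wells[~wells["chemical_id"].isin(self.excluded_chemicals)]
        kept, exclusions = qc_filter(wells, self.dead_threshold)
        summaries = summarize(kept)
        tested = set(zip(wells["chemical_id"], wells["concentration_um"]))
        zmatrix = zscores(summaries, tested=tested, ddof=self.ddof)
        classification = classify(zmatrix, self.z_threshold)
        return ZScoreScreenResults(
            model=self, kept_wells=kept, exclusions=exclusions,
            summaries=summaries, zmatrix=zmatrix, classification=classification)


@dataclass
class ZScoreScreenResults:
    """Fitted screen: QC log, per-group summaries, Z matrix and labels."""

    model: ZScoreScreen
    kept_wells: pd.DataFrame
    exclusions: pd.DataFrame
    summaries: pd.DataFrame
    zmatrix: ZScoreMatrix
    classification: pd.DataFrame
    extra: dict = field(default_factory=dict)

    @property
    def n_high(self) -> int:
        return int((self.classification["label"] == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.classification["label"] == "low").sum())

    def label_of(self, chemical: str) -> str:
        sel = self.classification.loc[
            self.classification["chemical_id"] == chemical, "label"]
        if sel.empty:
            raise KeyError(chemical)
        return sel.iloc[0]

    def count_above(self, threshold: Optional[float] = None,
                    min_concentrations: int = 1) -> int:
        thr = self.model.z_threshold if threshold is None else threshold
        return count_above(self.zmatrix, thr, min_concentrations)

    def summary(self) -> str:
        lines = [
            "Aneuploidy screen Z-score classification",
            "=" * 44,
            f"wells in: {len(self.model.wells):>6d}   "
            f"kept: {len(self.kept_wells)}   excluded: {len(self.exclusions)}",
            f"chemicals: {len(self.zmatrix.chemicals)}   "
            f"threshold: z > {self.model.z_threshold:g}   "
            f"sigma ddof: {self.zmatrix.ddof}",
            f"high: {self.n_high}   low: {self.n_low}   "
            f"unclassified: {len(self.classification) - self.n_high - self.n_low}",
            "",
            "top chemicals by max z:",
        ]
        top = self.classification.sort_values("max_z", ascending=False).head(10)
        for _, row in top.iterrows():
            lines.append(f"  {row['chemical_id']:<42s} max_z={row['max_z']:8.3f} "
                         f"[{row['label']}]")
        return "\n".join(lines)

    def to_csvs(self, outdir: str | Path) -> dict[str, Path]:
        """Write summary, Z-matrix (NT/NDA markers), classification and QC log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "summaries": outdir / "chem_conc_summary.csv",
            "zmatrix": outdir / "zscore_matrix.csv",
            "classification": outdir / "classification.csv",
            "exclusions": outdir / "exclusion_log.csv",
        }
        self.summaries.to_csv(paths["summaries"], index=False)
        self.zmatrix.to_frame().to_csv(paths["zmatrix"], index_label="chemical_id")
        self.classification.to_csv(paths["classification"], index=False)
        self.exclusions.to_csv(paths["exclusions"], index=False)
        return paths

    def plot_zscores(self, ax=None):
        """Strip plot of z by concentration with the threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        z = self.zmatrix.z
        for i, conc in enumerate(z.columns):
            vals = z[conc].dropna()
            ax.scatter(np.full(len(vals), i), vals, s=12, alpha=0.7)
        ax.axhline(self.model.z_threshold, color="red", lw=1,
                   label=f"z = {self.model.z_threshold:g}")
        ax.set_xticks(range(len(z.columns)),
                      [f"{c:g} uM" if not isinstance(c, str) else str(c)
                       for c in z.columns])
        ax.set_ylabel("Z-score")
        ax.legend()
        return ax


def _well_name(well: Mapping | pd.Series) -> str:
    return (f"{well.get('chemical_id', '?')}/"
            f"{well.get('plate_id', '?')}:{well.get('well_position', '?')}")
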