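"""ToxCast-style bioactivity summaries and target-family enrichment.

Per chemical the bioactivity ratio is active hit calls / total assays
tested; AC50 potencies are carried on the log10(uM) scale with a fixed
imputation constant of 3.0 (= 1 mM) for active assays lacking an AC50.
High- vs low-Z-score groups are compared on bioactivity (Welch t) and on
the distribution of intended target families among active hit calls
(per-family Fisher exact tests with Benjamini-Hochberg adjustment, plus an
overall chi-square test of independence). The non-descriptive
"channel 1"/"channel 2" pseudo-families count toward bioactivity but are
excluded from the family analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InvalidRecordError

CHANNEL_FAMILIES = ("channel 1", "channel 2")
#: log10(uM) value assigned to active assays without an AC50.
LOG10_AC50_IMPUTED = 3.0

__all__ = [
    "bioactivity_ratio", "bioactivity_table", "log10_ac50",
    "compare_group_bioactivity", "family_counts", "fisher_exact_p",
    "family_enrichment", "benjamini_hochberg", "FamilyEnrichment",
    "EnrichmentResults", "CHANNEL_FAMILIES", "LOG10_AC50_IMPUTED",
]


def bioactivity_ratio(records: pd.DataFrame) -> dict:
    """Bioactivity summary of one chemical's assay records.

    Returns ``{chemical_id, n_active, n_total, bioactivity_ratio,
    log10_ac50_values}``; a chemical with zero assay rows gets NaN markers
    (mirrors chemicals absent from the in vitro dashboard).
    """
    chems = records["chemical_id"].unique() if len(records) else []
    if len(chems) > 1:
        raise InvalidRecordError(f"records span several chemicals: {list(chems)}")
    if len(records) == 0:
        return {"chemical_id": None, "n_active": np.nan, "n_total": 0,
                "bioactivity_ratio": np.nan, "log10_ac50_values": []}
    n_total = len(records)
    n_active = int(records["hit_call"].astype(bool).sum())
    return {
        "chemical_id": chems[0],
        "n_active": n_active,
        "n_total": n_total,
        "bioactivity_ratio": n_active / n_total,
        "log10_ac50_values": log10_ac50(records),
    }


def bioactivity_table(
    records: pd.DataFrame, chemicals: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Per-chemical bioactivity ratios (full precision + 3-decimal display).

    ``chemicals`` optionally forces rows (with missing-data markers) for
    chemicals absent from ``records``.
    """
    agg = (records.assign(active=records["hit_call"].astype(bool))
           .groupby("chemical_id")
           .agg(n_active=("active", "sum"), n_total=("active", "size")))
    if chemicals is not None:
        agg = agg.reindex(list(chemicals))
    out = agg.reset_index()
    out["bioactivity_ratio"] = out["n_active"] / out["n_total"]
    out["ratio_display"] = out["bioactivity_ratio"].round(3)
    return out


def log10_ac50(records: pd.DataFrame, impute: float = LOG10_AC50_IMPUTED) -> list[float]:
    """log10 AC50 (uM) of each *active* assay; missing AC50 -> ``impute``."""
    active = records[records["hit_call"].astype(bool)]
    ac50 = active["ac50_um"].to_numpy(dtype=float)
    if np.any(ac50[~np.isnan(ac50)] <= 0):
        raise InvalidRecordError("non-positive AC50 in assay records")
    vals = np.where(np.isnan(ac50), impute, np.log10(np.where(np.isnan(ac50), 1.0, ac50)))
    return [float(v) for v in vals]


def compare_group_bioactivity(
    ratios_high: Sequence[float], ratios_low: Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample two-tailed t test on per-chemical bioactivity ratios.

    Returns ``(mean_high, mean_low, p)``.
    """
    a = np.asarray(ratios_high, dtype=float)
    b = np.asarray(ratios_low, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each group needs >= 2 bioactivity values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(res.pvalue)


def family_counts(
    records: pd.DataFrame,
    groups: Mapping[str, str],
    exclude: Sequence[str] = CHANNEL_FAMILIES,
) -> pd.DataFrame:
    """Active-hit counts per (intended target family, chemical group).

    ``groups`` maps every chemical in ``records`` to a group label
    (e.g. "top"/"bottom"). Channel pseudo-families are dropped, so a
    chemical active only in channel categories contributes nothing.
    Returns a family x group count table.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=sorted(set(groups.values())))
    present = set(records["chemical_id"].unique())
    unassigned = present - set(groups)
    if unassigned:
        raise ConfigurationError(
            f"chemicals without group assignment: {sorted(unassigned)[:3]}")
    active = records[records["hit_call"].astype(bool)].copy()
    active = active[active["intended_target_family"].notna()]
    active = active[~active["intended_target_family"].isin(exclude)]
    if active.empty:
        return pd.DataFrame(columns=sorted(set(groups.values())))
    active["group"] = active["chemical_id"].map(groups)
    counts = (active.groupby(["intended_target_family", "group"])
              .size().unstack(fill_value=0))
    counts.index.name = "family"
    return counts


def fisher_exact_p(table: np.ndarray, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for one 2x2 count table."""
    return float(stats.fisher_exact(np.asarray(table), alternative=alternative)[1])


def family_enrichment(
    counts: pd.DataFrame,
    top_group: str = "top",
    bottom_group: str = "bottom",
    construction: str = "rest",
    alternative: str = "greater",
    m: Optional[int] = None,
) -> "EnrichmentResults":
    """Per-family Fisher tests of top- vs bottom-group representation.

    Parameters
    ----------
    counts
        Family x group table of active-hit counts (channels already
        excluded), e.g. from :func:`family_counts`.
    construction
        How the per-family 2x2 table is built: ``"rest"`` (default) tests
        the family's counts against the remaining non-family active counts
        of each group; ``"margin"`` tests them against the groups' total
        active counts.
    alternative
        ``"greater"`` (default) tests over-representation in the top group;
        ``"two-sided"`` and ``"less"`` are available.
    m
        Number of tests for the Benjamini-Hochberg adjustment (defaults to
        the number of families).

    A family with zero total counts gets p = 1 by convention and is flagged
    in the ``degenerate`` column.
    """
    if counts.shape[0] < 2:
        raise ConfigurationError("family enrichment needs >= 2 families")
    for g in (top_group, bottom_group):
        if g not in counts.columns:
            raise ConfigurationError(f"group {g!r} missing from count table")
    top = counts[top_group].to_numpy(dtype=int)
    bottom = counts[bottom_group].to_numpy(dtype=int)
    top_total, bottom_total = int(top.sum()), int(bottom.sum())
    if top_total == 0 or bottom_total == 0:
        raise ConfigurationError("both group totals must be positive")

    pvals, degenerate = [], []
    for t, b in zip(top, bottom):
        if t + b == 0:
            pvals.append(1.0)
            degenerate.append(True)
            continue
        degenerate.append(False)
        if construction == "rest":
            table = [[t, top_total - t], [b, bottom_total - b]]
        elif construction == "margin":
            table = [[t, top_total], [b, bottom_total]]
        else:
            raise ConfigurationError(f"unknown construction {construction!r}")
        pvals.append(fisher_exact_p(table, alternative=alternative))

    m_eff = m if m is not None else len(pvals)
    adj = benjamini_hochberg(pvals, m=m_eff)
    enrich = pd.DataFrame({
        "family": list(counts.index),
        "count_bottom": bottom,
        "count_top": top,
        "fisher_p": pvals,
        "fdr_adjusted_p": adj,
        "degenerate": degenerate,
    })
    # overall association: chi-square of independence on families x groups
    table2 = np.column_stack([bottom, top])
    keep = table2.sum(axis=1) > 0
    chi2, chi2_p, chi2_df, _ = stats.chi2_contingency(table2[keep], correction=False)
    return EnrichmentResults(
        enrichment=enrich, chi2=float(chi2), chi2_p=float(chi2_p),
        chi2_df=int(chi2_df),
        meta={"construction": construction, "alternative": alternative,
              "fdr_method": "benjamini-hochberg", "m": m_eff,
              "top_total": top_total, "bottom_total": bottom_total})


def benjamini_hochberg(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the number of tests in the adjustment (defaults to
    ``len(p_values)``; a larger m supports testing a subset of a known
    family). Adjusted values are capped at 1 and monotone non-decreasing in
    the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise InvalidRecordError("p-values must lie in [0, 1]")
    m_eff = int(m) if m is not None else p.size
    if m_eff < p.size:
        raise ConfigurationError("m must be >= the number of p-values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_eff / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class FamilyEnrichment:
    """Model comparing two chemical groups' in vitro assay profiles.

    Parameters
    ----------
    records
        (chemical, assay) table with columns ``chemical_id, assay_id,
        hit_call, ac50_um, intended_target_family``.
    groups
        Mapping (or two-column DataFrame ``chemical_id, group``) assigning
        each chemical to ``top_group`` or ``bottom_group``.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        groups: Mapping[str, str] | pd.DataFrame,
        top_group: str = "top",
        bottom_group: str = "bottom",
        construction: str = "rest",
        alternative: str = "greater",
        m: Optional[int] = None,
    ):
        if isinstance(groups, pd.DataFrame):
            groups = dict(zip(groups["chemical_id"], groups["group"]))
        self.records = records
        self.groups = dict(groups)
        self.top_group = top_group
        self.bottom_group = bottom_group
        self.construction = construction
        self.alternative = alternative
        self.m = m

    @classmethod
    def from_csv(cls, assays_path: str | Path, groups_path: str | Path,
                 **kwargs) -> "FamilyEnrichment":
        return cls(pd.read_csv(assays_path), pd.read_csv(groups_path), **kwargs)

    def fit(self) -> "EnrichmentResults":
        bio = bioactivity_table(self.records, chemicals=self.groups.keys())
        bio["group"] = bio["chemical_id"].map(self.groups)
        counts = family_counts(self.records, self.groups)
        results = family_enrichment(
            counts, top_group=self.top_group, bottom_group=self.bottom_group,
            construction=self.construction, alternative=self.alternative,
            m=self.m)
        results.bioactivity = bio
        ok = bio.dropna(subset=["bioactivity_ratio"])
        high = ok.loc[ok["group"] == self.top_group, "bioactivity_ratio"]
        low = ok.loc[ok["group"] == self.bottom_group, "bioactivity_ratio"]
        if len(high) >= 2 and len(low) >= 2:
            results.group_comparison = compare_group_bioactivity(high, low)
        results.model = self
        return results


@dataclass
class EnrichmentResults:
    """Family-level enrichment table plus bioactivity group comparison."""

    enrichment: pd.DataFrame
    chi2: float
    chi2_p: float
    chi2_df: int
    meta: dict
    bioactivity: Optional[pd.DataFrame] = None
    #: (mean_top, mean_bottom, welch_p) when both groups had >= 2 ratios
    group_comparison: Optional[tuple[float, float, float]] = None
    model: Optional[FamilyEnrichment] = None
    extra: dict = field(default_factory=dict)

    def family_row(self, family: str) -> pd.Series:
        sel = self.enrichment.loc[self.enrichment["family"] == family]
        if sel.empty:
            raise KeyError(family)
        return sel.iloc[0]

    @property
    def n_significant_raw(self) -> int:
        return int((self.enrichment["fisher_p"] < 0.05).sum())

    @property
    def n_significant_adjusted(self) -> int:
        return int((self.enrichment["fdr_adjusted_p"] < 0.05).sum())

    def summary(self) -> str:
        lines = [
            "Intended-target-family enrichment (top vs bottom chemicals)",
            "=" * 60,
            f"families: {len(self.enrichment)}   construction: "
            f"{self.meta['construction']}   alternative: {self.meta['alternative']}",
            f"active counts: top = {self.meta['top_total']}, "
            f"bottom = {self.meta['bottom_total']}",
            f"overall chi-square({self.chi2_df}) = {self.chi2:.1f}, "
            f"p = {self.chi2_p:.3g}",
        ]
        if self.group_comparison is not None:
            mh, ml, p = self.group_comparison
            lines.append(f"bioactivity ratio means: top = {mh:.3f}, "
                         f"bottom = {ml:.3f} (Welch p = {p:.3g})")
        lines += ["", "families at unadjusted p < 0.05:"]
        sig = self.enrichment.sort_values("fisher_p")
        for _, row in sig[sig["fisher_p"] < 0.05].iterrows():
            lines.append(
                f"  {row['family']:<28s} bottom = {row['count_bottom']:>4d} "
                f"top = {row['count_top']:>4d}  p = {row['fisher_p']:.6f}  "
                f"p_adj = {row['fdr_adjusted_p']:.6f}")
        return "\n".join(lines)

    def to_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"enrichment": outdir / "family_enrichment.csv"}
        enrich = self.enrichment.copy()
        for key, val in self.meta.items():
            enrich.attrs[key] = val
        enrich.to_csv(paths["enrichment"], index=False)
        if self.bioactivity is not None:
            paths["bioactivity"] = outdir / "bioactivity.csv"
            self.bioactivity.to_csv(paths["bioactivity"], index=False)
        return paths
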