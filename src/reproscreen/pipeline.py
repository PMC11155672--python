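"""End-to-end orchestration: simulate/load -> screen -> lethality -> enrichment.

:func:`run_pipeline` wires the stage models together under a single
:class:`~reproscreen.config.RunConfig`, writes every stage output to the
configured directory and returns a :class:`RunReport` with stage counts and
provenance. :func:`reproduce_reference` re-derives the bundled reference
results (classification split, bioactivity ratios, family enrichment) from
the packaged tables.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import RunConfig
from .datasets import (
    load_reference_bioactivity,
    load_reference_family_counts,
    load_reference_zscore_matrix,
)
from .lethality import LethalityAnova, LethalityResults
from .screen import ZScoreScreen, ZScoreScreenResults, classify, count_above
from .simulate import (
    generate_assay_table,
    generate_lethality_dataset,
    generate_screen_dataset,
    write_provenance,
)
from .toxcast import EnrichmentResults, FamilyEnrichment, family_enrichment


@dataclass
class RunReport:
    """Stage-level accounting and provenance of one pipeline run."""

    n_wells_in: int
    n_wells_kept: int
    n_wells_excluded: int
    n_chemicals: int
    n_high: int
    n_low: int
    n_unclassified: int
    provenance: dict
    screen: ZScoreScreenResults
    lethality: Optional[LethalityResults] = None
    enrichment: Optional[EnrichmentResults] = None
    outputs: dict[str, Path] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "stages": {
                "wells_in": self.n_wells_in,
                "wells_kept": self.n_wells_kept,
                "wells_excluded": self.n_wells_excluded,
            },
            "classification": {
                "chemicals": self.n_chemicals,
                "high": self.n_high,
                "low": self.n_low,
                "unclassified": self.n_unclassified,
            },
            "lethality": (
                {"significant": self.lethality.significant_chemicals}
                if self.lethality else None),
            "enrichment": (
                {"n_families": int(len(self.enrichment.enrichment)),
                 "significant_raw": self.enrichment.n_significant_raw,
                 "significant_adjusted": self.enrichment.n_significant_adjusted,
                 **self.enrichment.meta}
                if self.enrichment else None),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Simulated inputs are generated from ``config.sim`` (seed-deterministic);
    otherwise tables are read from the configured CSV paths. Lethality and
    enrichment stages run only when their inputs exist.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    wells, plates, assays = _load_inputs(config, outdir)

    screen_model = ZScoreScreen(
        wells,
        dead_threshold=config.dead_threshold,
        z_threshold=config.z_threshold,
        sigma_convention=config.sigma_convention,
        excluded_chemicals=config.excluded_chemicals,
    )
    screen = screen_model.fit()
    outputs = screen.to_csvs(outdir)

    lethality = None
    if plates is not None:
        lethality = LethalityAnova(
            plates, control=config.control_label,
            method=config.comparison_method).fit()
        outputs["lethality"] = lethality.to_csv(outdir / "lethality.csv")

    enrichment = None
    if assays is not None:
        labels = dict(zip(screen.classification["chemical_id"],
                          screen.classification["label"]))
        groups = {c: ("top" if lbl == "high" else "bottom")
                  for c, lbl in labels.items() if lbl in ("high", "low")}
        present = set(assays["chemical_id"].unique())
        groups = {c: g for c, g in groups.items() if c in present}
        assays = assays[assays["chemical_id"].isin(groups)]
        if len(set(groups.values())) == 2:
            enrichment = FamilyEnrichment(
                assays, groups,
                construction=config.fisher_construction,
                alternative=config.fisher_alternative,
                m=config.fdr_m).fit()
            outputs.update(enrichment.to_csvs(outdir))

    counts = screen.classification["label"].value_counts()
    report = RunReport(
        n_wells_in=len(wells),
        n_wells_kept=len(screen.kept_wells),
        n_wells_excluded=len(screen.exclusions),
        n_chemicals=len(screen.classification),
        n_high=int(counts.get("high", 0)),
        n_low=int(counts.get("low", 0)),
        n_unclassified=int(counts.get("unclassified", 0)),
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "reproscreen_version": __version__,
        },
        screen=screen,
        lethality=lethality,
        enrichment=enrichment,
        outputs=outputs,
    )
    (outdir / "report.json").write_text(report.to_json())
    report.outputs["report"] = outdir / "report.json"
    return report


def reproduce_reference(outdir: Optional[str | Path] = None) -> dict:
    """Re-derive the reference results from the bundled tables.

    Returns a dict with the classification split, the counts of chemicals
    above threshold at >= 2 and >= 3 concentrations, the recomputed
    bioactivity ratios, and the family-enrichment results; optionally
    writes the mirrored tables to ``outdir``.
    """
    zmat = load_reference_zscore_matrix()
    classification = classify(zmat, threshold=1.0)
    labels = classification["label"].value_counts()

    bio = load_reference_bioactivity().copy()
    bio["bioactivity_ratio"] = bio["n_active"] / bio["n_total"]
    bio["ratio_display"] = bio["bioactivity_ratio"].round(3)

    fam = load_reference_family_counts()
    counts = fam[["count_bottom", "count_top"]].rename(
        columns={"count_bottom": "bottom", "count_top": "top"})
    enrichment = family_enrichment(counts, m=42)

    result = {
        "classification": classification,
        "n_high": int(labels.get("high", 0)),
        "n_low": int(labels.get("low", 0)),
        "n_above_2_concs": count_above(zmat, 1.0, 2),
        "n_above_3_concs": count_above(zmat, 1.0, 3),
        "bioactivity": bio,
        "enrichment": enrichment,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        zmat.to_frame().to_csv(outdir / "zscore_matrix.csv",
                               index_label="chemical_id")
        classification.to_csv(outdir / "classification.csv", index=False)
        bio.to_csv(outdir / "bioactivity.csv", index=False)
        enrichment.to_csvs(outdir)
        (outdir / "reference_summary.json").write_text(json.dumps({
            "n_high": result["n_high"], "n_low": result["n_low"],
            "n_above_2_concs": result["n_above_2_concs"],
            "n_above_3_concs": result["n_above_3_concs"],
            "enrichment_significant_raw": enrichment.n_significant_raw,
            "enrichment_significant_adjusted": enrichment.n_significant_adjusted,
        }, indent=2, sort_keys=True))
    return result


def export_tables(report: RunReport, outdir: str | Path) -> dict[str, Path]:
    """Re-emit every stage table of a finished run (idempotent)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = report.screen.to_csvs(outdir)
    if report.lethality is not None:
        paths["lethality"] = report.lethality.to_csv(outdir / "lethality.csv")
    if report.enrichment is not None:
        paths.update(report.enrichment.to_csvs(outdir))
    else:
        # keep the documented file set stable even without enrichment input
        empty = pd.DataFrame(columns=[
            "family", "count_bottom", "count_top", "fisher_p",
            "fdr_adjusted_p", "degenerate"])
        path = outdir / "family_enrichment.csv"
        empty.to_csv(path, index=False)
        paths["enrichment"] = path
    path = outdir / "report.json"
    path.write_text(report.to_json())
    paths["report"] = path
    return paths


def _load_inputs(config: RunConfig, outdir: Path):
    if config.sim is not None:
        sim = config.sim.model_copy(update={"seed": config.seed})
        wells = generate_screen_dataset(sim)
        plates = (generate_lethality_dataset(sim)
                  if sim.lethality_truth is not None else None)
        assays = generate_assay_table(sim)
        write_provenance(outdir, sim)
        wells.to_csv(outdir / "wells.csv", index=False)
        if plates is not None:
            plates.to_csv(outdir / "plates.csv", index=False)
        assays.to_csv(outdir / "assays.csv", index=False)
        return wells, plates, assays
    wells = pd.read_csv(config.wells_csv)
    plates = pd.read_csv(config.plates_csv) if config.plates_csv else None
    assays = pd.read_csv(config.assays_csv) if config.assays_csv else None
    return wells, plates, assays
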