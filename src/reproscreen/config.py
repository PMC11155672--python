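"""Configuration models for the simulator and the end-to-end pipeline.

Both configurations are pydantic models so that invalid values raise
:class:`~reproscreen.exceptions.ConfigurationError` naming the offending
field, and so that configs round-trip to/from YAML or JSON files.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Optional

import pydantic
import yaml
from pydantic import BaseModel, model_validator

from .exceptions import ConfigurationError

#: Intended-target-family labels used by the default assay-table simulator.
#: The two "channel" entries are the non-descriptive fluorescence-readout
#: pseudo-families that bioactivity keeps but family enrichment excludes.
DEFAULT_FAMILIES: tuple[str, ...] = (
    "Steroid hormone", "Cell cycle", "Gpcr", "Kinase", "Deiodinase",
    "Apoptosis", "Dehalogenase", "Cardiomyocyte function", "Mitochondria",
    "Esterase", "Hydrolase", "Neuroactivity", "Transporter", "Oxidoreductase",
    "growth factor receptor", "Cytokine receptor", "Cyp", "Nuclear receptor",
    "Protease inhibitor", "Ligase", "Filaments", "Mutagenicity response",
    "DNA binding", "Misc protein", "Oxidase", "Transcription factor",
    "Transferase", "Ion channel", "Growth factor", "Catalase", "Lyase",
    "MicroRNA", "Apolipoprotein", "Metabolite", "Phosphatase",
    "Cell morphology", "Cytokine", "Membrane protein", "Protease",
    "Cell adhesion molecules", "Malformation", "Neurodevelopment",
    "channel 1", "channel 2",
)


class _Base(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)

    def __init__(self, **data: Any):
        try:
            super().__init__(**data)
        except pydantic.ValidationError as err:
            raise ConfigurationError(str(err)) from err

    @classmethod
    def _validated(cls, **kwargs: Any):
        return cls(**kwargs)


class SimConfig(_Base):
    """Parameters of the synthetic screen / lethality / assay generators.

    The defaults emulate the structure of the screen the pipeline was built
    for: 133 chemicals at up to four concentrations (10, 30, 50, 100 uM),
    4 biological repeats in experimental duplicate, ~100 worms per well, and
    a baseline GFP+ worm rate below 0.2% (the natural male frequency).
    """

    n_chemicals: int = 133
    concentrations: list[float] = [10.0, 30.0, 50.0, 100.0]
    n_bio_repeats: int = 4
    n_tech_replicates: int = 2
    worms_per_well: int = 100
    baseline_gfp_rate: float = 0.002
    #: chemical -> per-concentration GFP+ worm probability, aligned with
    #: ``concentrations``. Arbitrary vectors; supports non-monotonic shapes.
    #: When None, every generated chemical sits at the baseline rate.
    effect_profiles: Optional[dict[str, list[float]]] = None
    #: Beta(alpha, beta) parameters of the per-well dead-worm fraction.
    #: alpha = 0 disables deaths entirely.
    dead_rate_alpha: float = 1.5
    dead_rate_beta: float = 30.0
    #: Additive dead-rate shift for edge wells (edge-effect emulation; 0 = off).
    edge_dead_shift: float = 0.0
    ectopic_rate: float = 0.02
    #: chemical (or control label) -> embryonic-lethality probability.
    lethality_truth: Optional[dict[str, float]] = None
    control_label: str = "DMSO"
    control_lethality: float = 0.02
    n_experiments: int = 3
    plates_per_experiment: int = 3
    mean_embryos: float = 100.0
    #: assay-table generator
    families: list[str] = list(DEFAULT_FAMILIES)
    #: optional sampling weights over ``families`` (normalised internally).
    family_weights: Optional[list[float]] = None
    n_assays_range: tuple[int, int] = (300, 1200)
    #: chemical -> per-assay hit probability; unlisted chemicals draw from
    #: Beta(2, 6) (mean 0.25, the order of magnitude of observed ratios).
    bioactivity_truth: Optional[dict[str, float]] = None
    p_missing_ac50: float = 0.10
    log10_ac50_mean: float = 1.0
    log10_ac50_sd: float = 1.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        def bad(field: str, msg: str):
            raise ConfigurationError(f"{field}: {msg}")

        if self.n_chemicals < 1:
            bad("n_chemicals", "must be >= 1")
        if not self.concentrations:
            bad("concentrations", "must be non-empty")
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            bad("concentrations", "must be strictly increasing")
        for field in ("n_bio_repeats", "n_tech_replicates", "worms_per_well",
                      "n_experiments", "plates_per_experiment"):
            if getattr(self, field) < 1:
                bad(field, "must be >= 1")
        for field in ("baseline_gfp_rate", "ectopic_rate", "control_lethality",
                      "p_missing_ac50"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                bad(field, f"probability {v} outside [0, 1]")
        if self.dead_rate_alpha < 0 or self.dead_rate_beta <= 0:
            bad("dead_rate_alpha/dead_rate_beta",
                "need alpha >= 0 and beta > 0")
        if self.mean_embryos <= 0:
            bad("mean_embryos", "must be > 0")
        if self.effect_profiles is not None:
            k = len(self.concentrations)
            for chem, probs in self.effect_profiles.items():
                if len(probs) != k:
                    bad("effect_profiles",
                        f"{chem!r}: expected {k} per-concentration values, got {len(probs)}")
                if any(not 0.0 <= p <= 1.0 for p in probs):
                    bad("effect_profiles", f"{chem!r}: probabilities outside [0, 1]")
        if self.lethality_truth is not None:
            for chem, p in self.lethality_truth.items():
                if not 0.0 <= p <= 1.0:
                    bad("lethality_truth", f"{chem!r}: probability {p} outside [0, 1]")
        if not self.families:
            bad("families", "must be non-empty")
        if self.family_weights is not None:
            if len(self.family_weights) != len(self.families):
                bad("family_weights", "length must match families")
            if any(w < 0 for w in self.family_weights) or sum(self.family_weights) <= 0:
                bad("family_weights", "must be non-negative with positive sum")
        lo, hi = self.n_assays_range
        if lo < 1 or hi < lo:
            bad("n_assays_range", "need 1 <= lo <= hi")
        if self.bioactivity_truth is not None:
            for chem, p in self.bioactivity_truth.items():
                if not 0.0 <= p <= 1.0:
                    bad("bioactivity_truth", f"{chem!r}: probability {p} outside [0, 1]")
        return self

    def chemical_ids(self) -> list[str]:
        """Chemical labels: effect-profile keys if given, else chem-001.. ."""
        if self.effect_profiles:
            return list(self.effect_profiles)
        return [f"chem-{i + 1:03d}" for i in range(self.n_chemicals)]

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        return cls._validated(**_load_mapping(path))


class RunConfig(_Base):
    """End-to-end pipeline configuration (file inputs or a simulation)."""

    wells_csv: Optional[Path] = None
    plates_csv: Optional[Path] = None
    assays_csv: Optional[Path] = None
    sim: Optional[SimConfig] = None
    z_threshold: float = 1.0
    dead_threshold: float = 0.10
    #: standard-deviation convention for Z-scores: "sample" (n-1) or "population"
    sigma_convention: Literal["sample", "population"] = "sample"
    #: chemicals removed before Z-scoring (assay-interference exclusions)
    excluded_chemicals: list[str] = []
    control_label: str = "DMSO"
    comparison_method: Literal["sidak", "dunnett"] = "sidak"
    fisher_construction: Literal["rest", "margin"] = "rest"
    fisher_alternative: Literal["greater", "two-sided", "less"] = "greater"
    fdr_m: Optional[int] = None
    outdir: Path = Path("reproscreen-out")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not 0.0 <= self.dead_threshold <= 1.0:
            raise ConfigurationError(
                f"dead_threshold: {self.dead_threshold} outside [0, 1]")
        if self.wells_csv is None and self.sim is None:
            raise ConfigurationError("wells_csv/sim: need an input table or a simulation")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls._validated(**_load_mapping(path))

    def config_hash(self) -> str:
        """Stable digest of the configuration, for provenance records."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_mapping(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data
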