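"""Seeded synthetic data with the statistical structure the analysis assumes.

Three generators emulate the three tables the pipeline consumes:

* :func:`generate_screen_dataset` - well-level aneuploidy-reporter counts.
  Each well holds ``worms_per_well`` worms; a worm is scored GFP+ when it
  carries at least one GFP-positive (male, i.e. X-segregation-error) embryo,
  so the well-level observation is Binomial(survivors, p) where p is the
  chemical's per-concentration effect probability. Dead-worm fractions are
  Beta-distributed with an upper tail that exercises the >10% QC cut, and
  wells are laid out on two alternating 96-well plate layouts so edge
  positions differ between repeats.
* :func:`generate_lethality_dataset` - per-plate embryos laid / larvae
  hatched, 3 experiments x 3 plates per chemical, ~100 embryos per plate.
* :func:`generate_assay_table` - a ToxCast-style (chemical, assay) table
  with hit calls, optionally-missing AC50 values and intended target
  families including the "channel 1"/"channel 2" pseudo-families.

A single integer seed in :class:`~reproscreen.config.SimConfig` fully
determines all three tables.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .exceptions import ConfigurationError

WELL_COLUMNS = [
    "chemical_id", "concentration_um", "bio_repeat", "tech_replicate",
    "plate_id", "well_position", "n_total", "n_dead", "n_gfp_pos", "ectopic",
]
PLATE_COLUMNS = ["chemical_id", "experiment", "plate", "n_embryos", "n_hatched"]
ASSAY_COLUMNS = ["chemical_id", "assay_id", "hit_call", "ac50_um",
                 "intended_target_family"]

_ROWS = "ABCDEFGH"
_NCOLS = 12


class PlateLayout:
    """One of two 96-well layouts assigning chemicals to plate positions.

    Layout "A" fills the plate row-major from A1; layout "B" fills it in the
    reversed order, so a chemical sitting on an edge in one layout sits in
    the interior (or the opposite edge) in the other. Chemicals beyond 96
    spill onto additional plates.
    """

    def __init__(self, layout_id: str):
        if layout_id not in {"A", "B"}:
            raise ConfigurationError(f"layout_id: unknown layout {layout_id!r}")
        self.layout_id = layout_id

    def position(self, index: int) -> tuple[str, str]:
        """(plate suffix, well label) for the chemical at ``index``."""
        plate, slot = divmod(index, len(_ROWS) * _NCOLS)
        if self.layout_id == "B":
            slot = len(_ROWS) * _NCOLS - 1 - slot
        row, col = divmod(slot, _NCOLS)
        return f"P{plate + 1}", f"{_ROWS[row]}{col + 1}"

    @staticmethod
    def is_edge(well: str) -> bool:
        row, col = well[0], int(well[1:])
        return row in {_ROWS[0], _ROWS[-1]} or col in {1, _NCOLS}


def generate_screen_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate the well-level screen table (one row per well).

    One record per (chemical, concentration, biological repeat, technical
    replicate). Odd-numbered biological repeats use plate layout "A", even
    ones layout "B".
    """
    rng = np.random.default_rng(config.seed)
    chemicals = config.chemical_ids()
    profiles = _effect_matrix(config, chemicals)

    n_chem = len(chemicals)
    n_conc = len(config.concentrations)
    n_rep = config.n_bio_repeats
    n_tech = config.n_tech_replicates
    n = n_chem * n_conc * n_rep * n_tech

    chem_idx = np.repeat(np.arange(n_chem), n_conc * n_rep * n_tech)
    conc_idx = np.tile(np.repeat(np.arange(n_conc), n_rep * n_tech), n_chem)
    rep_idx = np.tile(np.repeat(np.arange(n_rep), n_tech), n_chem * n_conc)
    tech_idx = np.tile(np.arange(n_tech), n_chem * n_conc * n_rep)

    layouts = {"A": PlateLayout("A"), "B": PlateLayout("B")}
    positions = {
        lid: [lay.position(i) for i in range(n_chem)] for lid, lay in layouts.items()
    }
    layout_for_rep = ["A" if r % 2 == 0 else "B" for r in range(n_rep)]

    plate_ids, wells, edge = [], [], np.empty(n, dtype=bool)
    for i in range(n):
        lid = layout_for_rep[rep_idx[i]]
        psuf, well = positions[lid][chem_idx[i]]
        plate_ids.append(
            f"R{rep_idx[i] + 1}T{tech_idx[i] + 1}"
            f"C{config.concentrations[conc_idx[i]]:g}L{lid}{psuf}")
        wells.append(well)
        edge[i] = PlateLayout.is_edge(well)

    n_total = np.full(n, config.worms_per_well, dtype=int)
    if config.dead_rate_alpha > 0:
        dead_frac = rng.beta(config.dead_rate_alpha, config.dead_rate_beta, size=n)
    else:
        dead_frac = np.zeros(n)
    dead_frac = np.clip(dead_frac + config.edge_dead_shift * edge, 0.0, 1.0)
    n_dead = rng.binomial(n_total, dead_frac)

    p_effect = profiles[chem_idx, conc_idx]
    n_gfp = rng.binomial(n_total - n_dead, p_effect)
    ectopic = rng.random(n) < config.ectopic_rate

    return pd.DataFrame({
        "chemical_id": np.asarray(chemicals, dtype=object)[chem_idx],
        "concentration_um": np.asarray(config.concentrations)[conc_idx],
        "bio_repeat": rep_idx + 1,
        "tech_replicate": tech_idx + 1,
        "plate_id": plate_ids,
        "well_position": wells,
        "n_total": n_total,
        "n_dead": n_dead,
        "n_gfp_pos": n_gfp,
        "ectopic": ectopic,
    })[WELL_COLUMNS]


def generate_lethality_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate the per-plate embryonic-lethality table.

    Per chemical (and the vehicle control): ``n_experiments`` x
    ``plates_per_experiment`` plates, embryos ~ Poisson(mean_embryos)
    (floored at 1), hatched ~ Binomial(embryos, 1 - lethality).
    """
    if config.lethality_truth is None:
        raise ConfigurationError("lethality_truth: required for lethality simulation")
    rng = np.random.default_rng(_substream(config.seed, 1))

    truth = dict(config.lethality_truth)
    truth.setdefault(config.control_label, config.control_lethality)

    rows = []
    for chem, lethality in truth.items():
        for exp in range(1, config.n_experiments + 1):
            for plate in range(1, config.plates_per_experiment + 1):
                embryos = max(1, int(rng.poisson(config.mean_embryos)))
                hatched = int(rng.binomial(embryos, 1.0 - lethality))
                rows.append((chem, exp, plate, embryos, hatched))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def generate_assay_table(config: SimConfig) -> pd.DataFrame:
    """Simulate the ToxCast-style (chemical, assay) table.

    Each chemical is "tested" in a few hundred assays; hit calls are
    Bernoulli with the chemical's bioactivity-truth rate; active rows carry
    a log-normal AC50 except for a ``p_missing_ac50`` fraction left missing;
    every row carries an intended target family drawn from ``families``
    (which includes the channel pseudo-families by default).
    """
    rng = np.random.default_rng(_substream(config.seed, 2))
    chemicals = config.chemical_ids()
    weights = config.family_weights
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()

    frames = []
    for chem in chemicals:
        n_assays = int(rng.integers(config.n_assays_range[0],
                                    config.n_assays_range[1] + 1))
        if config.bioactivity_truth and chem in config.bioactivity_truth:
            hit_rate = config.bioactivity_truth[chem]
        else:
            hit_rate = rng.beta(2.0, 6.0)
        hit = rng.random(n_assays) < hit_rate
        ac50 = np.full(n_assays, np.nan)
        active = np.flatnonzero(hit)
        has_ac50 = active[rng.random(active.size) >= config.p_missing_ac50]
        ac50[has_ac50] = 10.0 ** rng.normal(
            config.log10_ac50_mean, config.log10_ac50_sd, size=has_ac50.size)
        family = rng.choice(np.asarray(config.families, dtype=object),
                            size=n_assays, p=weights)
        frames.append(pd.DataFrame({
            "chemical_id": chem,
            "assay_id": [f"assay-{i + 1:04d}" for i in range(n_assays)],
            "hit_call": hit,
            "ac50_um": ac50,
            "intended_target_family": family,
        }))
    return pd.concat(frames, ignore_index=True)[ASSAY_COLUMNS]


def write_provenance(outdir: str | Path, config: SimConfig) -> Path:
    """Record the generating configuration (including the seed) as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(
        {"generator": "reproscreen.simulate", "seed": config.seed,
         "config": config.model_dump(mode="json")}, indent=2, sort_keys=True))
    return path


def make_effect_profiles(
    n_chemicals: int,
    concentrations: list[float],
    *,
    n_active: int = 13,
    baseline: float = 0.002,
    max_rate: float = 0.05,
    n_non_monotonic: int = 2,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Convenience builder for a realistic mixed effect-profile map.

    ``n_active`` chemicals get elevated GFP+ probabilities (up to
    ``max_rate``, i.e. tens of baseline standard deviations), the first
    ``n_non_monotonic`` of which peak at a mid concentration; everything
    else sits at baseline.
    """
    rng = np.random.default_rng(seed)
    k = len(concentrations)
    profiles: dict[str, list[float]] = {}
    for i in range(n_chemicals):
        chem = f"chem-{i + 1:03d}"
        if i < n_non_monotonic and k >= 2:
            peak = rng.uniform(5 * baseline, max_rate)
            shape = np.full(k, baseline)
            shape[k // 2] = peak
            profiles[chem] = shape.tolist()
        elif i < n_active:
            top = rng.uniform(5 * baseline, max_rate)
            profiles[chem] = np.linspace(baseline, top, k).tolist()
        else:
            profiles[chem] = [baseline] * k
    return profiles


def _effect_matrix(config: SimConfig, chemicals: list[str]) -> np.ndarray:
    k = len(config.concentrations)
    if config.effect_profiles is None:
        return np.full((len(chemicals), k), config.baseline_gfp_rate)
    missing = [c for c in chemicals if c not in config.effect_profiles]
    if missing:
        raise ConfigurationError(f"effect_profiles: missing chemicals {missing[:3]}")
    return np.asarray([config.effect_profiles[c] for c in chemicals], dtype=float)


def _substream(seed: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
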