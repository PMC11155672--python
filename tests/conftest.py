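import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from reproscreen import SimConfig, generate_screen_dataset


def make_wells(rows):
    """Build a well table from (chem, conc, repeat, replicate, total, dead,
    gfp, ectopic) tuples."""
    return pd.DataFrame(
        [
            {
                "chemical_id": chem, "concentration_um": conc,
                "bio_repeat": rep, "tech_replicate": tech,
                "plate_id": f"R{rep}T{tech}", "well_position": "B2",
                "n_total": total, "n_dead": dead, "n_gfp_pos": gfp,
                "ectopic": ectopic,
            }
            for chem, conc, rep, tech, total, dead, gfp, ectopic in rows
        ]
    )


@pytest.fixture
def five_chem_wells():
    """Hand-computable 5-chemical, 2-concentration, 2x2-replicate dataset."""
    rows = []
    counts = {
        "A": {10: [(2, 4), (0, 2)], 30: [(10, 12), (8, 10)]},
        "B": {10: [(0, 0), (0, 0)], 30: [(1, 1), (0, 0)]},
        "C": {10: [(1, 1), (1, 1)], 30: [(2, 2), (2, 2)]},
        "D": {10: [(0, 2), (2, 0)], 30: [(3, 1), (1, 3)]},
        "E": {10: [(5, 5), (5, 5)], 30: [(0, 1), (1, 0)]},
    }
    for chem, by_conc in counts.items():
        for conc, reps in by_conc.items():
            for rep, pair in enumerate(reps, start=1):
                for tech, gfp in enumerate(pair, start=1):
                    rows.append((chem, conc, rep, tech, 100, 0, gfp, False))
    return make_wells(rows)


@pytest.fixture
def null_sim_config():
    return SimConfig(n_chemicals=20, n_bio_repeats=4, seed=7)


@pytest.fixture
def small_screen(null_sim_config):
    return generate_screen_dataset(null_sim_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240508)
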