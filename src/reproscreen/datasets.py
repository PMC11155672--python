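"""Bundled reference dataset: the 25-chemical screen summary tables.

The package ships the published summary tables of the screen it
re-implements, as plain CSV: the chemical x concentration Z-score matrix
(13 high- plus 12 low-Z-score chemicals, with NT/NDA missing markers), the
per-chemical ToxCast bioactivity counts, and the intended-target-family
active-hit counts for the two groups. They serve as fixed inputs for
reproducing the reference results without any network access.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .screen import ZScoreMatrix

_CONC_COLUMNS = {"z_10uM": 10.0, "z_30uM": 30.0, "z_50uM": 50.0, "z_100uM": 100.0}


def _read(name: str) -> pd.DataFrame:
    with resources.files("reproscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_zscore_table() -> pd.DataFrame:
    """Raw reference Z-score table (chemical, cas, z at 10/30/50/100 uM)."""
    return _read("reference_zscores.csv")


def load_reference_zscore_matrix() -> ZScoreMatrix:
    """Reference Z-scores as a :class:`~reproscreen.screen.ZScoreMatrix`."""
    raw = load_reference_zscore_table().set_index("chemical")
    table = raw[list(_CONC_COLUMNS)].rename(columns=_CONC_COLUMNS)
    return ZScoreMatrix.from_table(table)


def load_reference_bioactivity() -> pd.DataFrame:
    """Reference bioactivity counts (chemical, group, n_active, n_total,
    reported_ratio)."""
    return _read("reference_bioactivity.csv")


def load_reference_family_counts() -> pd.DataFrame:
    """Reference family x group active-hit counts, indexed by family, with
    the reported Fisher and FDR-adjusted p-values as extra columns."""
    return _read("reference_family_counts.csv").set_index("family")
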