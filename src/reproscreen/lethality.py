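"""Embryonic-lethality statistics: Welch / Brown-Forsythe ANOVA and
control-wise multiple comparisons.

The analysis unit is the plate: lethality = 1 - hatched / embryos. Exposed
groups are compared to the vehicle control with heteroscedasticity-robust
tests, since lethal chemicals inflate the variance of their group:

* Welch's ANOVA (heteroscedastic F with Satterthwaite denominator df),
* the Brown-Forsythe ANOVA F* (classic between-group numerator over a
  variance-weighted denominator),
* per-chemical Welch t tests against the control with a Šidák family-wise
  adjustment over the k comparisons (a classic pooled-variance Dunnett test
  is available as ``method="dunnett"``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InvalidRecordError

__all__ = [
    "plate_lethality", "add_lethality", "welch_anova", "brown_forsythe_anova",
    "dunnett_vs_control", "LethalityAnova", "LethalityResults",
    "WelchAnovaResult",
]


def plate_lethality(plate: Mapping | pd.Series) -> float:
    """Embryonic lethality of one plate: 1 - n_hatched / n_embryos."""
    embryos, hatched = int(plate["n_embryos"]), int(plate["n_hatched"])
    if embryos <= 0:
        raise InvalidRecordError("n_embryos = 0 on plate "
                                 f"{plate.get('chemical_id', '?')}")
    if not 0 <= hatched <= embryos:
        raise InvalidRecordError(
            f"n_hatched outside [0, n_embryos] on plate "
            f"{plate.get('chemical_id', '?')}")
    return 1.0 - hatched / embryos


def add_lethality(plates: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the plate table with a ``lethality`` column."""
    if (plates["n_embryos"] <= 0).any():
        bad = plates.loc[plates["n_embryos"] <= 0].iloc[0]
        raise InvalidRecordError(f"n_embryos = 0 on plate {bad['chemical_id']}")
    if ((plates["n_hatched"] < 0) | (plates["n_hatched"] > plates["n_embryos"])).any():
        bad = plates.loc[plates["n_hatched"] > plates["n_embryos"]].iloc[0]
        raise InvalidRecordError(
            f"n_hatched outside [0, n_embryos] on plate {bad['chemical_id']}")
    out = plates.copy()
    out["lethality"] = 1.0 - out["n_hatched"] / out["n_embryos"]
    return out


@dataclass
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    bf_F: float
    bf_df1: float
    bf_df2: float
    bf_p: float
    method: str = "welch"


def welch_anova(groups: list[np.ndarray]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA plus the Brown-Forsythe F*.

    Each group needs >= 2 observations. A zero-variance group makes the
    weights undefined; in that case the function falls back to the ordinary
    one-way ANOVA with a warning (``method="oneway_fallback"``); if every
    observation is identical the design is degenerate and an error is raised.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigurationError("welch_anova needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ConfigurationError("every group needs >= 2 observations")
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    k = len(groups)

    if np.any(var == 0.0):
        if np.all(var == 0.0) and np.all(means == means[0]):
            raise ConfigurationError(
                "all groups are identical constants; ANOVA undefined")
        warnings.warn("zero-variance group: falling back to ordinary one-way "
                      "ANOVA", stacklevel=2)
        F, p = stats.f_oneway(*groups)
        df1, df2 = k - 1.0, n.sum() - k
        bf = brown_forsythe_anova(groups)
        return WelchAnovaResult(float(F), df1, df2, float(p), *bf,
                                method="oneway_fallback")

    w = n / var
    W = w.sum()
    mean_w = (w * means).sum() / W
    num = (w * (means - mean_w) ** 2).sum() / (k - 1)
    tmp = ((1 - w / W) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k ** 2 - 1) * tmp
    F = num / den
    df1 = k - 1.0
    df2 = (k ** 2 - 1) / (3 * tmp)
    p = float(stats.f.sf(F, df1, df2))
    bf = brown_forsythe_anova(groups)
    return WelchAnovaResult(float(F), df1, df2, p, *bf)


def brown_forsythe_anova(
    groups: list[np.ndarray],
) -> tuple[float, float, float, float]:
    """Brown-Forsythe ANOVA F* with Satterthwaite denominator df.

    F* = sum n_i (mean_i - grand)^2 / sum (1 - n_i/N) s_i^2. For balanced
    designs it equals the ordinary one-way F statistic.
    Returns ``(F*, df1, df2, p)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    n = np.array([len(g) for g in groups], dtype=float)
    N = n.sum()
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    var = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    num = (n * (means - grand) ** 2).sum()
    den_terms = (1 - n / N) * var
    den = den_terms.sum()
    if den == 0.0:
        return np.nan, k - 1.0, np.nan, np.nan
    c = den_terms / den
    df2 = 1.0 / (c ** 2 / (n - 1)).sum()
    F = num / den
    p = float(stats.f.sf(F, k - 1, df2))
    return float(F), k - 1.0, float(df2), p


def dunnett_vs_control(
    groups: Mapping[str, np.ndarray],
    control_label: str,
    method: str = "sidak",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chemical comparison against the control, family-wise adjusted.

    ``method="sidak"`` (default): Welch two-sample t per chemical vs
    control, two-tailed, with Šidák adjustment over the k comparisons
    (equivalently the studentized-maximum-modulus adjustment under
    independence). ``method="dunnett"``: scipy's classic pooled-variance
    Dunnett test.

    Returns one row per chemical: group mean, control mean, t, df, raw and
    adjusted p, and a significance flag at ``alpha`` (two-tailed).
    """
    if control_label not in groups:
        raise ConfigurationError(f"control group {control_label!r} missing")
    control = np.asarray(groups[control_label], dtype=float)
    chems = [c for c in groups if c != control_label]
    if not chems:
        raise ConfigurationError("no comparison groups besides the control")
    if len(control) < 2 or any(len(np.asarray(groups[c])) < 2 for c in chems):
        raise ConfigurationError("every group needs >= 2 observations")
    k = len(chems)

    rows = []
    if method == "sidak":
        for chem in chems:
            g = np.asarray(groups[chem], dtype=float)
            res = stats.ttest_ind(g, control, equal_var=False)
            p_raw = float(res.pvalue)
            p_adj = float(min(1.0, 1.0 - (1.0 - p_raw) ** k))
            rows.append((chem, g.mean(), control.mean(), float(res.statistic),
                         float(res.df), p_raw, p_adj))
    elif method == "dunnett":
        res = stats.dunnett(*(np.asarray(groups[c], dtype=float) for c in chems),
                            control=control)
        for i, chem in enumerate(chems):
            g = np.asarray(groups[chem], dtype=float)
            rows.append((chem, g.mean(), control.mean(),
                         float(res.statistic[i]), np.nan, np.nan,
                         float(res.pvalue[i])))
    else:
        raise ConfigurationError(f"unknown comparison method {method!r}")

    out = pd.DataFrame(rows, columns=[
        "chemical_id", "group_mean", "control_mean", "t", "df", "p_raw", "p_adj"])
    out["significant"] = out["p_adj"] < alpha
    return out


class LethalityAnova:
    """Embryonic-lethality model over a per-plate hatching table.

    Parameters
    ----------
    plates
        Table with columns ``chemical_id, experiment, plate, n_embryos,
        n_hatched``; one group per chemical plus the control label.
    control
        Label of the vehicle-control group (default ``"DMSO"``).
    method
        Multiple-comparison flavour, ``"sidak"`` or ``"dunnett"``.
    """

    def __init__(self, plates: pd.DataFrame, control: str = "DMSO",
                 method: str = "sidak", alpha: float = 0.05):
        self.plates = add_lethality(plates)
        self.control = control
        self.method = method
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "LethalityAnova":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "LethalityResults":
        grouped = {
            str(chem): sub["lethality"].to_numpy()
            for chem, sub in self.plates.groupby("chemical_id")
        }
        if self.control not in grouped:
            raise ConfigurationError(f"control group {self.control!r} missing")
        anova = welch_anova(list(grouped.values()))
        comparisons = dunnett_vs_control(
            grouped, self.control, method=self.method, alpha=self.alpha)
        means = pd.Series({c: g.mean() for c, g in grouped.items()},
                          name="mean_lethality")
        return LethalityResults(model=self, group_means=means, anova=anova,
                                comparisons=comparisons)


@dataclass
class LethalityResults:
    model: LethalityAnova
    group_means: pd.Series
    anova: WelchAnovaResult
    comparisons: pd.DataFrame

    @property
    def significant_chemicals(self) -> list[str]:
        sel = self.comparisons.loc[self.comparisons["significant"], "chemical_id"]
        return sorted(sel)

    def summary(self) -> str:
        a = self.anova
        lines = [
            "Embryonic lethality: Welch / Brown-Forsythe ANOVA",
            "=" * 50,
            f"groups: {len(self.group_means)} (control: {self.model.control})",
            f"Welch  F({a.df1:.0f}, {a.df2:.1f}) = {a.F:.3f}, p = {a.p:.3g}"
            + ("  [ordinary one-way fallback]" if a.method != "welch" else ""),
            f"Brown-Forsythe F*({a.bf_df1:.0f}, {a.bf_df2:.1f}) = {a.bf_F:.3f}, "
            f"p = {a.bf_p:.3g}",
            "",
            f"comparisons vs {self.model.control} "
            f"({self.model.method}-adjusted, alpha = {self.model.alpha}):",
        ]
        for _, row in self.comparisons.iterrows():
            flag = "*" if row["significant"] else " "
            lines.append(
                f"  {flag} {row['chemical_id']:<42s} "
                f"mean = {row['group_mean']:.3f}  p_adj = {row['p_adj']:.4g}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.comparisons.copy()
        out["welch_F"], out["welch_p"] = self.anova.F, self.anova.p
        out["brown_forsythe_F"], out["brown_forsythe_p"] = (
            self.anova.bf_F, self.anova.bf_p)
        out.to_csv(path, index=False)
        return path

    def plot(self, ax=None):
        """Bar plot of group mean lethality with significance stars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        order = [self.model.control] + list(self.comparisons["chemical_id"])
        means = self.group_means.reindex(order)
        ax.bar(range(len(order)), means.to_numpy())
        sig = set(self.significant_chemicals)
        for i, chem in enumerate(order):
            if chem in sig:
                ax.text(i, means.iloc[i], "*", ha="center", va="bottom")
        ax.set_xticks(range(len(order)), order, rotation=60, ha="right")
        ax.set_ylabel("embryonic lethality")
        return ax
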