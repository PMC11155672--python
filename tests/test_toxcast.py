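"""Bioactivity summaries, Fisher enrichment and BH adjustment."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from reproscreen import (
    ConfigurationError,
    InvalidRecordError,
    benjamini_hochberg,
    bioactivity_ratio,
    bioactivity_table,
    compare_group_bioactivity,
    family_counts,
    family_enrichment,
    log10_ac50,
)
from reproscreen.datasets import (
    load_reference_bioactivity,
    load_reference_family_counts,
)
from reproscreen.toxcast import fisher_exact_p


def assay_frame(rows):
    """rows: (chemical, hit, ac50, family)"""
    return pd.DataFrame(
        [{"chemical_id": c, "assay_id": f"a{i}", "hit_call": h,
          "ac50_um": a, "intended_target_family": f}
         for i, (c, h, a, f) in enumerate(rows)])


def two_sided_fisher_oracle(a, b, c, d):
    """Brute-force hypergeometric enumeration of the two-sided p."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: (math.comb(r1, k) * math.comb(r2, c1 - k)
               / math.comb(r1 + r2, c1)) for k in range(lo, hi + 1)}
    observed = pmf[a]
    return sum(p for p in pmf.values() if p <= observed * (1 + 1e-10))


def one_sided_greater_oracle(a, b, c, d):
    r1, r2, c1 = a + b, c + d, a + c
    hi = min(r1, c1)
    return sum(math.comb(r1, k) * math.comb(r2, c1 - k)
               / math.comb(r1 + r2, c1) for k in range(a, hi + 1))


class TestBioactivity:
    @pytest.mark.parametrize("n_active,n_total,expected",
                             [(218, 446, 0.489), (22, 858, 0.026), (0, 100, 0.0)])
    def test_ratio_rounding(self, n_active, n_total, expected):
        rows = [("X", i < n_active, 1.0 if i < n_active else np.nan, "Cyp")
                for i in range(n_total)]
        out = bioactivity_ratio(assay_frame(rows))
        assert out["n_active"] == n_active
        assert round(out["bioactivity_ratio"], 3) == expected

    def test_reference_tables_recompute_to_3_decimals(self):
        ref = load_reference_bioactivity()
        recomputed = (ref["n_active"] / ref["n_total"]).round(3)
        assert (recomputed == ref["reported_ratio"]).all()

    def test_zero_assays_marked_missing(self):
        out = bioactivity_ratio(assay_frame([]))
        assert np.isnan(out["bioactivity_ratio"])
        table = bioactivity_table(
            assay_frame([("X", True, 1.0, "Cyp")]), chemicals=["X", "absent"])
        missing = table.set_index("chemical_id").loc["absent"]
        assert np.isnan(missing["bioactivity_ratio"])


class TestLog10Ac50:
    def test_rules(self):
        rows = [("X", True, 1.0, "Cyp"),     # log10(1) = 0
                ("X", True, np.nan, "Cyp"),  # missing -> 3
                ("X", True, 1000.0, "Cyp"),  # log10(1000) = 3
                ("X", False, np.nan, "Cyp")]  # inactive ignored
        vals = log10_ac50(assay_frame(rows))
        assert vals == pytest.approx([0.0, 3.0, 3.0])

    def test_non_positive_ac50_rejected(self):
        with pytest.raises(InvalidRecordError):
            log10_ac50(assay_frame([("X", True, -1.0, "Cyp")]))


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        _, _, p = compare_group_bioactivity([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert p == pytest.approx(1.0)

    def test_separated_groups_p_tiny(self, rng):
        a = rng.normal(0.0, 1e-6, 4)
        b = 1 + rng.normal(0.0, 1e-6, 4)
        _, _, p = compare_group_bioactivity(b, a)
        assert p < 1e-6

    def test_welch_satterthwaite_closed_form(self):
        # textbook unequal-variance fixture, hand-computed df
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8])
        res = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df_hand = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                    + vb ** 2 / (len(b) - 1))
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        mh, ml, p = compare_group_bioactivity(a, b)
        assert p == pytest.approx(res.pvalue, rel=1e-12)
        assert (mh, ml) == (pytest.approx(a.mean()), pytest.approx(b.mean()))

    def test_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_group_bioactivity([0.1], [0.2, 0.3])


class TestFamilyCounts:
    def test_channels_excluded_and_chemicals_drop_out(self):
        rows = [("A", True, 1.0, "Cyp"), ("A", True, 1.0, "channel 1"),
                ("B", True, 1.0, "channel 2"), ("B", False, np.nan, "Cyp"),
                ("C", True, 1.0, "Kinase")]
        counts = family_counts(assay_frame(rows),
                               {"A": "top", "B": "top", "C": "bottom"})
        assert set(counts.index) == {"Cyp", "Kinase"}
        assert counts.loc["Cyp", "top"] == 1
        # chemical B was active only in a channel category: contributes nothing
        assert counts["top"].sum() == 1

    def test_all_channel_records_give_empty_table(self):
        rows = [("A", True, 1.0, "channel 2"), ("B", True, 1.0, "channel 2")]
        counts = family_counts(assay_frame(rows), {"A": "top", "B": "bottom"})
        assert counts.empty

    def test_empty_records_give_empty_counts(self):
        counts = family_counts(assay_frame([]), {})
        assert counts.empty

    def test_reference_family_totals(self):
        ref = load_reference_family_counts()
        total = ref["count_bottom"] + ref["count_top"]
        assert total["Cell cycle"] == 1106
        assert total["Nuclear receptor"] == 849

    def test_unassigned_chemical_rejected(self):
        rows = [("A", True, 1.0, "Cyp")]
        with pytest.raises(ConfigurationError, match="group assignment"):
            family_counts(assay_frame(rows), {})


class TestFisher:
    def test_enumeration_oracle_small_table(self):
        p = fisher_exact_p([[3, 1], [1, 3]])
        assert p == pytest.approx(two_sided_fisher_oracle(3, 1, 1, 3), abs=1e-12)
        assert p == pytest.approx(0.48571428571, abs=1e-9)

    def test_proportional_table_p_one(self):
        # counts in the exact ratio of the margins: no association
        assert fisher_exact_p([[10, 20], [20, 40]]) == pytest.approx(1.0)

    @settings(max_examples=80, deadline=None)
    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    def test_matches_enumeration_property(self, a, b, c, d):
        assert fisher_exact_p([[a, b], [c, d]]) == pytest.approx(
            two_sided_fisher_oracle(a, b, c, d), abs=1e-10)
        assert fisher_exact_p([[a, b], [c, d]], "greater") == pytest.approx(
            one_sided_greater_oracle(a, b, c, d), abs=1e-10)


class TestFamilyEnrichment:
    def test_reference_counts_reproduce_reported_enrichment(self):
        ref = load_reference_family_counts()
        counts = ref[["count_bottom", "count_top"]].rename(
            columns={"count_bottom": "bottom", "count_top": "top"})
        res = family_enrichment(counts, m=42)
        row = res.family_row("Steroid hormone")
        assert row["fisher_p"] == pytest.approx(0.000431, abs=2e-4)
        assert row["fdr_adjusted_p"] == pytest.approx(0.018115, abs=0.02)
        assert res.n_significant_raw == 5
        sig = set(res.enrichment.loc[res.enrichment["fisher_p"] < 0.05, "family"])
        assert sig == {"Steroid hormone", "Cell cycle", "Gpcr", "Kinase",
                       "Deiodinase"}
        # bottom-enriched families are not flagged by the one-sided default
        assert res.family_row("Neurodevelopment")["fisher_p"] == pytest.approx(1.0)
        assert res.meta["construction"] == "rest"

    def test_two_sided_option_flags_bottom_families_too(self):
        ref = load_reference_family_counts()
        counts = ref[["count_bottom", "count_top"]].rename(
            columns={"count_bottom": "bottom", "count_top": "top"})
        res = family_enrichment(counts, alternative="two-sided")
        assert res.family_row("Neurodevelopment")["fisher_p"] < 0.001

    def test_zero_total_family_flagged(self):
        counts = pd.DataFrame({"bottom": [5, 0, 10], "top": [8, 0, 2]},
                              index=["a", "empty", "c"])
        res = family_enrichment(counts)
        row = res.family_row("empty")
        assert row["fisher_p"] == 1.0 and bool(row["degenerate"])

    def test_construction_margin_differs(self):
        counts = pd.DataFrame({"bottom": [5, 100], "top": [30, 120]},
                              index=["a", "b"])
        res_rest = family_enrichment(counts, construction="rest")
        res_margin = family_enrichment(counts, construction="margin")
        assert (res_rest.family_row("a")["fisher_p"]
                != res_margin.family_row("a")["fisher_p"])
        assert res_margin.meta["construction"] == "margin"

    def test_input_validation(self):
        counts = pd.DataFrame({"bottom": [5], "top": [3]}, index=["a"])
        with pytest.raises(ConfigurationError, match=">= 2 families"):
            family_enrichment(counts)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_reference_top_rank(self):
        ref = load_reference_family_counts()
        adj = benjamini_hochberg(ref["reported_fisher_p"].tolist(), m=42)
        smallest = adj[np.argmin(ref["reported_fisher_p"].to_numpy())]
        assert smallest == pytest.approx(0.000431 * 42, rel=1e-6)
        assert smallest == pytest.approx(0.018115, abs=2e-5)

    def test_never_below_raw_and_stable(self, rng):
        p = rng.uniform(0, 1, size=40)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        # re-adjustment can only move values up, and sorted order is kept
        again = benjamini_hochberg(adj)
        assert (again >= adj - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # constant vectors are fixed points
        const = np.full(10, 0.2)
        np.testing.assert_allclose(benjamini_hochberg(const), const, atol=1e-12)

    def test_matches_statsmodels_when_m_equals_len(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, size=25)
        adj = benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidRecordError):
            benjamini_hochberg([0.5, 1.5])
        with pytest.raises(ConfigurationError):
            benjamini_hochberg([0.5, 0.1], m=1)

    def test_reference_printed_significance_pattern(self):
        ref = load_reference_family_counts()
        assert (ref["reported_fisher_p"] < 0.05).sum() == 5
        assert (ref["reported_fdr_p"] < 0.05).sum() == 1
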