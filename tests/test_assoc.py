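"""Variant filtering, Fisher/trend/rank statistics, logistic adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tc6mm import assoc


def _alt(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "alteration_type",
                                       "codon", "vaf"])


class TestFilterVariants:
    def test_non_activating_braf_dropped(self):
        raw = _alt([("s1", "BRAF", "missense", "D594G", 0.3)])
        assert len(assoc.filter_variants(raw)) == 0

    def test_vaf_boundary_inclusive(self):
        raw = _alt([("s1", "KRAS", "missense", "Q61", 0.05),
                    ("s2", "KRAS", "missense", "Q61", 0.049)])
        out = assoc.filter_variants(raw)
        assert list(out["sample_id"]) == ["s1"]

    def test_non_ras_gene_keeps_all_classes(self):
        raw = _alt([("s1", "TP53", "frameshift", "", 0.3),
                    ("s2", "TP53", "deletion", "", 1.0),
                    ("s3", "TP53", "splice", "", 0.2)])
        assert len(assoc.filter_variants(raw)) == 3

    def test_ras_non_missense_dropped(self):
        raw = _alt([("s1", "NRAS", "frameshift", "Q61", 0.3)])
        assert len(assoc.filter_variants(raw)) == 0

    def test_malformed_ras_codon_errors(self):
        raw = _alt([("s1", "KRAS", "missense", "", 0.3)])
        with pytest.raises(ValueError, match="codon"):
            assoc.filter_variants(raw)

    def test_idempotent_on_synthetic_calls(self, cohort900):
        once = assoc.filter_variants(cohort900.alterations)
        twice = assoc.filter_variants(once)
        pd.testing.assert_frame_equal(once, twice)


class TestResolveRasRaf:
    def test_highest_vaf_wins(self):
        raw = _alt([("s1", "KRAS", "missense", "G12", 0.30),
                    ("s1", "NRAS", "missense", "Q61", 0.10)])
        out = assoc.resolve_ras_raf(raw)
        assert len(out) == 1 and out["gene"].iloc[0] == "KRAS"

    def test_single_call_unchanged(self):
        raw = _alt([("s1", "NRAS", "missense", "Q61", 0.2)])
        out = assoc.resolve_ras_raf(raw)
        assert out["gene"].tolist() == ["NRAS"]

    def test_exact_tie_broken_by_gene_order(self):
        raw = _alt([("s1", "NRAS", "missense", "Q61", 0.20),
                    ("s1", "KRAS", "missense", "G12", 0.20)])
        out = assoc.resolve_ras_raf(raw)
        assert out["gene"].tolist() == ["KRAS"]

    def test_at_most_one_ras_row_per_sample(self, filtered_alterations):
        ras = filtered_alterations[
            filtered_alterations["gene"].isin(assoc.RAS_RAF_GENES)]
        assert ras["sample_id"].value_counts().max() == 1


class TestFisher:
    @pytest.mark.parametrize("table,printed", [
        ([[1, 24], [7, 18]], 0.049),
        ([[10, 8], [15, 56]], 0.007),
        ([[60, 234], [65, 446]], 0.005),
    ])
    def test_printed_p_values(self, table, printed):
        assert round(assoc.fisher_2x2(table).p_two_sided, 3) == printed

    def test_full_enumeration_example(self):
        res = assoc.fisher_2x2([[5, 0], [0, 5]])
        assert res.p_two_sided == pytest.approx(2 / 252, abs=1e-12)

    def test_symmetric_table_p_one(self):
        assert assoc.fisher_2x2([[3, 3], [3, 3]]).p_two_sided == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            assoc.fisher_2x2([[0, 0], [3, 4]])

    def test_odds_ratio_and_infinity(self):
        res = assoc.fisher_2x2([[6, 2], [3, 9]])
        assert res.odds_ratio == pytest.approx(9.0)
        assert assoc.fisher_2x2([[5, 0], [3, 9]]).odds_ratio == np.inf

    def test_doubling_method_valid(self):
        p = assoc.fisher_2x2([[1, 24], [7, 18]], method="doubling").p_two_sided
        assert 0 < p <= 1

    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_transposition_and_row_swap(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = assoc.fisher_2x2([[a, b], [c, d]]).p_two_sided
        assert assoc.fisher_2x2([[c, d], [a, b]]).p_two_sided == pytest.approx(p)
        assert assoc.fisher_2x2([[a, c], [b, d]]).p_two_sided == pytest.approx(p)


class TestCochranArmitage:
    @pytest.mark.parametrize("counts,printed", [
        ((3, 10, 16), 0.025),
        ((5, 14, 19), 0.056),
    ])
    def test_printed_trend_p(self, counts, printed):
        res = assoc.cochran_armitage(counts, (182, 329, 294))
        assert round(res.p_two_sided, 3) == printed

    def test_equal_proportions_no_trend(self):
        res = assoc.cochran_armitage((10, 10, 10), (100, 100, 100))
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_degenerate_counts_warn(self):
        with pytest.warns(UserWarning):
            res = assoc.cochran_armitage((0, 0), (10, 10))
        assert res.p_two_sided == 1.0

    def test_two_groups_reduce_to_proportion_z_test(self):
        k, n = (12, 30), (100, 90)
        res = assoc.cochran_armitage(k, n)
        p1, p2 = k[0] / n[0], k[1] / n[1]
        pbar = sum(k) / sum(n)
        z = (p2 - p1) / np.sqrt(pbar * (1 - pbar) * (1 / n[0] + 1 / n[1]))
        assert abs(res.z) == pytest.approx(abs(z), rel=1e-12)


class TestRankTest:
    def test_identical_samples(self):
        assert assoc.rank_test([1, 2, 3, 4], [1, 2, 3, 4]) > 0.9

    def test_exact_enumeration_small_groups(self):
        assert assoc.rank_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_large_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        assert assoc.rank_test(a, b) < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.rank_test([], [1.0])


class TestSubgroupEnrichment:
    def test_mmset_exclusive_fgfr3_mutations(self, cohort900, classified900,
                                             filtered_alterations):
        _, _, calls = classified900
        res = assoc.subgroup_enrichment(
            filtered_alterations, calls, "FGFR3",
            (("MMSET",), ("D1-HRD", "D2", "CCND1-11q13", "MAF")))
        assert res.p_two_sided < 0.001

    def test_permuted_labels_give_uniform_p(self, cohort5000):
        """Under label permutation the enrichment p-value is approximately
        Uniform(0,1) (KS p > 0.01). Tested on a large cohort so the discrete
        exact-test support is fine enough for the asymptotics to hold."""
        rng = np.random.default_rng(1)
        filtered = assoc.resolve_ras_raf(
            assoc.filter_variants(cohort5000.alterations))
        truth = cohort5000.truth[cohort5000.truth["subgroup"] != "NPC"]
        base = truth[["sample_id", "subgroup"]].copy()
        part = (("D1-HRD", "D2", "CCND1-11q13"), ("MMSET", "MAF", "CCND3-6p21"))
        pvals = []
        for _ in range(500):
            calls = base.copy()
            calls["subgroup"] = rng.permutation(calls["subgroup"].to_numpy())
            pvals.append(assoc.subgroup_enrichment(
                filtered, calls, "TP53", part).p_two_sided)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_overlapping_partition_rejected(self, classified900,
                                            filtered_alterations):
        _, _, calls = classified900
        with pytest.raises(ValueError, match="overlap"):
            assoc.subgroup_enrichment(filtered_alterations, calls, "TP53",
                                      (("D2",), ("D2", "MAF")))

    def test_all_mutated_cohort_zero_margin(self):
        calls = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                              "subgroup": ["D2", "D2", "MAF", "MAF"]})
        alts = _alt([(s, "TP53", "missense", "", 0.3)
                     for s in ("a", "b", "c", "d")])
        with pytest.raises(ValueError, match="margin"):
            assoc.subgroup_enrichment(alts, calls, "TP53",
                                      (("D2",), ("MAF",)))


class TestStageAdjustedLogistic:
    @staticmethod
    def _simulate(n, or_subgroup, seed):
        rng = np.random.default_rng(seed)
        subgroup = rng.choice(["A", "B"], n)
        stage = rng.choice(["untreated", "in_treatment", "relapse"], n)
        logit = -1.0 + np.log(or_subgroup) * (subgroup == "B") \
            + 0.4 * (stage == "relapse")
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return y.astype(int), subgroup, stage

    def test_recovers_planted_or_3(self):
        y, subgroup, stage = self._simulate(2000, 3.0, 0)
        res = {r.term: r for r in assoc.stage_adjusted_logistic(y, subgroup, stage)}
        beta = list(res["subgroup"].coefficients.values())[0]
        # 3 SEs at n=2000 is generous; SE(log OR) ~ 0.11 here
        assert abs(beta - np.log(3.0)) < 3 * 0.15
        assert res["subgroup"].p_value < 1e-6

    def test_null_p_values_approximately_uniform(self):
        pvals = []
        for s in range(150):
            y, subgroup, stage = self._simulate(300, 1.0, 100 + s)
            res = assoc.stage_adjusted_logistic(y, subgroup, stage)
            pvals.append(next(r.p_value for r in res if r.term == "subgroup"))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_factor_matches_closed_form_log_odds(self):
        y = np.array([1] * 30 + [0] * 70 + [1] * 10 + [0] * 90)
        subgroup = np.array(["B"] * 100 + ["A"] * 100)
        stage = np.array(["untreated"] * 200)  # constant: no stage dummies
        res = {r.term: r for r in assoc.stage_adjusted_logistic(y, subgroup, stage)}
        beta = list(res["subgroup"].coefficients.values())[0]
        expect = np.log((30 / 70) / (10 / 90))
        assert beta == pytest.approx(expect, rel=1e-4)

    def test_perfect_separation_flagged(self):
        y = np.array([1] * 50 + [0] * 50)
        subgroup = np.array(["B"] * 50 + ["A"] * 50)
        stage = np.tile(["untreated", "relapse"], 50)
        res = {r.term: r for r in assoc.stage_adjusted_logistic(y, subgroup, stage)}
        assert res["subgroup"].unstable

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            assoc.stage_adjusted_logistic([1, 1, 1], ["A", "B", "A"],
                                          ["untreated"] * 3)
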