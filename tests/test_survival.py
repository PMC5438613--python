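"""Kaplan-Meier, log-rank, conditional-inference tree, three-arm strata."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from tc6mm import survival as sv


def _km_oracle(times, events):
    """Brute-force product-limit: loop over distinct event times."""
    order = np.argsort(times)
    t, e = np.asarray(times, float)[order], np.asarray(events, int)[order]
    s = 1.0
    out = {}
    for u in np.unique(t[e == 1]):
        n = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= 1 - d / n
        out[u] = s
    return out


class TestKM:
    def test_uncensored_equals_empirical_survival(self):
        t = np.array([1.0, 2, 3, 4, 5])
        curve = sv.km(t, np.ones(5, int))
        assert sv.os_at(curve, 3.5) == pytest.approx(0.4)
        for u, expect in zip([1, 2, 3, 4, 5], [0.8, 0.6, 0.4, 0.2, 0.0]):
            assert sv.os_at(curve, u) == pytest.approx(expect)

    def test_all_censored_flat_at_one(self):
        curve = sv.km([3.0, 5.0, 9.0], [0, 0, 0])
        assert sv.os_at(curve, 100.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # times 1+, 2, 3, 4+, 5: S(2)=4/5*... n at 2 is 4 -> 3/4; at 3 -> 2/3; at 5 -> 0
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        e = [0, 1, 1, 0, 1]
        curve = sv.km(t, e)
        assert sv.os_at(curve, 2.5) == pytest.approx(3 / 4)
        assert sv.os_at(curve, 3.5) == pytest.approx(1 / 2)
        assert sv.os_at(curve, 5.0) == pytest.approx(0.0)

    def test_matches_oracle_on_random_censored_data(self):
        rng = np.random.default_rng(0)
        t = np.round(rng.exponential(10, 60), 1)
        e = (rng.random(60) < 0.6).astype(int)
        curve = sv.km(t, e)
        oracle = _km_oracle(t, e)
        for u, s in oracle.items():
            assert sv.os_at(curve, u) == pytest.approx(s, abs=1e-10)

    def test_greenwood_variance_nonnegative_and_monotone(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.7).astype(int)
        curve = sv.km(t, e)
        assert (curve.greenwood_var >= 0).all()
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sv.km([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_no_signal(self):
        t = np.array([1.0, 2, 3, 4, 5] * 2)
        e = np.ones(10, int)
        g = np.repeat([0, 1], 5)
        stat, p = sv.logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 150)
        e = (rng.random(150) < 0.6).astype(int)
        g = rng.choice(3, 150)
        stat, p = sv.logrank(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_power_against_hazard_ratio_3(self):
        """Exponential groups with HR=3 at n=200/200 are detected at
        p < 1e-4 in at least 95% of 200 simulations."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            t = np.concatenate([rng.exponential(30, 200),
                                rng.exponential(10, 200)])
            c = rng.exponential(40, 400)
            e = (t <= c).astype(int)
            obs = np.minimum(t, c)
            _, p = sv.logrank(obs, e, np.repeat([0, 1], 200))
            hits += p < 1e-4
        assert hits / 200 >= 0.95

    def test_permutation_null_uniform(self):
        from scipy import stats as spstats
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 120)
        e = (rng.random(120) < 0.7).astype(int)
        pvals = [sv.logrank(t, e, rng.permutation(np.repeat([0, 1], 60)))[1]
                 for _ in range(300)]
        assert spstats.kstest(pvals, "uniform").pvalue > 0.01

    def test_invariant_to_monotone_time_rescaling(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 100)
        e = (rng.random(100) < 0.6).astype(int)
        g = np.repeat([0, 1], 50)
        stat1, _ = sv.logrank(t, e, g)
        stat2, _ = sv.logrank(t**2, e, g)  # strictly monotone rescaling
        assert stat1 == pytest.approx(stat2, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="single stratum|2 groups"):
            sv.logrank([1.0, 2.0], [1, 1], [0, 0])


def _sim_survival(rng, n, hr_gene, n_noise=20, hr=3.0, base_scale=30.0,
                  prevalence=0.15):
    feats = pd.DataFrame(
        rng.random((n, n_noise + 1)) < prevalence,
        columns=[hr_gene] + [f"noise{i}" for i in range(n_noise)],
    )
    lam = (1 / base_scale) * np.where(feats[hr_gene], hr, 1.0)
    t = rng.exponential(1 / lam)
    c = rng.exponential(25, n)
    return np.minimum(t, c), (t <= c).astype(int), feats


class TestCITree:
    def test_null_features_rarely_split(self):
        """Global null: a root-only tree in >= 90% of 200 simulations with
        20 uninformative candidates at alpha = 0.05."""
        rng = np.random.default_rng(6)
        root_only = 0
        for _ in range(200):
            t, e, feats = _sim_survival(rng, 200, "g0", n_noise=19, hr=1.0)
            tree = sv.ci_tree(t, e, feats, alpha=0.05, min_node=20)
            root_only += tree.is_leaf
        assert root_only / 200 >= 0.90

    def test_planted_adverse_gene_found_first(self):
        """Planted HR=3 gene among 20 noise genes at n=500: first split on
        the planted gene in >= 90% of 200 simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            t, e, feats = _sim_survival(rng, 500, "TP53", n_noise=20, hr=3.0)
            tree = sv.ci_tree(t, e, feats, alpha=0.05, min_node=20)
            hits += (not tree.is_leaf) and tree.feature == "TP53"
        assert hits / 200 >= 0.90

    def test_min_node_larger_than_n_gives_root_only(self):
        rng = np.random.default_rng(8)
        t, e, feats = _sim_survival(rng, 50, "g", n_noise=3, hr=5.0)
        tree = sv.ci_tree(t, e, feats, min_node=60)
        assert tree.is_leaf

    def test_no_candidates_gives_root_only(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 100)
        e = np.ones(100, int)
        tree = sv.ci_tree(t, e, pd.DataFrame(index=range(100)))
        assert tree.is_leaf and tree.n == 100

    def test_deterministic_and_serializable(self):
        rng = np.random.default_rng(10)
        t, e, feats = _sim_survival(rng, 400, "TP53", hr=4.0)
        t1 = sv.ci_tree(t, e, feats)
        t2 = sv.ci_tree(t, e, feats)
        assert t1.to_text() == t2.to_text()
        d = t1.to_dict()
        assert d["leaf"] is False and d["feature"] == "TP53"
        assert t1.p_adjusted < 0.05

    def test_permutation_option_agrees_on_strong_signal(self):
        rng = np.random.default_rng(11)
        t, e, feats = _sim_survival(rng, 400, "TP53", n_noise=5, hr=4.0)
        tree = sv.ci_tree(t, e, feats, n_permutations=199, seed=1)
        assert not tree.is_leaf and tree.feature == "TP53"


class TestThreeArm:
    def test_arm_assignment_rules(self):
        t = np.array([5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 1, 0, 1])
        res = sv.three_arm(t, e, adverse_flag=[1, 0, 1, 0],
                           gep70_hr_flag=[1, 1, 0, 0],
                           sample_ids=list("abcd"))
        assert res.arms["a"] == "poor"
        assert res.arms["b"] == "intermediate"
        assert res.arms["c"] == "intermediate"
        assert res.arms["d"] == "standard"

    def test_single_stratum_surfaces_error(self):
        with pytest.raises(ValueError, match="single stratum"):
            sv.three_arm([1.0, 2.0], [1, 1], [0, 0], [0, 0])

    def test_missing_flags_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            sv.three_arm([1.0, 2.0], [1, 1], [0, np.nan], [0, 1])

    def test_planted_ordered_hazards_give_ordered_18_month_os(self):
        """With hazards ordered poor > intermediate > standard, the estimated
        18-month OS is strictly ordered in >= 95% of 200 simulations (n=500)."""
        rng = np.random.default_rng(12)
        ordered = 0
        for _ in range(200):
            adv = rng.random(500) < 0.25
            hr70 = rng.random(500) < 0.25
            lam = 0.008 * np.where(adv, 3.5, 1.0) * np.where(hr70, 3.5, 1.0)
            t = rng.exponential(1 / lam)
            c = rng.exponential(20, 500)
            res = sv.three_arm(np.minimum(t, c), (t <= c).astype(int), adv, hr70)
            if set(res.os_18) == {"poor", "intermediate", "standard"}:
                ordered += (res.os_18["poor"] < res.os_18["intermediate"]
                            < res.os_18["standard"])
        assert ordered / 200 >= 0.95


class TestMutualExclusivity:
    def test_disjoint_sets_have_zero_cooccurrence(self):
        alt = pd.DataFrame({"sample_id": ["a", "b", "c", "d"],
                            "gene": ["CDKN2C", "CDKN2C", "RB1", "RB1"]})
        n, res = sv.mutual_exclusivity_check(alt, "CDKN2C", "RB1",
                                             list("abcdefgh"))
        assert n == 0
        assert res is not None

    def test_identical_sets_cooccur_fully(self):
        alt = pd.DataFrame({"sample_id": ["a", "b", "a", "b"],
                            "gene": ["X", "X", "Y", "Y"]})
        n, _ = sv.mutual_exclusivity_check(alt, "X", "Y", list("abcd"))
        assert n == 2

    def test_independent_rare_events_near_expected(self):
        rng = np.random.default_rng(13)
        universe = [f"s{i}" for i in range(800)]
        rows = []
        for s in universe:
            if rng.random() < 0.05:
                rows.append({"sample_id": s, "gene": "A"})
            if rng.random() < 0.05:
                rows.append({"sample_id": s, "gene": "B"})
        n, res = sv.mutual_exclusivity_check(pd.DataFrame(rows), "A", "B",
                                             universe)
        assert n <= 8  # expectation 2 under independence
        assert res.p_two_sided > 0.001

    def test_absent_gene_warns(self):
        alt = pd.DataFrame({"sample_id": ["a"], "gene": ["X"]})
        with pytest.warns(UserWarning, match="zero margin"):
            n, res = sv.mutual_exclusivity_check(alt, "X", "MISSING",
                                                 list("ab"))
        assert n == 0 and res is None
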