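"""Statistics layer against enumeration and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliamorph import stats as st
from gliamorph.datasets import human_cohort_demographics


def mw_exact_p_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mean_u = len(x) * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    dev = abs(u_obs - mean_u)
    p = np.mean([abs(u - mean_u) >= dev - 1e-12 for u in us])
    return float(p)


class TestMannWhitney:
    def test_separated_samples_enumeration(self):
        # {1,2,3} vs {4,5,6}: U = 0, the most extreme of C(6,3)=20
        # labelings on both sides -> two-sided exact p = 2/20 = 0.10
        u, p = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)
        assert p == pytest.approx(mw_exact_p_enumeration([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        _, p = st.mann_whitney(x, y)
        assert p == pytest.approx(mw_exact_p_enumeration(x, y))

    def test_identical_groups_not_significant(self):
        _, p = st.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1, 2])


def bky_brute_force(p, q):
    """Independent step-up implementation of the two-stage procedure."""
    p = np.asarray(p, float)
    m = len(p)

    def step_up(level):
        order = np.argsort(p)
        reject = np.zeros(m, bool)
        kmax = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= level * rank / m:
                kmax = rank
        reject[order[:kmax]] = True
        return reject

    q1 = q / (1 + q)
    r1 = step_up(q1).sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return step_up(q1 * m / (m - r1))


class TestBKY:
    def test_example_vector_matches_oracle(self):
        p = [0.001, 0.009, 0.04, 0.5]
        got = st.bky_two_stage(p, q=0.05)
        assert np.array_equal(got, bky_brute_force(p, 0.05))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_pvectors_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 40))
        # mixture of nulls and signals
        p = np.concatenate([rng.uniform(size=m),
                            rng.uniform(0, 0.01, size=rng.integers(0, 5))])
        for q in (0.01, 0.05, 0.1):
            assert np.array_equal(st.bky_two_stage(p, q), bky_brute_force(p, q))

    def test_matches_statsmodels_two_stage(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(50):
            p = rng.uniform(size=12) ** 2
            ours = st.bky_two_stage(p, q=0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert np.array_equal(ours, theirs)

    def test_adaptivity_dominates_bh(self):
        # BKY discoveries are a superset of plain BH at the same q
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=20) ** 3
            bky = st.bky_two_stage(p, q=0.05)
            bh = st._linear_step_up(np.asarray(p), 0.05)
            assert np.all(bky | ~bh)

    def test_family_discovery_flags(self):
        comps = {
            "a": ([1, 2, 3], [10, 11, 12, 13, 14, 15]),
            "b": ([1, 2, 3], [1.1, 2.1, 3.1]),
        }
        res = st.mannwhitney_bky(comps, q=0.05)
        assert res[0].discovery in (True, False)
        assert not res[1].discovery
        assert all(r.p_value <= 1 for r in res)


class TestSpearman:
    def test_monotone_transform_gives_unit_r(self):
        x = np.arange(1, 11, dtype=float)
        df = pd.DataFrame({"x": x, "cube": x**3, "neg": -x})
        cm = st.spearman_matrix(df)
        assert cm.r.loc["x", "cube"] == pytest.approx(1.0)
        assert cm.r.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.allclose(cm.r.values, cm.r.values.T, equal_nan=True)

    def test_hand_rankable_pairs_equal_rank_pearson(self):
        pts = [(1, 2), (2, 1), (3, 4), (4, 3), (5, 5)]
        x, y = map(np.array, zip(*pts))
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        df = pd.DataFrame({"x": x, "y": y})
        cm = st.spearman_matrix(df)
        assert cm.r.loc["x", "y"] == pytest.approx(expected)

    def test_constant_variable_reported_missing(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "c": [2, 2, 2, 2, 2]})
        cm = st.spearman_matrix(df)
        assert np.isnan(cm.r.loc["x", "c"])
        assert cm.strength.loc["x", "c"] == "none"

    def test_invariance_under_monotone_transform(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        df1 = pd.DataFrame({"a": a, "b": b})
        df2 = pd.DataFrame({"a": np.exp(a), "b": b**3})
        r1 = st.spearman_matrix(df1).r.loc["a", "b"]
        r2 = st.spearman_matrix(df2).r.loc["a", "b"]
        # exp is increasing; cube is increasing -> r unchanged
        assert r1 == pytest.approx(r2)


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            (0.85, 1e-5, "strong"),
            (0.99, 1e-5, "strong"),
            (-0.75, 0.01, "strong"),
            (0.5, 0.02, "moderate"),
            (-0.4, 0.05, "moderate"),
            (0.69, 0.2, "none"),
            (0.95, 0.2, "none"),
            (0.39, 0.001, "none"),
        ],
    )
    def test_strength_classes(self, r, p, expected):
        assert st.classify_correlation(r, p) == expected

    def test_out_of_range_r_raises(self):
        with pytest.raises(ValueError):
            st.classify_correlation(1.2, 0.01)


class TestTwoWayAnova:
    def test_constant_response_gives_zero_f(self):
        d = pd.DataFrame({
            "y": [5.0] * 8,
            "genotype": ["a", "a", "b", "b"] * 2,
            "timepoint": ["t1"] * 4 + ["t2"] * 4,
        })
        res = st.two_way_anova_tukey(d, "y")
        assert np.allclose(res["anova"]["F"].iloc[:3].fillna(0), 0)
        assert not any(t.discovery for t in res["tukey"])

    def test_balanced_design_matches_hand_computation(self):
        # cells (a1,b1)={1,3} (a1,b2)={2,4} (a2,b1)={5,7} (a2,b2)={6,8}
        # SS_A=32, SS_B=2, SS_AB=0, MSE=2 -> F_A=16, F_B=1, F_AB=0
        d = pd.DataFrame({
            "y": [1, 3, 2, 4, 5, 7, 6, 8.0],
            "genotype": ["a1"] * 4 + ["a2"] * 4,
            "timepoint": ["b1", "b1", "b2", "b2"] * 2,
        })
        a = st.two_way_anova_tukey(d, "y")["anova"]
        f = dict(zip(a.index, a["F"]))
        assert f["C(_a)"] == pytest.approx(16.0)
        assert f["C(_b)"] == pytest.approx(1.0)
        assert f["C(_a):C(_b)"] == pytest.approx(0.0, abs=1e-10)

    def test_tukey_flags_effect_at_right_timepoint(self, rng):
        rows = []
        for tp, delta in (("t1", 0.0), ("t2", 8.0)):
            for g, off in (("ctrl", 0.0), ("mut", delta)):
                for _ in range(6):
                    rows.append({"y": rng.normal(off, 1.0),
                                 "genotype": g, "timepoint": tp})
        res = st.two_way_anova_tukey(pd.DataFrame(rows), "y")
        flags = {t.comparison: t.discovery for t in res["tukey"]}
        t1 = [v for k, v in flags.items() if "timepoint=t1" in k][0]
        t2 = [v for k, v in flags.items() if "timepoint=t2" in k][0]
        assert not t1 and t2

    def test_empty_cell_raises(self):
        d = pd.DataFrame({"y": [1, 2, 3], "genotype": ["a", "a", "b"],
                          "timepoint": ["t1", "t2", "t1"]})
        with pytest.raises(ValueError):
            st.two_way_anova_tukey(d, "y")


class TestKruskalDunn:
    def test_identical_group_distributions_give_small_h(self):
        res = st.kruskal_dunn({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert res["h"] == pytest.approx(0.0, abs=1e-9)

    def test_h_matches_rank_formula(self):
        # groups {1,2},{3,4},{5,6}: ranks 1..6, H = 12/42 * (8+0+8)
        res = st.kruskal_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert res["h"] == pytest.approx(12 / 42 * 16)

    def test_dunn_adjustment_monotone(self, rng):
        samples = {g: rng.normal(i, 1, 10) for i, g in enumerate("abc")}
        res = st.kruskal_dunn(samples)
        for d in res["dunn"]:
            assert d.p_value >= d.extra["p_raw"] - 1e-12

    def test_fewer_than_three_groups_raises(self):
        with pytest.raises(ValueError):
            st.kruskal_dunn({"a": [1, 2], "b": [3, 4]})


class TestDemographics:
    def test_reference_cohort_summary(self):
        df = human_cohort_demographics()
        s = st.summarize_demographics(df)
        assert round(s.loc["control", "age_mean"], 2) == 62.60
        assert round(s.loc["control", "age_sd"], 2) == 10.95
        assert round(s.loc["control", "pmd_mean"], 2) == 24.15
        assert round(s.loc["control", "pmd_sd"], 2) == 11.06
        assert round(s.loc["ALS", "age_mean"], 2) == 70.10
        assert round(s.loc["ALS", "age_sd"], 2) == 11.07
        assert round(s.loc["ALS", "pmd_mean"], 2) == 18.20
        assert round(s.loc["ALS", "pmd_sd"], 3) == 4.063
        assert s.loc["control", "sex_ratio"] == "5 M:5 F"
        assert s.loc["ALS", "sex_ratio"] == "6 M:4 F"

    def test_single_case_sd_missing(self):
        df = pd.DataFrame({"group": ["g"], "age": [50.0], "sex": ["F"],
                           "pmd": [10.0]})
        s = st.summarize_demographics(df)
        assert np.isnan(s.loc["g", "age_sd"])


def test_significance_stars():
    assert st.significance_stars(0.04) == "*"
    assert st.significance_stars(0.009) == "**"
    assert st.significance_stars(0.0009) == "***"
    assert st.significance_stars(0.00009) == "****"
    assert st.significance_stars(0.2) == "ns"
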