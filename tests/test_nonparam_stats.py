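"""Rank-test stack: formula correctness against independent oracles,
tie handling, and calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronobeh.nonparam_stats import (
    kruskal_wallis,
    scheirer_ray_hare,
    lsd_posthoc,
    mann_whitney,
    ks_normality,
    midranks,
)


def _naive_kruskal_h(groups):
    """Independent H computation: ranks by explicit counting, H from the
    definition with the classical tie correction."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = []
    for x in pooled:
        less = sum(1 for y in pooled if y < x)
        equal = sum(1 for y in pooled if y == x)
        ranks.append(less + (equal + 1) / 2.0)
    rbar = (n + 1) / 2.0
    i = 0
    h = 0.0
    for g in groups:
        r = ranks[i : i + len(g)]
        h += len(g) * (sum(r) / len(r) - rbar) ** 2
        i += len(g)
    h *= 12.0 / (n * (n + 1))
    ties = {}
    for r in ranks:
        ties[r] = ties.get(r, 0) + 1
    corr = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / corr if corr > 0 else 0.0


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_small_instances_match_naive_rank_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            sizes = rng.integers(2, 4, size=rng.integers(2, 4))
            if sizes.sum() > 9:
                continue
            groups = [list(rng.integers(0, 5, s).astype(float)) for s in sizes]
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(_naive_kruskal_h(groups), abs=1e-10)

    def test_matches_scipy_with_ties(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = [rng.integers(0, 6, rng.integers(3, 12)).astype(float) for _ in range(4)]
            ours = kruskal_wallis(groups)
            try:
                ref = kruskal(*groups)
            except ValueError:  # all values identical
                continue
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_permutation_null_contains_observed_h(self):
        """On a tiny instance the chi-square p is close to the exact
        permutation p obtained by enumerating every group assignment."""
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        obs = kruskal_wallis(groups).statistic
        values = [x for g in groups for x in g]
        exact = []
        for perm in itertools.permutations(values):
            exact.append(
                _naive_kruskal_h([list(perm[:3]), list(perm[3:6]), list(perm[6:])])
            )
        exact = np.asarray(exact)
        assert obs == pytest.approx(exact.max(), abs=1e-10)  # maximal separation
        p_exact = float(np.mean(exact >= obs - 1e-12))
        assert 0.0 < p_exact < 0.01

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.lists(
                st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 2)),
                min_size=3,
                max_size=8,
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_invariant_under_monotone_transform(self, groups):
        res_raw = kruskal_wallis(groups)
        res_tr = kruskal_wallis([[np.exp(x / 50) for x in g] for g in groups])
        assert res_tr.statistic == pytest.approx(res_raw.statistic, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


def _rank_anova_oracle(values, a, b):
    """Independent rank-transform two-way ANOVA via statsmodels."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from scipy.stats import rankdata

    r = rankdata(values)
    df = pd.DataFrame({"r": r, "a": np.asarray(a).astype(str), "b": np.asarray(b).astype(str)})
    fit = ols("r ~ C(a)*C(b)", df).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    mst = np.var(r, ddof=1)
    return {
        "factor_a": an.loc["C(a)", "sum_sq"] / mst,
        "factor_b": an.loc["C(b)", "sum_sq"] / mst,
        "interaction": an.loc["C(a):C(b)", "sum_sq"] / mst,
    }


class TestScheirerRayHare:
    a = np.repeat([0, 1], 50)
    b = np.tile(np.repeat([0, 1, 2, 3, 4], 10), 2)

    def test_constant_data_gives_zero(self):
        res = scheirer_ray_hare(np.ones(100), self.a, self.b)
        for r in res.values():
            assert r.statistic == 0.0 and r.p == 1.0

    def test_matches_rank_transform_anova(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.standard_normal(100)
            ours = scheirer_ray_hare(y, self.a, self.b)
            ref = _rank_anova_oracle(y, self.a, self.b)
            for k in ref:
                assert ours[k].statistic == pytest.approx(ref[k], abs=1e-10)

    def test_reduces_to_kruskal_wallis_on_replicate_factor(self):
        """When factor B is a pure replicate relabeling, the A effect
        equals the one-way Kruskal-Wallis H."""
        rng = np.random.default_rng(4)
        y = rng.standard_normal(60)
        a = np.repeat([0, 1, 2], 20)
        b = np.tile([0, 1], 30)  # uninformative labels
        srh = scheirer_ray_hare(y, a, b)
        kw = kruskal_wallis([y[a == k] for k in range(3)])
        assert srh["factor_a"].statistic == pytest.approx(kw.statistic, rel=1e-6)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            scheirer_ray_hare([1, 2, 3, 4], [0, 0, 1, 1], [0, 1, 0, 0])

    def test_unbalanced_design_is_accepted_and_finite(self):
        rng = np.random.default_rng(5)
        a = np.array([0] * 30 + [1] * 20)
        b = np.array(([0] * 10 + [1] * 20) + ([0] * 12 + [1] * 8))
        res = scheirer_ray_hare(rng.standard_normal(50), a, b)
        for r in res.values():
            assert np.isfinite(r.statistic) and 0 <= r.p <= 1


class TestLsdPosthoc:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(6)
        g = [list(rng.standard_normal(10)) for _ in range(4)]
        shared = [g[0]] * 4
        out = lsd_posthoc(shared)
        assert not any(c.significant for c in out)

    def test_separated_group_significant_against_all_others(self):
        rng = np.random.default_rng(7)
        groups = [list(rng.normal(0, 1, 12)) for _ in range(3)] + [
            list(rng.normal(40, 1, 12))
        ]
        out = lsd_posthoc(groups, labels=["a", "b", "c", "far"], control_label="a")
        far = [c for c in out if "far" in (c.group_i, c.group_j)]
        assert all(c.significant for c in far)
        others = [c for c in out if "far" not in (c.group_i, c.group_j)]
        assert not any(c.significant for c in others)

    def test_family_wise_error_controlled_under_global_null(self):
        """Omnibus gating keeps the family-wise error at or below nominal."""
        rng = np.random.default_rng(8)
        fwer = 0
        reps = 800
        for _ in range(reps):
            groups = [rng.standard_normal(10) for _ in range(5)]
            out = lsd_posthoc(groups)
            fwer += any(c.significant for c in out)
        # binomial 99.9% upper bound around 0.05 for 800 reps is ~0.075
        assert fwer / reps <= 0.075


class TestMannWhitneyAndKs:
    def test_u_at_null_mean_for_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2.0)

    def test_u_matches_exhaustive_pair_counting_at_n3(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            x = rng.integers(0, 5, 3).astype(float)
            y = rng.integers(0, 5, 3).astype(float)
            u_pairs = sum(
                1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y
            )
            assert mann_whitney(x, y).statistic == pytest.approx(u_pairs, abs=1e-12)

    def test_exact_enumeration_of_20_orderings_recovers_u_distribution(self):
        """All C(6,3) = 20 assignments of 6 distinct values to two samples
        of 3 enumerate the exact null U distribution."""
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        us = []
        for combo in itertools.combinations(range(6), 3):
            x = [values[i] for i in combo]
            y = [values[i] for i in range(6) if i not in combo]
            us.append(mann_whitney(x, y).statistic)
        assert len(us) == 20
        assert sorted(set(us)) == list(np.arange(0.0, 10.0))
        assert np.mean(us) == pytest.approx(4.5)  # null mean n1 n2 / 2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_ks_normality_sane_and_degenerate_rejected(self):
        rng = np.random.default_rng(10)
        res = ks_normality(rng.standard_normal(200))
        assert res.p > 0.05
        with pytest.raises(ValueError):
            ks_normality([2.0, 2.0, 2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-40, 40, allow_nan=False).map(lambda v: round(v, 2)), min_size=2, max_size=10),
        st.lists(st.floats(-40, 40, allow_nan=False).map(lambda v: round(v, 2)), min_size=2, max_size=10),
    )
    def test_mann_whitney_rank_invariance(self, x, y):
        res_raw = mann_whitney(x, y)
        res_tr = mann_whitney(np.exp(np.asarray(x) / 40), np.exp(np.asarray(y) / 40))
        assert res_tr.statistic == pytest.approx(res_raw.statistic, abs=1e-9)


def test_midranks_average_ties():
    assert list(midranks([10.0, 20.0, 20.0, 30.0])) == [1.0, 2.5, 2.5, 4.0]
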