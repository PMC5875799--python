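"""Exact tests, rank tests and kymograph correlation."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coleokin.fields import KinematicField
from coleokin.stats import (cohort_compare, fisher_exact,
                            kymograph_correlation, mann_whitney_u)
from coleokin.synthetic import WaveParams, wave_field


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided p by enumerating all tables with the margins."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    probs = {}
    for k in range(lo, hi + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(N - r1, c1 - k),
                            math.comb(N, c1))
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def mw_exact_oracle(x, y):
    """Two-sided permutation p for the Mann-Whitney deviation |U - mu|."""
    import scipy.stats

    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2
    off = n1 * (n1 + 1) / 2
    U_obs = ranks[:n1].sum() - off
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        U = sum(ranks[i] for i in idx) - off
        total += 1
        if abs(U - mu) >= abs(U_obs - mu) - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisher:
    def test_overshoot_table_reproduces_printed_values(self):
        # 16/54 predicted vs 5/54 observed overshoots
        res = fisher_exact([[16, 38], [5, 49]])
        assert res.p_right == pytest.approx(0.006854, abs=2e-4)
        assert res.odds_ratio == pytest.approx(784 / 190, abs=1e-9)
        assert res.p_two_sided == pytest.approx(0.0137, abs=5e-4)

    def test_symmetric_table(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_small_table_enumeration(self):
        # margins (4,4)/(4,4): 5 tables, two-sided p = 34/70
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.p_two_sided == pytest.approx(34 / 70, abs=1e-12)

    def test_point_probabilities_sum_to_one(self):
        import scipy.stats
        for (N, r1, c1) in [(20, 8, 11), (33, 15, 4), (40, 20, 20)]:
            lo, hi = max(0, r1 + c1 - N), min(r1, c1)
            pmf = scipy.stats.hypergeom.pmf(np.arange(lo, hi + 1), N, r1, c1)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infinite_odds_ratio(self):
        res = fisher_exact([[4, 0], [1, 5]])
        assert math.isinf(res.odds_ratio)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 9), st.integers(0, 9), st.integers(0, 9),
           st.integers(0, 9))
    def test_two_sided_matches_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        res = fisher_exact([[a, b], [c, d]])
        oracle = float(fisher_two_sided_oracle(a, b, c, d))
        assert res.p_two_sided == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.U == 0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(x, x, method="exact")
        assert res.U == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0, abs=0.01)

    def test_exact_vs_normal_agree(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        pe = mann_whitney_u(x, y, method="exact").p_value
        pn = mann_whitney_u(x, y, method="normal").p_value
        assert abs(pe - pn) < 0.02

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=2, max_size=6),
           st.lists(st.integers(0, 6), min_size=2, max_size=6))
    def test_exact_matches_permutation_oracle(self, x, y):
        # ties included: midranks handled exactly by both routes
        res = mann_whitney_u(x, y, method="exact")
        assert res.p_value == pytest.approx(mw_exact_oracle(x, y), abs=1e-9)


# ---------------------------------------------------------------------------
# kymograph correlation
# ---------------------------------------------------------------------------

def _wave_pair(phase):
    s = 0.1 * np.arange(121)
    t = 0.25 * np.arange(96)  # 8 whole periods of Tp = 3, no endpoint dup
    a = wave_field(WaveParams(Tp=3.0, vp=12.0), s, t)
    b = wave_field(WaveParams(Tp=3.0, vp=12.0, phase=phase), s, t)
    return a, b


class TestKymographCorrelation:
    def test_self_and_negated(self):
        a, _ = _wave_pair(0.0)
        neg = a.copy_like(-a.values)
        assert kymograph_correlation(a, a).r == pytest.approx(1.0)
        assert kymograph_correlation(a, neg).r == pytest.approx(-1.0)

    def test_antiphase_is_minus_one(self):
        a, b = _wave_pair(np.pi)
        assert kymograph_correlation(a, b).r == pytest.approx(-1.0, abs=1e-6)

    def test_quadrature_is_zero(self):
        a, b = _wave_pair(np.pi / 2)
        assert abs(kymograph_correlation(a, b).r) < 1e-3

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        s, t = np.arange(12.0), np.arange(30.0)
        va = rng.normal(size=(30, 12))
        vb = rng.normal(size=(30, 12))
        a = KinematicField(s, t, va, np.ones_like(va, bool), "wave")
        b = KinematicField(s, t, vb, np.ones_like(vb, bool), "wave")
        r1 = kymograph_correlation(a, b).r
        r2 = kymograph_correlation(b, a).r
        b2 = b.copy_like(3.0 * vb + 7.0)
        r3 = kymograph_correlation(a, b2).r
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_zero_variance_errors(self):
        a, _ = _wave_pair(0.0)
        flat = a.copy_like(np.zeros_like(a.values))
        with pytest.raises(ValueError):
            kymograph_correlation(a, flat)

    def test_small_joint_support_errors(self):
        a, b = _wave_pair(0.0)
        mask = np.zeros_like(a.mask)
        mask[0, :5] = True
        small = KinematicField(a.s_grid, a.t_grid, a.values, mask, "wave")
        with pytest.raises(ValueError):
            kymograph_correlation(small, b)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

class TestCohortCompare:
    def _table(self, shift=0.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, delta in (("straight", 0.0), ("tilted", shift)):
            for _ in range(n):
                rows.append({"group": grp,
                             "Tp_regr": rng.normal(3.0 + delta, 0.1),
                             "r_coupling": rng.normal(0.0 + delta, 0.05)})
        return pd.DataFrame(rows)

    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(3.0, 0.2, 8)
        df = pd.DataFrame({
            "group": ["straight"] * 8 + ["tilted"] * 8,
            "Tp_regr": np.concatenate([base, base]),
        })
        rep = cohort_compare(df)
        assert (rep["p"] > 0.9).all()

    def test_shifted_groups_detected(self):
        rep = cohort_compare(self._table(shift=1.0, n=8))
        assert (rep["p"] < 0.01).all()

    def test_single_plant_group_errors(self):
        df = self._table(n=4)
        df = df[~((df["group"] == "tilted") & (df.index >= len(df) - 3))]
        with pytest.raises(ValueError):
            cohort_compare(df)
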