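"""Unit and property tests for the statistical primitives.

Every primitive is checked against an independent oracle: a brute-force
re-implementation of its defining formula, an exhaustive enumeration, or the
corresponding scipy/statsmodels routine.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sticomics.stats import (
    bh_adjust,
    clopper_pearson_ci,
    fisher_exact,
    spearman_rho,
    two_sample_t,
    two_sample_t_matrix,
)

# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


def bh_brute_force(p):
    """Direct transcription of the step-up definition:
    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j), capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rank_of = np.empty(m, int)
    rank_of[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / rank_of[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.5], [0.5]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.001, 1.0], [0.002, 1.0]),
    ],
)
def test_bh_hand_computed(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


def test_bh_matches_brute_force_on_random_vectors(rng):
    for _ in range(1000):
        m = int(rng.integers(1, 201))
        p = rng.random(m)
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), rtol=1e-12)


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(50):
        p = rng.random(int(rng.integers(2, 300)))
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_is_order_preserving_and_bounded(p):
    q = bh_adjust(p)
    assert np.all((q >= np.asarray(p) - 1e-15) & (q <= 1.0))
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_adjust([])
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([0.1, np.nan])


# ---------------------------------------------------------------------------
# Clopper–Pearson
# ---------------------------------------------------------------------------


def test_clopper_pearson_study_interval():
    # 75 of 85 tumors better correlated with fallopian tube: 88% (79-94%)
    lo, hi = clopper_pearson_ci(75, 85, 0.95)
    assert round(100 * 75 / 85) == 88
    assert (round(100 * lo), round(100 * hi)) == (79, 94)


def test_clopper_pearson_closed_form_small_n():
    # s=1, n=2: lower = 1 - sqrt(0.975), upper = sqrt(0.975)
    lo, hi = clopper_pearson_ci(1, 2, 0.95)
    assert lo == pytest.approx(1 - math.sqrt(0.975), abs=1e-10)
    assert hi == pytest.approx(math.sqrt(0.975), abs=1e-10)
    assert (round(lo, 4), round(hi, 4)) == (0.0126, 0.9874)


def test_clopper_pearson_boundaries():
    assert clopper_pearson_ci(0, 10)[0] == 0.0
    assert clopper_pearson_ci(10, 10)[1] == 1.0


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for s, n in [(3, 10), (50, 85), (1, 100), (99, 100)]:
        lo, hi = clopper_pearson_ci(s, n, 0.95)
        elo, ehi = proportion_confint(s, n, alpha=0.05, method="beta")
        assert (lo, hi) == pytest.approx((elo, ehi), abs=1e-10)


def test_clopper_pearson_coverage(rng):
    """Empirical coverage >= nominal level (exact interval is conservative)."""
    for p in (0.1, 0.5, 0.9):
        for n in (10, 85):
            draws = rng.binomial(n, p, size=10_000)
            intervals = {s: clopper_pearson_ci(s, n, 0.95) for s in np.unique(draws)}
            covered = np.mean([intervals[s][0] <= p <= intervals[s][1] for s in draws])
            assert covered >= 0.95, (p, n, covered)


def test_clopper_pearson_rejects_bad_input():
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 3)
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 2, 1.0)


# ---------------------------------------------------------------------------
# Fisher's exact (Freeman–Halton)
# ---------------------------------------------------------------------------


def fisher_enumerate_oracle(table):
    """Independent exhaustive oracle: iterate the full cell product space,
    keep tables matching the margins, sum probabilities <= observed."""
    t = np.asarray(table, int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()

    def prob(tab):
        num = sum(math.lgamma(x + 1) for x in rows) + sum(math.lgamma(x + 1) for x in cols)
        den = math.lgamma(n + 1) + sum(math.lgamma(x + 1) for x in tab.ravel())
        return math.exp(num - den)

    p_obs = prob(t)
    total = 0.0
    ranges = [range(min(rows[i], cols[j]) + 1) for i in range(t.shape[0]) for j in range(t.shape[1])]
    for cells in itertools.product(*ranges):
        cand = np.array(cells).reshape(t.shape)
        if np.array_equal(cand.sum(axis=1), rows) and np.array_equal(cand.sum(axis=0), cols):
            p = prob(cand)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return min(total, 1.0)


def test_fisher_hand_examples():
    assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)
    assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)


def test_fisher_zero_row_reduces():
    assert fisher_exact([[2, 0], [0, 0], [0, 2]]) == pytest.approx(
        fisher_exact([[2, 0], [0, 2]])
    )


def test_fisher_extreme_split_two_tail():
    # 10/10 vs 0/10 altered: only the two extreme tables are as improbable
    expected = 2 / math.comb(20, 10)
    assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(expected, rel=1e-9)


def test_fisher_matches_exhaustive_enumeration_small_tables(rng):
    for _ in range(60):
        shape = rng.choice([(2, 2), (2, 3), (3, 2), (3, 3)])
        t = rng.integers(0, 4, size=shape)
        if t.sum() == 0 or t.sum() > 12:
            continue
        if (t.sum(axis=1) > 0).sum() < 2 or (t.sum(axis=0) > 0).sum() < 2:
            continue
        assert fisher_exact(t) == pytest.approx(fisher_enumerate_oracle(t), rel=1e-9), t


def test_fisher_matches_scipy_2x2(rng):
    for _ in range(40):
        t = rng.integers(0, 12, size=(2, 2))
        if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
            continue
        expected = sps.fisher_exact(t, alternative="two-sided")[1]
        assert fisher_exact(t) == pytest.approx(expected, rel=1e-9), t


def test_fisher_p_in_unit_interval(rng):
    for _ in range(30):
        t = rng.integers(0, 8, size=(2, 2)) + 1
        p = fisher_exact(t)
        assert 0 < p <= 1


def test_fisher_enumeration_cap():
    big = [[300, 10], [10, 300]]
    with pytest.raises(ValueError, match="cap"):
        fisher_exact(big)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_spearman_monotone_extremes():
    assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_spearman_ties_average_rank_oracle():
    x, y = [1, 2, 2, 4], [1, 3, 2, 4]
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)
    assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


def test_spearman_matches_scipy_random(rng):
    for _ in range(50):
        n = int(rng.integers(3, 40))
        x = rng.integers(0, 10, n).astype(float)  # integer values force ties
        y = rng.normal(size=n)
        if np.ptp(sps.rankdata(x)) == 0:
            continue
        assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(3, 30), st.integers(0, 2**31 - 1))
def test_spearman_invariant_under_monotone_transform(n, seed):
    r = np.random.default_rng(seed)
    x, y = r.normal(size=n), r.normal(size=n)
    base = spearman_rho(x, y)
    assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
    assert spearman_rho(x, y**3) == pytest.approx(base, abs=1e-12)


def test_spearman_constant_errors():
    with pytest.raises(ValueError):
        spearman_rho([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------


def test_t_identical_groups():
    t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p) == (0.0, pytest.approx(1.0))


def test_t_pooled_closed_form_df2():
    # x=(0,1), y=(2,3): t = -2.828, p = 2*(1/2 + t/(2*sqrt(2+t^2)))
    t, p = two_sample_t([0, 1], [2, 3], variant="pooled")
    assert t == pytest.approx(-2 * math.sqrt(2), rel=1e-9)
    closed = 2 * (0.5 + t / (2 * math.sqrt(2 + t * t)))
    assert p == pytest.approx(closed, rel=1e-9)
    assert p == pytest.approx(0.1056, abs=2e-4)


def test_t_antisymmetric_under_group_swap(rng):
    x, y = rng.normal(size=6), rng.normal(1, 1, size=8)
    for variant in ("pooled", "welch"):
        t1, p1 = two_sample_t(x, y, variant=variant)
        t2, p2 = two_sample_t(y, x, variant=variant)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


@pytest.mark.parametrize("variant,equal_var", [("pooled", True), ("welch", False)])
def test_t_matches_scipy(rng, variant, equal_var):
    for _ in range(30):
        x = rng.normal(size=int(rng.integers(2, 20)))
        y = rng.normal(0.5, 2.0, size=int(rng.integers(2, 20)))
        t, p = two_sample_t(x, y, variant=variant)
        ref = sps.ttest_ind(x, y, equal_var=equal_var)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_t_zero_variance_convention():
    t, p = two_sample_t([1.0, 1.0], [1.0, 1.0])
    assert (t, p) == (0.0, 1.0)


def test_t_matrix_agrees_with_scalar(rng):
    x = rng.normal(size=(5, 4))
    y = rng.normal(size=(5, 6))
    tm, pm = two_sample_t_matrix(x, y, variant="welch")
    for i in range(5):
        t, p = two_sample_t(x[i], y[i], variant="welch")
        assert tm[i] == pytest.approx(t)
        assert pm[i] == pytest.approx(p)


def test_t_rejects_tiny_groups():
    with pytest.raises(ValueError):
        two_sample_t([1.0], [1.0, 2.0])
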