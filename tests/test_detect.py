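"""Rank-based detector: references, Kendall S, exact null, recovery, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmdiff.detect import (
    PeriodGrid,
    TimeSeries,
    bh_adjust,
    build_references,
    concatenate_cycle,
    exact_null_S,
    fisher_combine,
    jtk_test,
    kendall_S,
    lomb_scargle_test,
)

T8 = np.arange(0, 24, 3.0)


def cosine(amp=0.5, phase=6.0, mesor=100.0, t=T8, period=24.0):
    return mesor * (1 + amp * np.cos(2 * np.pi * (t - phase) / period))


class TestPeriodGrid:
    def test_default_periods(self):
        assert list(PeriodGrid(3.0, 20.0, 28.0).periods_h) == [21.0, 24.0, 27.0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            PeriodGrid(3.0, 25.0, 26.0)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            PeriodGrid(0.0, 20.0, 28.0)


class TestReferences:
    def test_lag_count_per_period(self):
        refs = build_references(PeriodGrid(3.0, 20.0, 28.0), T8)
        by_period = {}
        for r in refs:
            by_period.setdefault(r.period_h, []).append(r.lag_h)
        assert len(by_period[24.0]) == 8
        assert len(by_period[21.0]) == 7
        assert len(by_period[27.0]) == 9

    def test_lag0_peaks_at_t0(self):
        refs = build_references(PeriodGrid(3.0, 24.0, 24.0), T8)
        lag0 = next(r for r in refs if r.lag_h == 0.0)
        assert np.argmax(lag0.ranks) == 0


class TestKendallS:
    def test_perfect_concordance(self):
        s, tau = kendall_S([1, 2, 3, 4], [1, 2, 3, 4])
        assert (s, tau) == (6, 1.0)

    def test_antisymmetry(self):
        s, tau = kendall_S([4, 3, 2, 1], [1, 2, 3, 4])
        assert (s, tau) == (-6, -1.0)

    def test_hand_counted_pairs(self):
        s, _ = kendall_S([1, 3, 2], [1, 2, 3])
        assert s == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_S([1, 2], [1, 2, 3])


def brute_force_two_sided(ref_ranks, s_obs):
    """Exhaustive-permutation two-sided tail P(|S| >= |s_obs|)."""
    n = len(ref_ranks)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        s, _ = kendall_S(np.asarray(perm, dtype=float), ref_ranks)
        hits += abs(s) >= abs(s_obs)
        total += 1
    return hits / total


class TestExactNull:
    def test_n3_tie_free(self):
        support, pmf = exact_null_S(3)
        table = dict(zip(support.tolist(), pmf.tolist()))
        assert table[3] == pytest.approx(1 / 6)
        assert table[-3] == pytest.approx(1 / 6)
        assert table[1] == pytest.approx(2 / 6)
        assert table[-1] == pytest.approx(2 / 6)

    @pytest.mark.parametrize("ties", [(1, 1, 1, 1, 1), (2, 3), (1, 2, 2), (1, 1, 4)])
    def test_symmetry_and_normalisation(self, ties):
        support, pmf = exact_null_S(sum(ties), ties)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        table = dict(zip(support.tolist(), pmf.tolist()))
        for s, p in table.items():
            assert p == pytest.approx(table[-s], abs=1e-15)

    def test_matches_exhaustive_enumeration(self):
        ref = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        from scipy.stats import rankdata

        ranks = rankdata(ref)
        support, pmf = exact_null_S(6, (2, 1, 2, 1))
        for s_obs in support[support >= 0]:
            tail = pmf[np.abs(support) >= s_obs].sum()
            assert tail == pytest.approx(brute_force_two_sided(ranks, s_obs), abs=1e-12)

    def test_too_many_points_rejected(self):
        with pytest.raises(ValueError):
            exact_null_S(26)


class TestJtk:
    def test_noiseless_recovery_concatenated(self):
        series = concatenate_cycle(TimeSeries(T8, cosine()), 2)
        res = jtk_test(series)
        assert res.period_h == 24.0
        assert res.lag_h == 6.0
        assert res.adj_p < 0.001
        assert res.tau == pytest.approx(1.0)

    @pytest.mark.parametrize("lag", list(range(0, 24, 3)))
    def test_all_ongrid_lags_recovered(self, lag):
        series = concatenate_cycle(TimeSeries(T8, cosine(phase=lag)), 2)
        assert jtk_test(series).lag_h == lag

    def test_constant_series_flagged(self):
        res = jtk_test(TimeSeries(T8, np.full(8, 7.0)))
        assert res.adj_p == 1.0
        assert res.constant
        assert np.isnan(res.lag_h)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.lognormal(4, 0.5, 8)
        base = jtk_test(TimeSeries(T8, y))
        for transform in (lambda v: 3.7 * v, lambda v: v**2, lambda v: np.exp(v / v.max())):
            res = jtk_test(TimeSeries(T8, transform(y)))
            assert res.p == pytest.approx(base.p, abs=1e-14)
            assert res.lag_h == base.lag_h
            assert res.period_h == base.period_h

    def test_concatenation_keeps_lag_and_shrinks_p(self):
        single = TimeSeries(T8, cosine(phase=15.0))
        res1 = jtk_test(single)
        res2 = jtk_test(concatenate_cycle(single, 2))
        assert res2.lag_h == res1.lag_h == 15.0
        assert res2.p <= res1.p

    def test_concat_validation(self):
        with pytest.raises(ValueError):
            concatenate_cycle(TimeSeries(T8, cosine()), 0)
        long_series = TimeSeries(np.arange(0, 48, 3.0), np.tile(cosine(), 2))
        with pytest.raises(ValueError):
            concatenate_cycle(long_series, 2)


class TestBhAdjust:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identities(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestFisher:
    def test_closed_forms(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        # X² = −4·ln 0.05 = 11.98; χ²₄ tail = (1 + x/2)·e^{−x/2} = 0.017479
        x = -4 * np.log(0.05)
        closed_form = (1 + x / 2) * np.exp(-x / 2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(closed_form, rel=1e-9)
        assert fisher_combine([0.2]) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])


class TestLombScargle:
    def test_noiseless_cosine_significant(self):
        assert lomb_scargle_test(TimeSeries(T8, cosine())) < 0.01

    def test_constant_series(self):
        assert lomb_scargle_test(TimeSeries(T8, np.full(8, 5.0))) == 1.0

    def test_uniform_under_gaussian_noise(self):
        # single-period grid: the R²-based tail is exact for Gaussian noise
        grid = PeriodGrid(3.0, 23.0, 25.0)
        rng = np.random.default_rng(0)
        ps = [
            lomb_scargle_test(TimeSeries(T8, 100 + rng.normal(0, 5, 8)), grid)
            for _ in range(5000)
        ]
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.floats(1.0, 1e4), min_size=6, max_size=6),
    st.floats(0.1, 10.0),
)
def test_scaling_never_changes_rank_statistics(values, scale):
    """Property: the detector depends on data only through ranks."""
    v = np.asarray(values)
    if len(np.unique(v)) < 2:
        return
    a = jtk_test(TimeSeries(np.arange(0, 18, 3.0), v))
    b = jtk_test(TimeSeries(np.arange(0, 18, 3.0), v * scale))
    assert a.p == b.p
    assert (np.isnan(a.lag_h) and np.isnan(b.lag_h)) or a.lag_h == b.lag_h
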