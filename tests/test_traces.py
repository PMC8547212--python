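"""Trace processing: rebinning, moments, Mandel Q, empirical mSMR curve."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msmr import (PhotonTrace, average_curves, bin_timestamps, integer_divisors,
                  mandel_q, msmr_curve, raw_moments, rebin)
from msmr.errors import (ConfigError, InsufficientDataError, ProcessingError,
                         UndefinedQError)


def brute_divisors(n):
    return [d for d in range(1, n + 1) if n % d == 0]


class TestIntegerDivisors:
    @pytest.mark.parametrize("n,expected", [
        (12, [1, 2, 3, 4, 6, 12]),
        (1, [1]),
        (7, [1, 7]),
    ])
    def test_known_values(self, n, expected):
        assert integer_divisors(n).tolist() == expected

    def test_360_against_brute_force(self):
        d = integer_divisors(360)
        assert d.tolist() == brute_divisors(360)
        assert len(d) == 24
        assert all(360 % x == 0 and (360 // x) in d for x in d)

    @given(st.integers(1, 5000))
    def test_matches_trial_division(self, n):
        assert integer_divisors(n).tolist() == brute_divisors(n)

    def test_invalid(self):
        with pytest.raises(ConfigError):
            integer_divisors(0)


class TestRebin:
    def test_pairwise(self):
        t = rebin(PhotonTrace([1, 2, 3, 4], 1.0), 2)
        assert t.counts.tolist() == [3, 7]
        assert t.bin_width == 2.0

    def test_triplet(self):
        assert rebin(PhotonTrace([1, 2, 3, 4, 5, 6], 1.0), 3).counts.tolist() == [6, 15]

    def test_identity(self):
        t = PhotonTrace([5, 0, 2], 1e-6)
        assert rebin(t, 1) is t

    def test_non_divisor_rejected(self):
        with pytest.raises(ProcessingError):
            rebin(PhotonTrace([1, 2, 3], 1.0), 2)

    @given(st.lists(st.integers(0, 50), min_size=12, max_size=12),
           st.sampled_from([1, 2, 3, 4, 6, 12]))
    def test_counts_conserved(self, counts, factor):
        t = PhotonTrace(counts, 1e-6)
        assert rebin(t, factor).counts.sum() == sum(counts)

    @given(st.lists(st.integers(0, 20), min_size=24, max_size=24))
    def test_composition(self, counts):
        t = PhotonTrace(counts, 1e-6)
        ab = rebin(rebin(t, 2), 3)
        direct = rebin(t, 6)
        assert ab.counts.tolist() == direct.counts.tolist()
        assert ab.bin_width == direct.bin_width


class TestRawMoments:
    def test_worked_example(self):
        m1, m2, m3 = raw_moments(PhotonTrace([2, 0, 1, 3], 1.0))
        assert (m1, m2, m3) == (1.5, 3.5, 9.0)

    def test_all_zero(self):
        assert raw_moments(PhotonTrace([0, 0, 0], 1.0)) == (0.0, 0.0, 0.0)

    @given(st.integers(1, 9), st.integers(2, 30))
    def test_constant_trace(self, c, n):
        assert raw_moments(PhotonTrace([c] * n, 1.0)) == (c, c**2, c**3)

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=200))
    def test_matches_naive_python(self, counts):
        m = raw_moments(PhotonTrace(counts, 1.0))
        n = len(counts)
        expected = tuple(sum(c**j for c in counts) / n for j in (1, 2, 3))
        assert m == pytest.approx(expected, rel=1e-14)

    def test_large_counts_exact(self):
        # <k^3> sums that would overflow int32 and lose bits in float32
        counts = [10**5, 10**5 + 1] * 10
        m1, m2, m3 = raw_moments(PhotonTrace(counts, 1.0))
        assert m3 == (10**15 + (10**5 + 1) ** 3) / 2


class TestMandelQ:
    def test_worked_example(self):
        assert mandel_q(1.5, 3.5) == pytest.approx(-1 / 6, abs=1e-7)

    def test_constant_trace_is_minus_one(self):
        m1, m2, _ = raw_moments(PhotonTrace([5] * 100, 1.0))
        assert mandel_q(m1, m2) == -1.0

    def test_poisson_null(self, rng):
        n = 200_000
        counts = rng.poisson(3.0, n)
        m1, m2, _ = raw_moments(PhotonTrace(counts, 1.0))
        assert abs(mandel_q(m1, m2)) < 3 * np.sqrt(2 / n)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedQError):
            mandel_q(0.0, 0.0)


class TestMSMRCurve:
    def test_worked_example_arithmetic(self):
        # trace [2,0,1,3] at 1 s bins: mu(1) = -1/6, mu(2) = -1/3
        t = PhotonTrace([2, 0, 1, 3], 1.0)
        m1, m2, _ = raw_moments(t)
        assert mandel_q(m1, m2) / 1.0 == pytest.approx(-0.16667, abs=1e-4)
        t2 = rebin(t, 2)
        m1, m2, _ = raw_moments(t2)
        assert mandel_q(m1, m2) == pytest.approx(-2 / 3, abs=1e-9)
        assert mandel_q(m1, m2) / 2.0 == pytest.approx(-1 / 3, abs=1e-9)

    def test_curve_matches_bruteforce_reshaping_oracle(self, rng):
        counts = rng.poisson(2.0, 720)
        trace = PhotonTrace(counts, 1e-3)
        curve = msmr_curve(trace, t_max_fraction=1.0, min_points=1)
        for T, Q, n_bins in zip(curve.T, curve.Q, curve.n_bins):
            d = int(round(T / trace.bin_width))
            # explicit-loop oracle
            sums = [sum(counts[i * d:(i + 1) * d]) for i in range(len(counts) // d)]
            m1 = sum(sums) / len(sums)
            m2 = sum(s * s for s in sums) / len(sums)
            assert n_bins == len(sums)
            assert Q == pytest.approx((m2 - m1 * m1 - m1) / m1, rel=1e-12)

    def test_poisson_trace_mu_consistent_with_zero(self, rng):
        n = 60_000
        trace = PhotonTrace(rng.poisson(1.5, n), 1e-6)
        curve = msmr_curve(trace)
        assert np.all(curve.n_bins >= 100)
        limit = 5 * np.sqrt(2 / curve.n_bins)
        assert np.all(np.abs(curve.Q) < limit)

    def test_default_t_max_keeps_100_bins(self, rng):
        trace = PhotonTrace(rng.poisson(1.0, 10_000), 1e-6)
        curve = msmr_curve(trace)
        assert curve.T.max() <= trace.duration / 100
        assert np.all(curve.n_bins >= 100)

    def test_sampling_times_are_divisor_grid(self, rng):
        trace = PhotonTrace(rng.poisson(1.0, 7200), 1e-6)
        curve = msmr_curve(trace)
        ratios = curve.T / trace.bin_width
        assert np.allclose(ratios, np.round(ratios))
        assert np.all(np.diff(curve.T) > 0)
        assert np.all(curve.n_bins * np.round(ratios) == len(trace))

    def test_mu_is_q_over_t(self, rng):
        trace = PhotonTrace(rng.poisson(2.0, 7200), 1e-6)
        curve = msmr_curve(trace)
        assert np.allclose(curve.mu, curve.Q / curve.T, rtol=1e-14)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            msmr_curve(PhotonTrace([1, 2, 1, 2], 1.0), t_max_fraction=1.0)

    def test_zero_mean_entries_dropped(self, rng):
        # all-zero trace: every sampling time has m1 = 0
        with pytest.raises(InsufficientDataError):
            msmr_curve(PhotonTrace([0] * 7200, 1e-6), t_max_fraction=1.0)


class TestBinTimestamps:
    def test_half_open_binning(self):
        trace = bin_timestamps([0.0, 0.5, 0.999, 1.0, 2.5], 1.0, duration=3.0)
        assert trace.counts.tolist() == [3, 1, 1]

    def test_events_at_end_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping 1 events"):
            trace = bin_timestamps([0.1, 3.0], 1.0, duration=3.0)
        assert trace.counts.tolist() == [1, 0, 0]

    def test_unsorted_rejected(self):
        with pytest.raises(ProcessingError):
            bin_timestamps([1.0, 0.5], 1.0)


class TestAverageCurves:
    def test_average_of_identical_is_identity(self, rng):
        trace = PhotonTrace(rng.poisson(2.0, 7200), 1e-6)
        c = msmr_curve(trace)
        avg = average_curves([c, c])
        assert np.allclose(avg.mu, c.mu)
        assert np.all(avg.n_bins == 2 * c.n_bins)

    def test_mismatched_grids_rejected(self, rng):
        c1 = msmr_curve(PhotonTrace(rng.poisson(2.0, 7200), 1e-6))
        c2 = msmr_curve(PhotonTrace(rng.poisson(2.0, 6000), 1e-6))
        with pytest.raises(ProcessingError):
            average_curves([c1, c2])
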