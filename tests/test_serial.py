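import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isimodels import (
    ISISequence,
    SpikeTrain,
    detect_sequences,
    fano_factor,
    make_poisson_train,
    recurrence_matrix,
    serial_correlation,
    shuffle_isis,
)


def src_bruteforce(x, lag):
    x = np.asarray(x, float)
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    prods = [(x[k + lag] - mu) * (x[k] - mu) for k in range(x.size - lag)]
    return float(np.mean(prods) / var)


class TestSerialCorrelation:
    def test_alternating_is_fully_negative(self):
        x = np.tile([1.0, 3.0], 500)
        sc = serial_correlation(ISISequence(x), 1)
        # every cross-product equals -Var(ISI)
        assert sc.src == pytest.approx(-1.0, abs=1e-12)
        assert sc.p_value < 1e-10

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(14)
        x = rng.gamma(2.0, 10.0, size=400)
        for lag in (1, 2, 5, 17):
            sc = serial_correlation(ISISequence(x), lag)
            assert sc.src == pytest.approx(src_bruteforce(x, lag), abs=1e-12)

    def test_iid_within_null_band(self):
        rng = np.random.default_rng(15)
        x = rng.exponential(30.0, size=2000)
        sc = serial_correlation(ISISequence(x), 1)
        assert abs(sc.src) < 2 / math.sqrt(2000)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            serial_correlation(ISISequence([2.0] * 50), 1)

    def test_shuffling_kills_correlation(self):
        # strongly positively correlated sequence; shuffling sends SRC(1)
        # into the null band around zero
        rng = np.random.default_rng(16)
        blocks = [rng.exponential(m, size=50) for m in rng.choice([5.0, 80.0], 40)]
        x = np.concatenate(blocks)
        isis = ISISequence(x)
        assert serial_correlation(isis, 1).src > 0.1
        shuffled = shuffle_isis(isis, seed=3)
        assert abs(serial_correlation(shuffled, 1).src) < 2 / math.sqrt(x.size)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_shuffle_preserves_multiset(self, seed):
        rng = np.random.default_rng(17)
        x = rng.exponential(10.0, size=100)
        isis = ISISequence(x)
        sh = shuffle_isis(isis, seed)
        assert np.allclose(np.sort(sh.isis), np.sort(x))
        assert np.mean(sh.isis) == pytest.approx(np.mean(x))


class TestRecurrenceMatrix:
    def test_iid_near_uniform(self):
        rng = np.random.default_rng(1)
        q = recurrence_matrix(ISISequence(rng.exponential(50.0, 20000))).q
        assert np.all(np.abs(q - 1 / 16) < 0.01)

    def test_normalization_and_margins(self):
        rng = np.random.default_rng(19)
        q = recurrence_matrix(ISISequence(rng.gamma(3.0, 5.0, 5000))).q
        assert q.sum() == pytest.approx(1.0)
        assert np.all(np.abs(q.sum(axis=0) - 0.25) < 0.03)
        assert np.all(np.abs(q.sum(axis=1) - 0.25) < 0.03)

    def test_sorted_sequence_stays_near_diagonal(self):
        # strictly ascending ISIs can only move within a quartile or to the
        # next one; enumeration on a small instance
        x = np.arange(1.0, 41.0)
        q = recurrence_matrix(ISISequence(x)).q
        for i in range(4):
            for j in range(4):
                if j not in (i, i + 1):
                    assert q[i, j] == 0.0

    def test_heavy_ties_rejected(self):
        x = np.concatenate([np.full(50, 5.0), [1.0, 9.0]])
        with pytest.raises(ValueError, match="degenerate quartiles"):
            recurrence_matrix(ISISequence(x))


class TestSequences:
    def test_separated_blocks(self):
        isis = ISISequence([1.0, 1.0, 1.0, 9.0, 9.0, 9.0, 1.0, 9.0, 1.0, 9.0])
        part = detect_sequences(isis)
        assert (0, 2, "short") in part.runs
        assert (3, 5, "long") in part.runs
        assert part.mu_short == pytest.approx(1.0)
        assert part.mu_long == pytest.approx(9.0)

    def test_time_rescale_invariance(self):
        rng = np.random.default_rng(23)
        x = rng.exponential(20.0, 500)
        a = detect_sequences(ISISequence(x))
        b = detect_sequences(ISISequence(x * 1000.0))
        assert a.runs == b.runs
        assert a.frac_in_short == b.frac_in_short

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            detect_sequences(ISISequence([3.0] * 20))

    def test_switching_data_richer_in_sequences_than_iid(self):
        from isimodels import SwitchingParams, simulate_switching

        params = SwitchingParams.from_p_fast(
            k_sf=1e-4, p_fast=0.5, tau_fast=20.0, tau_slow=200.0
        )
        sw_frac, iid_frac = [], []
        for seed in range(5):
            trace = simulate_switching(params, 2000, seed, record_switches=False)
            p_sw = detect_sequences(trace.isis)
            sw_frac.append(p_sw.frac_in_short + p_sw.frac_in_long)
            sh = shuffle_isis(trace.isis, seed=seed + 100)
            p_sh = detect_sequences(sh)
            iid_frac.append(p_sh.frac_in_short + p_sh.frac_in_long)
        assert np.median(sw_frac) > np.median(iid_frac)


class TestFano:
    def test_periodic_train_zero_variance(self):
        train = SpikeTrain(np.arange(0.0, 30000.0, 10.0))
        fc = fano_factor(train, [100.0])
        assert fc.F[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_near_one(self):
        train = make_poisson_train(0.02, 200_000.0, seed=2)
        fc = fano_factor(train, [10.0, 100.0])
        assert np.all(np.abs(fc.F - 1.0) < 0.1)

    def test_window_longer_than_tenth_of_recording_rejected(self):
        train = make_poisson_train(0.05, 5000.0, seed=3)
        with pytest.raises(ValueError):
            fano_factor(train, [1000.0])

    def test_switching_timescale_separation_raises_fano(self):
        # larger tau_slow/tau_fast ratio gives uniformly larger F(dt) for
        # windows spanning several ISIs
        from isimodels import SwitchingParams, simulate_switching

        curves = {}
        for tau_slow in (80.0, 160.0):
            params = SwitchingParams.from_p_fast(
                k_sf=1e-4, p_fast=0.4, tau_fast=40.0, tau_slow=tau_slow
            )
            F = []
            for seed in range(3):
                trace = simulate_switching(params, 4000, seed, record_switches=False)
                train = trace.isis.to_spike_train()
                F.append(fano_factor(train, [100.0, 300.0, 1000.0]).F)
            curves[tau_slow] = np.mean(F, axis=0)
        assert np.all(curves[160.0] > curves[80.0])
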