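import math

import numpy as np
import pytest
from scipy import stats

from isimodels import (
    ExpExcitation,
    RefractoryParams,
    RenewalModel,
    SwitchingParams,
    TwoStateSwitchingModel,
    equivalent_mixture,
    serial_correlation,
    simulate_switching,
    src_sweep,
)
from isimodels.switching import simulate_switching_per_interval


class TestParams:
    def test_p_fast(self):
        p = SwitchingParams(k_sf=1e-4, k_fs=1e-4)
        assert p.p_fast == pytest.approx(0.5)

    def test_from_p_fast(self):
        p = SwitchingParams.from_p_fast(k_sf=1e-3, p_fast=0.6)
        assert p.p_fast == pytest.approx(0.6)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            SwitchingParams(k_sf=1e-4, k_fs=1e-4, tau_fast=300.0, tau_slow=200.0)

    def test_no_switching_needs_initial_state(self):
        p = SwitchingParams(k_sf=0.0, k_fs=0.0)
        with pytest.raises(ValueError):
            simulate_switching(p, 10, seed=0)


class TestMapping:
    def test_equivalent_mixture_values(self):
        p = SwitchingParams.from_p_fast(
            k_sf=1e-4, p_fast=0.6, tau_fast=40.0, tau_slow=200.0
        )
        mix = equivalent_mixture(p)
        assert mix.p == pytest.approx(0.6)
        assert mix.lambda_e1 == pytest.approx(0.025)
        assert mix.lambda_e2 == pytest.approx(0.005)

    def test_equal_taus_collapse_to_single_rate(self):
        p = SwitchingParams(k_sf=1e-4, k_fs=1e-4, tau_fast=50.0, tau_slow=50.0)
        mix = equivalent_mixture(p)
        assert mix.lambda_e1 == mix.lambda_e2 == pytest.approx(0.02)

    def test_per_interval_marginal_matches_mapped_renewal(self):
        p = SwitchingParams.from_p_fast(
            k_sf=1e-4, p_fast=0.6, tau_fast=40.0, tau_slow=200.0
        )
        trace = simulate_switching_per_interval(p, 20000, seed=3)
        model = TwoStateSwitchingModel(p).equivalent_renewal()
        ks = stats.kstest(trace.isis.isis, lambda t: model.cdf(t))
        assert ks.pvalue > 0.01


class TestSimulation:
    def test_no_switching_is_case_i_renewal(self):
        p = SwitchingParams(k_sf=0.0, k_fs=1e-12, tau_fast=40.0, tau_slow=200.0)
        trace = simulate_switching(
            p, 20000, seed=3, init_state="slow", record_switches=False
        )
        ref = RenewalModel(RefractoryParams(2.0, 2.0), ExpExcitation(1 / 200.0))
        assert stats.kstest(trace.isis.isis, lambda t: ref.cdf(t)).pvalue > 0.01

    def test_equal_taus_give_null_src(self):
        p = SwitchingParams(k_sf=1e-4, k_fs=1e-4, tau_fast=100.0, tau_slow=100.0)
        srcs = [
            serial_correlation(
                simulate_switching(p, 2000, s, record_switches=False).isis, 1
            ).src
            for s in range(10)
        ]
        assert abs(np.median(srcs)) < 2 / math.sqrt(2000)

    def test_seed_reproducible(self):
        p = SwitchingParams.from_p_fast(k_sf=1e-3, p_fast=0.5)
        a = simulate_switching(p, 200, seed=5)
        b = simulate_switching(p, 200, seed=5)
        assert np.array_equal(a.isis.isis, b.isis.isis)
        assert np.array_equal(a.state_at_spike, b.state_at_spike)

    def test_spike_weighted_occupancy_with_equal_taus(self):
        # with equal release rates in both modes, spikes sample the modes
        # in proportion to time, i.e. p_fast
        p = SwitchingParams.from_p_fast(
            k_sf=2e-4, p_fast=0.3, tau_fast=50.0, tau_slow=50.0
        )
        trace = simulate_switching(p, 30000, seed=8, record_switches=False)
        frac_fast = np.mean(trace.state_at_spike == "fast")
        assert frac_fast == pytest.approx(0.3, abs=0.03)

    def test_mean_isi_bracketed_by_mode_means(self):
        p = SwitchingParams.from_p_fast(
            k_sf=1e-4, p_fast=0.6, tau_fast=40.0, tau_slow=200.0
        )
        trace = simulate_switching(p, 20000, seed=9, record_switches=False)
        m = np.mean(trace.isis.isis)
        assert 40.0 + 4.0 < m < 200.0 + 4.0

    def test_switch_holding_times_exponential(self):
        p = SwitchingParams(k_sf=5e-3, k_fs=5e-3, tau_fast=40.0, tau_slow=200.0)
        trace = simulate_switching(p, 5000, seed=10, record_switches=True)
        holds = np.diff(trace.switch_times)
        assert stats.kstest(holds, "expon", args=(0, 1 / 5e-3)).pvalue > 0.01


class TestParameterDependence:
    def test_src_positive_and_decreasing_in_switch_rate(self):
        med = {}
        for k_sf in (1e-4, 1e-3, 1e-2):
            p = SwitchingParams.from_p_fast(
                k_sf=k_sf, p_fast=0.6, tau_fast=40.0, tau_slow=200.0
            )
            srcs = [
                serial_correlation(
                    simulate_switching(p, 5000, s, record_switches=False).isis, 1
                ).src
                for s in range(10)
            ]
            med[k_sf] = np.median(srcs)
        assert med[1e-4] > med[1e-3] > med[1e-2]
        assert med[1e-4] > 0.1

    def test_src_increases_as_timescales_separate(self):
        med = {}
        for tau_fast in (180.0, 100.0, 40.0):
            p = SwitchingParams.from_p_fast(
                k_sf=1e-4, p_fast=0.6, tau_fast=tau_fast, tau_slow=200.0
            )
            srcs = [
                serial_correlation(
                    simulate_switching(p, 5000, s, record_switches=False).isis, 1
                ).src
                for s in range(10)
            ]
            med[tau_fast] = np.median(srcs)
        assert med[40.0] > med[100.0] > med[180.0]

    def test_src_vanishes_at_p_fast_extremes(self):
        meds = {}
        for pf in (0.02, 0.5, 0.98):
            p = SwitchingParams.from_p_fast(
                k_sf=1e-4, p_fast=pf, tau_fast=40.0, tau_slow=200.0
            )
            srcs = [
                serial_correlation(
                    simulate_switching(p, 5000, s, record_switches=False).isis, 1
                ).src
                for s in range(10)
            ]
            meds[pf] = np.median(srcs)
        assert meds[0.5] > meds[0.02]
        assert meds[0.5] > meds[0.98]

    def test_src_decays_with_lag_and_stays_nonnegative(self):
        df = src_sweep(
            [SwitchingParams.from_p_fast(k_sf=1e-4, p_fast=0.4,
                                         tau_fast=40.0, tau_slow=200.0)],
            n_trials=10,
            n_isis=2000,
            lags=(1, 5, 10, 50),
            seed=0,
        )
        means = df.groupby("lag")["src"].mean()
        assert means[1] > means[50]
        assert (means > -0.02).all()

    def test_slower_switching_decays_more_gradually(self):
        decay = {}
        for k_sf in (1e-4, 1e-3):
            df = src_sweep(
                [SwitchingParams.from_p_fast(k_sf=k_sf, p_fast=0.4,
                                             tau_fast=40.0, tau_slow=200.0)],
                n_trials=10,
                n_isis=2000,
                lags=(1, 10),
                seed=1,
            )
            means = df.groupby("lag")["src"].mean()
            decay[k_sf] = means[10] / means[1]
        assert decay[1e-4] > decay[1e-3]
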