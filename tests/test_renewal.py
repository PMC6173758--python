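import math

import numpy as np
import pytest
from scipy import integrate, stats

from isimodels import (
    ExpExcitation,
    GammaMixExcitation,
    RefractoryParams,
    RenewalModel,
    TwoExpMixExcitation,
    excitation_pdf,
    isi_cdf,
    isi_pdf,
    refractory_pdf,
    sample_isis,
)


def quad_convolution_oracle(model, t):
    """Independent numerical evaluation of the refractory*excitation
    convolution, straight from its integral definition."""
    refr = model.refractory
    lam_r = 1.0 / refr.tau_rel

    def f_r(u):
        return lam_r * math.exp(-lam_r * (u - refr.t_abs)) if u >= refr.t_abs else 0.0

    val, _ = integrate.quad(
        lambda u: f_r(u) * float(model.excitation.pdf(t - u)),
        refr.t_abs,
        t,
        epsabs=1e-13,
        epsrel=1e-11,
        limit=300,
    )
    return val


PARAM_GRID = [
    RenewalModel(RefractoryParams(2.0, 2.0), ExpExcitation(0.1)),
    RenewalModel(RefractoryParams(0.5, 8.0), ExpExcitation(0.02)),
    RenewalModel(RefractoryParams(2.0, 2.0), GammaMixExcitation(0.7, 0.05, 2.5)),
    RenewalModel(RefractoryParams(1.0, 3.0), GammaMixExcitation(0.2, 0.08, 1.3)),
    RenewalModel(RefractoryParams(2.0, 2.0), TwoExpMixExcitation(0.6, 0.025, 0.005)),
    RenewalModel(RefractoryParams(0.0, 1.0), TwoExpMixExcitation(0.3, 0.5, 0.01)),
]


class TestExcitation:
    def test_exp_at_zero(self):
        assert excitation_pdf(ExpExcitation(0.5), 0.0) == pytest.approx(0.5)

    def test_gamma_mix_n1_reduces_to_exp(self):
        t = np.linspace(0, 100, 200)
        g = GammaMixExcitation(p=0.3, lambda_e=0.1, n=1.0)
        e = ExpExcitation(0.1)
        assert np.allclose(g.pdf(t), e.pdf(t), atol=1e-14)
        assert np.allclose(g.cdf(t), e.cdf(t), atol=1e-12)

    def test_two_exp_equal_rates_collapse(self):
        t = np.linspace(0, 100, 200)
        m = TwoExpMixExcitation(p=0.5, lambda_e1=0.2, lambda_e2=0.2)
        assert np.allclose(m.pdf(t), ExpExcitation(0.2).pdf(t))

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            ExpExcitation(0.5).pdf(-1.0)

    def test_rate_order_enforced(self):
        with pytest.raises(ValueError):
            TwoExpMixExcitation(p=0.5, lambda_e1=0.01, lambda_e2=0.5)


class TestRefractory:
    def test_support(self):
        r = RefractoryParams(t_abs=2.0, tau_rel=2.0)
        assert refractory_pdf(r, 1.0) == 0.0
        assert refractory_pdf(r, 2.0) == pytest.approx(0.5)

    def test_normalization(self):
        r = RefractoryParams(t_abs=3.0, tau_rel=5.0)
        val, _ = integrate.quad(lambda t: float(refractory_pdf(r, t)), 0, 300)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_has_no_density(self):
        with pytest.raises(ValueError):
            refractory_pdf(RefractoryParams(2.0, 0.0), 2.0)


class TestISIDistribution:
    @pytest.mark.parametrize("model", PARAM_GRID)
    def test_zero_inside_refractory(self, model):
        t_abs = model.refractory.t_abs
        assert isi_pdf(model, t_abs / 2) == 0.0
        assert isi_pdf(model, t_abs) == 0.0
        assert isi_cdf(model, t_abs) == 0.0

    @pytest.mark.parametrize("model", PARAM_GRID)
    def test_matches_quadrature_oracle(self, model):
        for t in [model.refractory.t_abs + 0.3, 5.0, 25.0, 120.0]:
            if t <= model.refractory.t_abs:
                continue
            assert isi_pdf(model, t) == pytest.approx(
                quad_convolution_oracle(model, t), rel=1e-8, abs=1e-12
            )

    @pytest.mark.parametrize("model", PARAM_GRID)
    def test_pdf_normalization(self, model):
        val, _ = integrate.quad(
            lambda t: float(model.pdf(t)), model.refractory.t_abs, 6000, limit=500
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("model", PARAM_GRID)
    def test_cdf_monotone_and_consistent(self, model):
        t = np.linspace(0, 600, 400)
        F = model.cdf(t)
        assert np.all(np.diff(F) >= -1e-12)
        # CDF equals the integral of the pdf
        mid = 30.0
        val, _ = integrate.quad(
            lambda u: float(model.pdf(u)), model.refractory.t_abs, mid, limit=300
        )
        assert model.cdf(mid) == pytest.approx(val, abs=1e-8)

    def test_coincident_rates_branch(self):
        # lambda_R == lambda_E hits the removable singularity
        m = RenewalModel(RefractoryParams(2.0, 10.0), ExpExcitation(0.1))
        for t in [3.0, 12.0, 60.0]:
            assert m.pdf(t) == pytest.approx(
                quad_convolution_oracle(m, t), rel=1e-8
            )

    def test_no_relative_refractory_limit(self):
        # tau_rel = 0: the convolution collapses to a shifted excitation
        m = RenewalModel(RefractoryParams(2.0, 0.0), ExpExcitation(0.1))
        t = np.array([2.5, 10.0, 40.0])
        assert np.allclose(m.pdf(t), 0.1 * np.exp(-0.1 * (t - 2.0)))

    def test_case_ii_n1_equals_case_i(self):
        m2 = RenewalModel(RefractoryParams(2.0, 2.0), GammaMixExcitation(0.3, 0.1, 1.0))
        m1 = RenewalModel(RefractoryParams(2.0, 2.0), ExpExcitation(0.1))
        t = np.linspace(0, 150, 300)
        assert np.allclose(m2.pdf(t), m1.pdf(t), atol=1e-12)
        assert np.allclose(m2.cdf(t), m1.cdf(t), atol=1e-10)

    def test_case_iii_equal_rates_equals_case_i(self):
        m3 = RenewalModel(
            RefractoryParams(2.0, 2.0), TwoExpMixExcitation(0.4, 0.05, 0.05)
        )
        m1 = RenewalModel(RefractoryParams(2.0, 2.0), ExpExcitation(0.05))
        t = np.linspace(0, 300, 300)
        assert np.allclose(m3.pdf(t), m1.pdf(t), atol=1e-13)


class TestSampling:
    def test_mean_additivity(self, case_i_model):
        x = sample_isis(case_i_model, 100_000, seed=2)
        # E[ISI] = t_abs + tau_rel + 1/lambda_E = 2 + 2 + 20 = 24
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - 24.0) < 4 * se

    @pytest.mark.parametrize("model", PARAM_GRID)
    def test_support_and_ks(self, model):
        x = sample_isis(model, 20_000, seed=7)
        assert x.min() >= model.refractory.t_abs
        p = stats.kstest(x, lambda t: model.cdf(t)).pvalue
        assert p > 0.01

    def test_seed_reproducible(self, case_iii_model):
        a = sample_isis(case_iii_model, 100, seed=9)
        b = sample_isis(case_iii_model, 100, seed=9)
        assert np.array_equal(a, b)


class TestSerialization:
    @pytest.mark.parametrize("model", PARAM_GRID)
    def test_dict_round_trip(self, model):
        back = RenewalModel.from_dict(model.to_dict())
        assert back == model
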