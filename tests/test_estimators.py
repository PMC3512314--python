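"""Work averages, Jarzynski estimator, bootstrap, corrections, affinity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pullwork as pw
from pullwork.errors import PullworkError, ValidationError


def sample(works, kBT=1.0):
    return pw.WorkSample(works=np.asarray(works, dtype=float),
                         temperature_T=kBT)


works_strategy = st.lists(
    st.floats(-50.0, 50.0, allow_nan=False), min_size=2, max_size=40)


class TestAverages:
    def test_arithmetic_mean(self):
        wa, se = pw.average_work(sample([1.0, 2.0, 3.0]))
        assert wa == 2.0
        assert se == pytest.approx(1.0 / np.sqrt(3.0))

    def test_single_measurement_warns_zero_se(self):
        with pytest.warns(UserWarning, match="single-measurement"):
            wa, se = pw.average_work(sample([5.0]))
        assert (wa, se) == (5.0, 0.0)

    def test_jarzynski_two_value_arithmetic(self):
        # -ln[(e^-1 + e^-2)/2], evaluated independently in plain floats
        expected = -np.log((np.exp(-1.0) + np.exp(-2.0)) / 2.0)
        wx, _ = pw.jarzynski_work(sample([1.0, 2.0]))
        assert wx == pytest.approx(expected, rel=1e-12)
        assert wx == pytest.approx(1.3799, abs=5e-5)

    def test_single_measurement_estimators_coincide(self):
        with pytest.warns(UserWarning):
            wa, _ = pw.average_work(sample([7.3]))
            wx, _ = pw.jarzynski_work(sample([7.3]))
        assert wx == pytest.approx(wa, rel=1e-14)

    def test_constant_sample_returns_the_constant(self):
        wx, _ = pw.jarzynski_work(sample([4.2] * 10))
        assert wx == pytest.approx(4.2, rel=1e-12)

    def test_huge_works_do_not_underflow(self):
        wx, se = pw.jarzynski_work(sample([1.0e4, 1.2e4, 0.9e4]))
        assert np.isfinite(wx) and np.isfinite(se)
        assert 0.9e4 <= wx <= np.mean([1.0e4, 1.2e4, 0.9e4])

    @given(works_strategy)
    def test_jensen_inequality(self, works):
        s = sample(works)
        wa, _ = pw.average_work(s)
        wx, _ = pw.jarzynski_work(s)
        assert wx <= wa + 1e-9
        if np.ptp(works) > 1e-6:
            assert wx < wa

    @given(works_strategy, st.floats(-30.0, 30.0, allow_nan=False))
    def test_shift_covariance(self, works, c):
        wa0, _ = pw.average_work(sample(works))
        wx0, _ = pw.jarzynski_work(sample(works))
        wa1, _ = pw.average_work(sample(np.asarray(works) + c))
        wx1, _ = pw.jarzynski_work(sample(np.asarray(works) + c))
        assert wa1 - wa0 == pytest.approx(c, abs=1e-8)
        assert wx1 - wx0 == pytest.approx(c, abs=1e-8)


class TestBootstrap:
    def test_constant_sample_zero_se(self):
        assert pw.bootstrap_se(sample([2.0] * 5), "Wa", B=200, seed=1) == 0.0

    def test_two_value_enumeration(self):
        # resamples of {1,2}: (1,1),(1,2),(2,1),(2,2) equally likely;
        # Wa values {1, 1.5, 1.5, 2} => SD = sqrt(1/8)
        exact = np.sqrt(np.mean((np.array([1.0, 1.5, 1.5, 2.0]) - 1.5) ** 2))
        se = pw.bootstrap_se(sample([1.0, 2.0]), "Wa", B=4000, seed=3)
        assert se == pytest.approx(exact, rel=0.05)

    def test_gaussian_se_matches_closed_form(self):
        rng = np.random.default_rng(11)
        ses = [pw.bootstrap_se(sample(rng.normal(10.0, 2.0, 30)), "Wa",
                               B=400, seed=i) for i in range(20)]
        assert np.mean(ses) == pytest.approx(2.0 / np.sqrt(30.0), rel=0.3)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pw.bootstrap_se(sample([1.0]), "Wa")
        with pytest.raises(ValidationError):
            pw.bootstrap_se(sample([1.0, 2.0]), "Wa", B=10)
        with pytest.raises(ValidationError):
            pw.bootstrap_se(sample([1.0, 2.0]), "median")

    def test_seeded_reproducibility(self):
        s = sample([1.0, 2.0, 3.0, 4.0])
        assert pw.bootstrap_se(s, "Wx", B=500, seed=9) == \
            pw.bootstrap_se(s, "Wx", B=500, seed=9)


class TestOrderingAndCorrection:
    def test_estimator_result_enforces_jensen(self):
        with pytest.raises(PullworkError, match="Jensen"):
            pw.EstimatorResult(Wa=1.0, Wx=2.0, se_Wa=0.1, se_Wx=0.1, N_s=5,
                               temperature_T=1.0, kBT=1.0)

    def test_ordering_report_margins(self):
        res = pw.EstimatorResult(Wa=10.0, Wx=8.5, se_Wa=0.2, se_Wx=0.2,
                                 N_s=30, temperature_T=1.0, kBT=1.0)
        rep = pw.ordering_check(8.0, res)
        assert rep.passed
        assert rep.margin_dg_wx_kbt == pytest.approx(0.5)
        assert rep.margin_wx_wa_kbt == pytest.approx(1.5)
        assert not pw.ordering_check(9.0, res).dg_le_wx

    def test_viscous_correction_quadrature(self):
        # in units of 1e-19 J: bound 4.0±0.6, viscous 0.4±0.2
        bound = pw.EstimatorResult(Wa=5.0e-19, Wx=4.0e-19, se_Wa=0.6e-19,
                                   se_Wx=0.6e-19, N_s=30, temperature_T=300.0,
                                   kBT=4.141947e-21, label="bound")
        viscous = pw.EstimatorResult(Wa=0.8e-19, Wx=0.4e-19, se_Wa=0.2e-19,
                                     se_Wx=0.2e-19, N_s=30,
                                     temperature_T=300.0, kBT=4.141947e-21,
                                     label="viscous")
        corr = pw.viscous_correction(bound, viscous)
        assert corr.Wx == pytest.approx(3.6e-19, rel=1e-12)
        assert corr.se_Wx == pytest.approx(np.hypot(0.6, 0.2) * 1e-19,
                                           rel=1e-12)
        value, err = pw.display_correction(corr, bound, viscous, scale=1e-19)
        assert (value, err) == (3.6, 0.6)

    def test_zero_viscous_is_identity(self):
        bound = pw.EstimatorResult(Wa=5.0, Wx=4.0, se_Wa=0.6, se_Wx=0.6,
                                   N_s=30, temperature_T=1.0, kBT=1.0)
        zero = pw.EstimatorResult(Wa=0.0, Wx=0.0, se_Wa=0.0, se_Wx=0.0,
                                  N_s=30, temperature_T=1.0, kBT=1.0,
                                  label="viscous")
        corr = pw.viscous_correction(bound, zero)
        assert (corr.Wa, corr.Wx) == (bound.Wa, bound.Wx)
        equal = pw.viscous_correction(bound, bound)
        assert equal.Wx == 0.0

    def test_temperature_mismatch_rejected(self):
        bound = pw.EstimatorResult(Wa=5.0, Wx=4.0, se_Wa=0.1, se_Wx=0.1,
                                   N_s=3, temperature_T=300.0, kBT=1.0)
        cold = pw.EstimatorResult(Wa=1.0, Wx=0.5, se_Wa=0.1, se_Wx=0.1,
                                  N_s=3, temperature_T=200.0, kBT=1.0)
        with pytest.raises(ValidationError, match="temperature"):
            pw.viscous_correction(bound, cold)


class TestAffinity:
    def test_reference_affinity_constant(self):
        # Ka = 18.79e3 1/M at 300 K: kBT ln Ka = 4.07e-20 J (3 s.f.)
        dg = pw.delta_g_from_ka(18.79e3, 300.0)
        assert dg == pytest.approx(4.07e-20, rel=5e-3)

    def test_unit_affinity_is_zero(self):
        assert pw.delta_g_from_ka(1.0, 300.0) == 0.0

    def test_roundtrip_inverse(self):
        ka = 18.79e3
        back = pw.ka_from_delta_g(pw.delta_g_from_ka(ka, 300.0), 300.0)
        assert back == pytest.approx(ka, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pw.delta_g_from_ka(-1.0, 300.0)
        with pytest.raises(ValidationError):
            pw.delta_g_from_ka(10.0, 0.0)


class TestGaussianClosedForm:
    def test_estimator_approaches_mu_minus_half_variance(self):
        # i.i.d. N(10, 2^2) works at kBT = 1: Jarzynski free energy is
        # mu - sigma^2/2 = 8
        rng = np.random.default_rng(5)
        s = sample(rng.normal(10.0, 2.0, 20000))
        wx, _ = pw.jarzynski_work(s)
        assert wx == pytest.approx(8.0, abs=0.2)
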