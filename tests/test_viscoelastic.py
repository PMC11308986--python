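"""Power-law rheology, Ting auxiliary time, force backends, cycle fits."""

import math

import numpy as np
import pytest

from forcerheo.curves import TipGeometry
from forcerheo.elastic import ElasticModelParams, elastic_force
from forcerheo.synthetic import make_ting_fdc
from forcerheo.viscoelastic import (
    PLRParams,
    drag_correct_fdc,
    fit_viscoelastic,
    plr_modulus,
    t1_analytic,
    t1_numerical,
    ting_force_analytic,
    ting_force_numerical,
)


@pytest.fixture
def tip():
    return TipGeometry("paraboloid", radius=5e-6)


def triangular_ramp(v=2e-5, t_m=0.025, n=512):
    t = np.linspace(0.0, 2 * t_m, n)
    delta = np.where(t <= t_m, v * t, v * t_m - v * (t - t_m))
    return t, np.clip(delta, 0.0, None)


class TestPlrModulus:
    def test_reference_time(self, tip):
        p = PLRParams(E0=326.0, beta=0.18, tip=tip)
        assert plr_modulus(np.array([1.0]), p)[0] == pytest.approx(326.0)

    def test_solid_limit(self, tip):
        p = PLRParams(E0=500.0, beta=0.0, tip=tip)
        t = np.logspace(-3, 2, 20)
        np.testing.assert_allclose(plr_modulus(t, p), 500.0)

    def test_hand_value(self, tip):
        """E(0.5 s) = 326 * 0.5^-0.18 ~ 369.3 Pa."""
        p = PLRParams(E0=326.0, beta=0.18, tip=tip)
        assert plr_modulus(np.array([0.5]), p)[0] == pytest.approx(369.3,
                                                                   abs=0.2)


class TestT1:
    def test_continuity_at_max_indentation(self):
        assert t1_analytic(np.array([0.025]), 0.025, 1e-5, 1e-5, 0.3)[0] == (
            pytest.approx(0.025)
        )

    def test_equal_speeds_beta_zero(self):
        """v_r = v_a, beta = 0: t1 = 2 t_m - t, zero at t = 2 t_m."""
        t = np.linspace(0.025, 0.05, 11)
        t1 = t1_analytic(t, 0.025, 1e-5, 1e-5, 0.0)
        np.testing.assert_allclose(t1, np.clip(2 * 0.025 - t, 0, None),
                                   atol=1e-15)

    def test_equal_speeds_beta_half(self):
        """Multiplier (1+1)^(1/0.5) = 4."""
        t = np.array([0.03])
        t1 = t1_analytic(t, 0.025, 1e-5, 1e-5, 0.5)
        assert t1[0] == pytest.approx(0.03 - 4 * (0.03 - 0.025))

    def test_non_increasing_on_retract(self):
        t = np.linspace(0.025, 0.06, 50)
        t1 = t1_analytic(t, 0.025, 2e-5, 3e-5, 0.3)
        assert np.all(np.diff(t1) <= 1e-15)

    @pytest.mark.parametrize("beta", [0.0, 0.2, 0.4])
    def test_numerical_root_matches_closed_form(self, beta):
        """The integral-condition root agrees with the closed form < 1% t_m."""
        t, delta = triangular_ramp()
        t_m = 0.025
        for tj in np.linspace(1.05 * t_m, 1.9 * t_m, 8):
            t1n = t1_numerical(float(tj), t, delta, beta, t_m)
            t1a = float(t1_analytic(np.array([tj]), t_m, 2e-5, 2e-5, beta)[0])
            assert abs(t1n - t1a) < 0.01 * t_m


class TestForceBackends:
    def test_elastic_limit_of_hereditary_integral(self, tip):
        """beta = 0 collapses the convolution to the Hertz force."""
        t, delta = triangular_ramp()
        p = PLRParams(E0=326.0, beta=0.0, tip=tip)
        F = ting_force_numerical(t, delta, p)
        approach = t <= 0.025
        F_el = elastic_force(delta[approach],
                             ElasticModelParams(E=326.0, tip=tip))
        assert np.max(np.abs(F[approach] - F_el)) < 0.005 * F_el.max()

    def test_gamma_identity_forces_elastic_limit_analytic(self, tip):
        """beta = 0: Gamma(1) 3 sqrt(pi) / (4 Gamma(5/2)) = 1 exactly."""
        t, delta = triangular_ramp()
        p = PLRParams(E0=326.0, beta=0.0, tip=tip)
        F = ting_force_analytic(t, p, 2e-5, 2e-5, 0.025)
        approach = (t > 0) & (t <= 0.025)
        F_el = elastic_force(delta[approach],
                             ElasticModelParams(E=326.0, tip=tip))
        np.testing.assert_allclose(F[approach], F_el, rtol=1e-10)

    @pytest.mark.parametrize("beta", [0.1, 0.3])
    @pytest.mark.parametrize("shape,kw", [
        ("paraboloid", {"radius": 5e-6}),
        ("cone", {"half_angle": math.radians(35)}),
    ])
    def test_backend_oracle_equivalence(self, beta, shape, kw):
        """Analytic closed forms vs numerical hereditary integral < 1%."""
        tip = TipGeometry(shape, **kw)
        t, delta = triangular_ramp()
        p = PLRParams(E0=326.0, beta=beta, tip=tip)
        Fn = ting_force_numerical(t, delta, p)
        Fa = ting_force_analytic(t, p, 2e-5, 2e-5, 0.025)
        assert np.max(np.abs(Fn - Fa)) < 0.01 * Fa.max()

    def test_force_vanishes_at_liftoff(self, tip):
        t, delta = triangular_ramp()
        p = PLRParams(E0=326.0, beta=0.3, tip=tip)
        F = ting_force_analytic(t, p, 2e-5, 2e-5, 0.025)
        # t1 hits 0 before the end of retract for beta > 0
        assert F[-1] == 0.0

    def test_linear_in_E0(self, tip):
        t, delta = triangular_ramp(n=256)
        p1 = PLRParams(E0=200.0, beta=0.25, tip=tip)
        p2 = PLRParams(E0=400.0, beta=0.25, tip=tip)
        np.testing.assert_allclose(
            ting_force_numerical(t, delta, p2),
            2 * ting_force_numerical(t, delta, p1), rtol=1e-12)
        np.testing.assert_allclose(
            ting_force_analytic(t, p2, 2e-5, 2e-5, 0.025),
            2 * ting_force_analytic(t, p1, 2e-5, 2e-5, 0.025), rtol=1e-12)

    def test_retract_relaxation_increases_with_beta(self, tip):
        """More fluid-like -> more relaxation: the retract force relative
        to the peak force drops monotonically with beta. (The raw force at
        fixed E0 is not monotone for t << t0, where the power-law modulus
        E0 (t/t0)^-beta amplifies short-time stiffness.)"""
        t, delta = triangular_ramp()
        j = np.searchsorted(t, 0.030)  # fixed retract time
        j_peak = np.searchsorted(t, 0.025)
        prev = np.inf
        for beta in (0.0, 0.15, 0.3, 0.45):
            p = PLRParams(E0=326.0, beta=beta, tip=tip)
            F = ting_force_analytic(t, p, 2e-5, 2e-5, 0.025)
            ratio = F[j] / F[j_peak]
            assert ratio < prev
            prev = ratio

    def test_non_uniform_grid_rejected(self, tip):
        t = np.concatenate([np.linspace(0, 0.01, 100),
                            np.linspace(0.0101, 0.05, 100)])
        p = PLRParams(E0=326.0, beta=0.2, tip=tip)
        with pytest.raises(ValueError, match="resample"):
            ting_force_numerical(t, np.abs(np.sin(t)), p)


class TestDragCorrection:
    def test_zero_factor_is_identity(self):
        F = np.linspace(0, 1e-9, 20)
        np.testing.assert_array_equal(drag_correct_fdc(F, np.ones(20), 0.0), F)

    def test_piecewise_constant_velocity_step(self):
        v = np.concatenate([np.full(10, 2e-5), np.full(10, -3e-5)])
        F = np.zeros(20)
        out = drag_correct_fdc(F, v, 1e-6)
        np.testing.assert_allclose(out[:10], -1e-6 * 2e-5)
        np.testing.assert_allclose(out[10:], 1e-6 * 3e-5)


class TestFitViscoelastic:
    def test_noiseless_cross_backend_recovery(self):
        """Analytic fit of a numerically generated curve: the closed forms
        and the hereditary integral agree on the recovered parameters."""
        curve = make_ting_fdc(E0=326.0, beta=0.18)
        res = fit_viscoelastic(curve, model="analytic")
        assert res.success
        assert res.E0 == pytest.approx(326.0, rel=0.01)
        assert res.beta == pytest.approx(0.18, abs=0.005)

    def test_numerical_backend_recovery(self):
        curve = make_ting_fdc(E0=326.0, beta=0.18)
        res = fit_viscoelastic(curve, model="numerical")
        assert res.success
        assert res.E0 == pytest.approx(326.0, rel=0.005)
        assert res.beta == pytest.approx(0.18, abs=0.005)

    def test_drag_inject_and_recover(self):
        """Drag contamination at the instrument's b0 is removed by the
        correction: fitted beta returns to the clean value within 0.01."""
        clean = fit_viscoelastic(make_ting_fdc(E0=326.0, beta=0.18),
                                 model="analytic")
        contaminated = make_ting_fdc(E0=326.0, beta=0.18, drag_b0=3e-6)
        corrected = fit_viscoelastic(contaminated, model="analytic", b0=3e-6)
        uncorrected = fit_viscoelastic(contaminated, model="analytic", b0=0.0)
        assert abs(corrected.beta - clean.beta) < 0.01
        assert uncorrected.beta - clean.beta > 0.02  # contamination is real

    def test_noise_bias(self):
        """2% force noise: median beta bias < 0.02 across seeds."""
        betas = []
        for seed in range(30):
            curve = make_ting_fdc(E0=326.0, beta=0.18,
                                  force_noise_fraction=0.02, seed=seed)
            res = fit_viscoelastic(curve, model="analytic")
            if res.success:
                betas.append(res.beta)
        assert abs(np.median(betas) - 0.18) < 0.02
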