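"""Detrending, lock-in, G* pipeline, drag model, double power law."""

import cmath
import math

import numpy as np
import pytest

from forcerheo.microrheology import (
    ComplexModulusPoint,
    DragMeasurement,
    compute_gstar_curve,
    detrend_rolling,
    double_power_law,
    drag_model_b,
    drag_profile,
    fit_double_power_law,
    fit_drag_model,
    gstar_cell_average,
    piezo_characterize,
    single_frequency_response,
)
from forcerheo.synthetic import (
    make_glass_piezochar,
    make_microrheo_curve,
    make_vdrag_sweep,
)

SIX_FREQS = (0.6, 1.0, 10.0, 60.0, 120.0, 200.0)


class TestDetrend:
    def test_sinusoid_preserved(self):
        fs, f = 640.0, 10.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.sin(2 * np.pi * f * t)
        out = detrend_rolling(x, fs / f)
        core = slice(int(fs / f), -int(fs / f))
        np.testing.assert_allclose(out[core], x[core], atol=1e-10)

    def test_removes_linear_ramp(self):
        fs, f = 640.0, 10.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.sin(2 * np.pi * f * t) + 3.0 * t
        out = detrend_rolling(x, fs / f)
        core = slice(int(fs / f), -int(fs / f))
        resid = out[core] - np.sin(2 * np.pi * f * t)[core]
        assert np.max(np.abs(resid)) < 0.01

    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(detrend_rolling(np.full(100, 4.2), 10), 0.0,
                                   atol=1e-12)


class TestLockIn:
    def test_in_phase_scaling(self):
        t = np.arange(0, 1.0, 1 / 512)
        x = 2e-9 * np.sin(2 * np.pi * 8 * t)
        resp = single_frequency_response(x, 3.0 * x, 8.0, t)
        assert resp.H == pytest.approx(3.0 + 0j, abs=1e-9)

    def test_quadrature_lag(self):
        t = np.arange(0, 1.0, 1 / 512)
        d = 1e-9 * np.sin(2 * np.pi * 8 * t)
        F = 1e-9 * np.sin(2 * np.pi * 8 * t - np.pi / 2)
        resp = single_frequency_response(d, F, 8.0, t)
        assert resp.phase == pytest.approx(-np.pi / 2, abs=1e-6)
        assert abs(resp.H) == pytest.approx(1.0, rel=1e-9)

    def test_noisy_recovery(self):
        """SNR 20 dB, 16 cycles: |H| within 3%, phase within 2 degrees."""
        amp_ok = phase_ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 16 / 10.0, 1 / 640.0)
            d = 1e-9 * np.sin(2 * np.pi * 10 * t)
            F = 2e-9 * np.sin(2 * np.pi * 10 * t - 0.3)
            noise = 0.1 * 2e-9  # -20 dB relative to signal
            Fn = F + rng.normal(0, noise / math.sqrt(2), len(t))
            resp = single_frequency_response(d, Fn, 10.0, t)
            if abs(abs(resp.H) - 2.0) < 0.06:
                amp_ok += 1
            if abs(resp.phase + 0.3) < math.radians(2):
                phase_ok += 1
        assert amp_ok >= 90 and phase_ok >= 90

    def test_few_cycles_flagged(self):
        t = np.arange(0, 0.2, 1 / 512)  # 2 cycles at 10 Hz
        x = np.sin(2 * np.pi * 10 * t)
        assert single_frequency_response(x, x, 10.0, t).flagged


class TestPiezoCharacterize:
    def test_ideal_instrument(self):
        pc = piezo_characterize(make_glass_piezochar())
        np.testing.assert_allclose(pc.phase_lag, 0.0, atol=1e-10)
        np.testing.assert_allclose(pc.amp_quotient, 1.0, rtol=1e-10)

    def test_first_order_lag_recovered(self):
        tau = 1e-3
        pc = piezo_characterize(make_glass_piezochar(piezo_lag_tau=tau))
        expected = -np.arctan(2 * np.pi * pc.f * tau)
        np.testing.assert_allclose(pc.phase_lag, expected,
                                   atol=math.radians(1))

    def test_amplitude_quotient(self):
        pc = piezo_characterize(make_glass_piezochar(piezo_amp_quotient=0.9))
        np.testing.assert_allclose(pc.amp_quotient, 0.9, rtol=1e-6)


class TestComputeGstar:
    def test_purely_elastic_sample(self):
        """F proportional to delta with zero lag: G'' = 0 and
        G' = E / (2 (1 + nu))."""
        E, nu = 1000.0, 0.5
        G = E / (2 * (1 + nu))
        curve = make_microrheo_curve(gstar=lambda f: complex(G, 0.0))
        pts = compute_gstar_curve(curve)
        for p in pts:
            assert p.g_storage == pytest.approx(G, rel=0.01)
            assert abs(p.g_loss) < 0.01 * G
            assert abs(p.loss_tangent) < 0.01

    def test_power_law_exponent_recovery(self):
        """Single power-law G*(f): recovered G', G'' exponents within 0.02."""
        alpha = 0.2
        curve = make_microrheo_curve()  # default: G0=1 kPa, alpha=0.2
        pts = compute_gstar_curve(curve)
        f = np.array([p.f for p in pts])
        for comp in ("g_storage", "g_loss"):
            y = np.array([getattr(p, comp) for p in pts])
            slope = np.polyfit(np.log(f), np.log(y), 1)[0]
            assert slope == pytest.approx(alpha, abs=0.02)

    def test_drag_inject_and_recover(self):
        b0 = 5e-6
        clean = compute_gstar_curve(make_microrheo_curve())
        corrected = compute_gstar_curve(
            make_microrheo_curve(drag_b0=b0), b0=b0)
        for p, c in zip(corrected, clean):
            assert p.g_loss == pytest.approx(c.g_loss, rel=0.01)

    def test_drag_correction_only_lowers_loss(self):
        contaminated = make_microrheo_curve(drag_b0=5e-6)
        raw = compute_gstar_curve(contaminated)
        corr = compute_gstar_curve(contaminated, b0=5e-6)
        for p, c in zip(raw, corr):
            assert c.g_loss < p.g_loss
            assert c.g_storage == pytest.approx(p.g_storage, rel=1e-6)

    def test_piezo_phase_rotation_is_rigid(self):
        """The phase correction preserves |G*|."""
        tau = 1e-4
        glass = make_glass_piezochar(piezo_lag_tau=tau)
        pc = piezo_characterize(glass)
        curve = make_microrheo_curve()
        raw = compute_gstar_curve(curve)
        rot = compute_gstar_curve(curve, piezo=pc)
        for p, c in zip(raw, rot):
            assert math.hypot(c.g_storage, c.g_loss) == pytest.approx(
                math.hypot(p.g_storage, p.g_loss), rel=1e-6)

    def test_piezo_inject_and_recover(self):
        """Instrument lag + amplitude error applied by the generator and
        removed by the calibration restores G'' within 1%."""
        tau, aq = 1e-5, 0.93
        clean = compute_gstar_curve(make_microrheo_curve())
        pc = piezo_characterize(
            make_glass_piezochar(piezo_lag_tau=tau, piezo_amp_quotient=aq))
        corrected = compute_gstar_curve(
            make_microrheo_curve(piezo_lag_tau=tau, piezo_amp_quotient=aq),
            piezo=pc)
        for p, c in zip(corrected, clean):
            assert p.g_loss == pytest.approx(c.g_loss, rel=0.01)


class TestDrag:
    def test_forward_model_recovery(self):
        """Fluid-only response F = b d(delta)/dt: b recovered within 0.5%."""
        curve = make_vdrag_sweep(a_eff=30e-6, h_eff=5e-6)
        pts = drag_profile(curve)
        for p in pts:
            b_true = float(drag_model_b(np.array([p.h]), 30e-6, 5e-6,
                                        8.9e-4)[0])
            assert p.b == pytest.approx(b_true, rel=0.005)

    def test_monotone_decreasing_in_h(self):
        pts = drag_profile(make_vdrag_sweep())
        bs = [p.b for p in sorted(pts, key=lambda q: q.h)]
        assert all(b1 > b2 for b1, b2 in zip(bs, bs[1:]))

    def test_fit_exact_on_noiseless_points(self):
        h = np.array([0.5e-6, 1e-6, 1.5e-6, 2e-6, 3e-6])
        b = drag_model_b(h, 25e-6, 4e-6, 8.9e-4)
        pts = [DragMeasurement(h=float(hi), b=float(bi), f=500.0)
               for hi, bi in zip(h, b)]
        fit = fit_drag_model(pts, eta_fluid=8.9e-4)
        assert fit.a_eff == pytest.approx(25e-6, rel=1e-6)
        assert fit.h_eff == pytest.approx(4e-6, rel=1e-6)
        assert fit.b0 == pytest.approx(
            6 * math.pi * 8.9e-4 * 25e-6**2 / 4e-6, rel=1e-6)

    def test_noisy_b0_recovery(self):
        """5% noise on b(h): median |b0 error| < 5% over seeds."""
        h = np.array([0.5e-6, 1e-6, 1.5e-6, 2e-6, 2.5e-6, 3e-6])
        b_true = drag_model_b(h, 25e-6, 4e-6, 8.9e-4)
        b0_true = 6 * math.pi * 8.9e-4 * 25e-6**2 / 4e-6
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            b = b_true * (1 + rng.normal(0, 0.05, len(h)))
            pts = [DragMeasurement(h=float(hi), b=float(bi), f=500.0)
                   for hi, bi in zip(h, b)]
            fit = fit_drag_model(pts, eta_fluid=8.9e-4)
            errs.append(abs(fit.b0 / b0_true - 1))
        assert float(np.median(errs)) < 0.05

    def test_two_points_insufficient(self):
        pts = [DragMeasurement(h=1e-6, b=1e-6, f=500.0),
               DragMeasurement(h=2e-6, b=5e-7, f=500.0)]
        with pytest.raises(ValueError, match="insufficient separations"):
            fit_drag_model(pts)


def _points_from_law(A, B, alpha, beta, freqs=SIX_FREQS):
    gp, gpp = double_power_law(np.array(freqs), A, B, alpha, beta)
    return [
        ComplexModulusPoint(f=float(f), g_storage=float(a), g_loss=float(b),
                            loss_tangent=float(b / a), delta0=5e-7)
        for f, a, b in zip(freqs, gp, gpp)
    ]


class TestDoublePowerLaw:
    def test_four_parameter_recovery(self):
        """Noiseless samples at the six standard frequencies recover
        (A, B, alpha, beta) = (2663, 38, 0.17, 0.99) within 2%."""
        fit = fit_double_power_law(_points_from_law(2663.0, 38.0, 0.17, 0.99))
        assert fit.A == pytest.approx(2663.0, rel=0.02)
        assert fit.B == pytest.approx(38.0, rel=0.02)
        assert fit.alpha == pytest.approx(0.17, rel=0.02)
        assert fit.beta == pytest.approx(0.99, rel=0.02)

    def test_single_power_law_degenerate(self):
        """B = 0 truth: alpha recovered within 0.01 and B ~ 0."""
        pts = _points_from_law(1500.0, 1e-5, 0.17, 0.9)
        fit = fit_double_power_law(pts)
        assert fit.alpha == pytest.approx(0.17, abs=0.01)
        assert fit.B < 0.01 * fit.A

    def test_low_frequency_loss_tangent_limit(self):
        """When the B term is negligible, G''/G' -> tan(pi alpha / 2)."""
        alpha = 0.17
        pts = _points_from_law(2000.0, 1e-6, alpha, 0.99,
                               freqs=(0.01, 0.02, 0.05, 0.1))
        fit = fit_double_power_law(pts)
        gp, gpp = double_power_law(np.array([0.01]), fit.A, fit.B, fit.alpha,
                                   fit.beta)
        assert gpp[0] / gp[0] == pytest.approx(math.tan(math.pi * alpha / 2),
                                               rel=0.01)


class TestCellAverage:
    def test_idempotent_on_identical_curves(self):
        pts = _points_from_law(1000.0, 20.0, 0.2, 0.9)
        agg = gstar_cell_average([pts, pts, pts])
        np.testing.assert_allclose(agg["g_storage"],
                                   [p.g_storage for p in pts])
        np.testing.assert_allclose(agg["g_storage_se"], 0.0, atol=1e-12)

    def test_geometric_mean_definition(self):
        a = _points_from_law(100.0, 1e-6, 0.0, 0.9, freqs=(1, 2, 4, 8))
        b = _points_from_law(400.0, 4e-6, 0.0, 0.9, freqs=(1, 2, 4, 8))
        agg = gstar_cell_average([a, b])
        np.testing.assert_allclose(
            agg["g_storage"],
            np.sqrt(np.array([p.g_storage for p in a])
                    * np.array([p.g_storage for p in b])),
            rtol=1e-12)

    def test_lognormal_scatter_unbiased_in_log_domain(self):
        rng = np.random.default_rng(7)
        base = _points_from_law(1000.0, 20.0, 0.2, 0.9)
        maps = []
        for _ in range(200):
            s = float(np.exp(rng.normal(0, 0.3)))
            maps.append([
                ComplexModulusPoint(f=p.f, g_storage=p.g_storage * s,
                                    g_loss=p.g_loss * s,
                                    loss_tangent=p.loss_tangent,
                                    delta0=p.delta0)
                for p in base
            ])
        agg = gstar_cell_average(maps)
        log_err = np.log(agg["g_storage"].to_numpy()
                         / np.array([p.g_storage for p in base]))
        assert np.all(np.abs(log_err) < 0.05)

    def test_mismatched_frequencies_rejected(self):
        a = _points_from_law(100.0, 1.0, 0.2, 0.9, freqs=(1, 2, 4, 8))
        b = _points_from_law(100.0, 1.0, 0.2, 0.9, freqs=(1, 2, 4, 16))
        with pytest.raises(ValueError, match="frequency set"):
            gstar_cell_average([a, b])
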