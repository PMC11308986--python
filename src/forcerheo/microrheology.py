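"""Frequency-domain microrheology: complex shear modulus with corrections.

Small sinusoidal oscillations about a working indentation ``delta0`` probe
the complex shear modulus G*(f) = G' + iG''. Per drive frequency the
pipeline is: correct the piezo amplitude (glass calibration), detrend both
signals by a one-period rolling average, extract complex amplitudes by
lock-in (least-squares sinusoid projection at the known drive frequency),
form the transfer function H(f) = F(f)/delta(f), subtract the hydrodynamic
drag contribution i*2*pi*f*b0, scale by the contact-model prefactor

    paraboloid: G* = (1 - nu) / (4 sqrt(R delta0)) * H
    pyramid:    G* = (1 - nu) / (3 delta0 tan(theta)) * H

and finally rotate by the z-piezo phase lag, G*_corr = G* exp(-i phi_PZT).

The hydrodynamic drag coefficient b(h) is measured by oscillating the
cantilever at several tip–sample separations h and extrapolating the
scaled-sphere model b(h) = 6 pi eta a_eff^2 / (h + h_eff) to contact.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

from .contact import DEFAULT_ROV_WINDOW, estimate_poc
from .curves import ForceCurve, Segment, SegmentKind, TipShape
from .stats import GofMetrics, gof_metrics

__all__ = [
    "FrequencyResponse",
    "ComplexModulusPoint",
    "PiezoCharacterization",
    "DragMeasurement",
    "DragModelFit",
    "PowerLawFit",
    "detrend_rolling",
    "single_frequency_response",
    "piezo_characterize",
    "compute_gstar",
    "compute_gstar_curve",
    "drag_profile",
    "fit_drag_model",
    "fit_double_power_law",
    "gstar_cell_average",
    "ETA_WATER_25C",
]

ETA_WATER_25C = 8.9e-4  # Pa s, default surrounding-fluid viscosity


@dataclass(frozen=True)
class FrequencyResponse:
    """Complex transfer function at a single drive frequency."""

    f: float  # Hz
    H: complex  # output/input complex amplitude ratio
    amp_in: float
    amp_out: float
    phase: float  # rad, in (-pi, pi]
    n_cycles: float
    flagged: bool = False  # fewer than 4 full cycles


@dataclass(frozen=True)
class ComplexModulusPoint:
    f: float  # Hz
    g_storage: float  # Pa, G'
    g_loss: float  # Pa, G''
    loss_tangent: float  # G''/G'
    delta0: float  # m, working indentation


@dataclass(frozen=True)
class PiezoCharacterization:
    """Per-frequency instrument phase lag and amplitude quotient on glass."""

    f: np.ndarray  # Hz
    phase_lag: np.ndarray  # rad, phi_PZT
    amp_quotient: np.ndarray  # A_d/A_z

    def at(self, f: float) -> tuple[float, float]:
        """(phi_PZT, A_corr) at the nearest characterized frequency."""
        i = int(np.argmin(np.abs(self.f - f)))
        return float(self.phase_lag[i]), float(self.amp_quotient[i])


@dataclass(frozen=True)
class DragMeasurement:
    h: float  # m, tip-sample separation
    b: float  # N s/m
    f: float  # Hz


@dataclass(frozen=True)
class DragModelFit:
    a_eff: float  # m
    h_eff: float  # m
    eta_fluid: float  # Pa s
    b0: float  # N s/m, extrapolation to contact


@dataclass(frozen=True)
class PowerLawFit:
    A: float  # Pa (per Hz^alpha)
    B: float  # Pa (per Hz^beta)
    alpha: float
    beta: float
    gof: GofMetrics


def detrend_rolling(x: np.ndarray, points_per_period: float) -> np.ndarray:
    """Subtract a centered rolling mean of one oscillation period.

    ``points_per_period`` is rounded to the window size; edges use shrunken
    (still centered) windows. Removes offsets and slow drift while leaving
    the oscillation essentially untouched.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(points_per_period))
    if w < 3:
        raise ValueError("points_per_period must round to >= 3")
    n = len(x)
    # symmetric kernel spanning exactly one period: for even w use w+1 taps
    # with half-weight endpoints so a period-w sinusoid averages to zero
    if w % 2 == 0:
        kernel = np.ones(w + 1)
        kernel[0] = kernel[-1] = 0.5
        kernel /= w
    else:
        kernel = np.ones(w) / w
    half = len(kernel) // 2
    # edges: shrunken centered plain means
    c = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    rolling = (c[hi] - c[lo]) / (hi - lo)
    if n >= len(kernel):
        rolling[half : n - half] = np.convolve(x, kernel, mode="valid")
    return x - rolling


def single_frequency_response(
    delta: np.ndarray,
    force: np.ndarray,
    f: float,
    t: np.ndarray,
) -> FrequencyResponse:
    """Lock-in transfer function H = F(f)/delta(f) at a known drive frequency.

    Complex amplitudes come from least-squares projection onto
    cos(2 pi f t) and sin(2 pi f t) (tolerates non-integer cycle counts);
    X = A - iB for x(t) = A cos + B sin, so x(t) = Re[X exp(i 2 pi f t)].
    Fewer than 4 full cycles flags the result.
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    t = np.asarray(t, dtype=float)
    n_cycles = f * (t[-1] - t[0])
    w = 2.0 * math.pi * f
    basis = np.vstack([np.cos(w * t), np.sin(w * t), np.ones_like(t)]).T

    def complex_amp(x: np.ndarray) -> complex:
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
        return complex(coef[0], -coef[1])

    Xin = complex_amp(delta)
    Xout = complex_amp(force)
    if abs(Xin) == 0:
        raise ValueError("input signal has no component at the drive frequency")
    H = Xout / Xin
    return FrequencyResponse(
        f=float(f),
        H=H,
        amp_in=abs(Xin),
        amp_out=abs(Xout),
        phase=cmath.phase(H),
        n_cycles=float(n_cycles),
        flagged=n_cycles < 4,
    )


def _trim_edges(ppp: float, *arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    """Drop one oscillation period at each end (detrending edge effects)."""
    w = int(round(ppp))
    n = len(arrays[0])
    if n <= 3 * w:  # keep at least one period
        return arrays
    return tuple(a[w : n - w] for a in arrays)


def _modulation_segments(curve: ForceCurve) -> list[Segment]:
    segs = curve.get_segments(SegmentKind.MODULATION)
    if not segs:
        raise ValueError("curve has no modulation segments")
    return segs


def piezo_characterize(glass_curve: ForceCurve) -> PiezoCharacterization:
    """Instrument phase lag and amplitude quotient from glass modulation data.

    On a rigid substrate the deflection should track the piezo exactly; any
    phase between z and d is instrument-intrinsic (phi_PZT) and the
    amplitude quotient A_d/A_z calibrates the piezo amplitude.
    """
    fs, phases, amps = [], [], []
    for seg in _modulation_segments(glass_curve):
        f = seg.drive_frequency
        ppp = seg.sampling_rate / f
        z = detrend_rolling(seg.z, ppp)
        d = detrend_rolling(seg.d, ppp)
        z, d, t = _trim_edges(ppp, z, d, seg.t)
        resp = single_frequency_response(z, d, f, t)
        fs.append(f)
        phases.append(resp.phase)
        amps.append(abs(resp.H))
    return PiezoCharacterization(
        f=np.asarray(fs), phase_lag=np.asarray(phases), amp_quotient=np.asarray(amps)
    )


def _gstar_prefactor(curve_meta, delta0: float) -> float:
    tip = curve_meta.tip
    nu = curve_meta.poisson_ratio
    if delta0 <= 0:
        raise ValueError("working indentation delta0 must be > 0")
    if tip.shape is TipShape.PARABOLOID:
        return (1.0 - nu) / (4.0 * math.sqrt(tip.radius * delta0))
    if tip.shape is TipShape.PYRAMID:
        return (1.0 - nu) / (3.0 * delta0 * math.tan(tip.half_angle))
    raise ValueError(
        "frequency-domain models are implemented for paraboloid and pyramid tips"
    )


def compute_gstar(
    modulation: Sequence[Segment],
    delta0: float,
    meta,
    piezo: Optional[PiezoCharacterization] = None,
    b0: Optional[float] = None,
) -> list[ComplexModulusPoint]:
    """Complex shear modulus per modulation segment.

    Steps per frequency: piezo amplitude correction of z (if calibrated),
    rolling-average detrend of z and d, lock-in transfer function
    H = F(f)/delta(f), drag correction H - i 2 pi f b0, contact-model
    prefactor, and the piezo phase rotation exp(-i phi_PZT).
    """
    k = meta.spring_constant
    pref = _gstar_prefactor(meta, delta0)
    points: list[ComplexModulusPoint] = []
    for seg in modulation:
        f = seg.drive_frequency
        phi_pzt, a_corr = (0.0, 1.0)
        if piezo is not None:
            phi_pzt, a_corr = piezo.at(f)
        ppp = seg.sampling_rate / f
        z = detrend_rolling(seg.z * a_corr, ppp)
        d = detrend_rolling(seg.d, ppp)
        z, d, t = _trim_edges(ppp, z, d, seg.t)
        delta_ac = z - d
        force_ac = k * d
        resp = single_frequency_response(delta_ac, force_ac, f, t)
        H = resp.H
        if b0 is not None and b0 > 0:
            H = H - 1j * 2.0 * math.pi * f * b0
        gstar = pref * H * cmath.exp(-1j * phi_pzt)
        gp, gpp = gstar.real, gstar.imag
        points.append(
            ComplexModulusPoint(
                f=float(f),
                g_storage=gp,
                g_loss=gpp,
                loss_tangent=gpp / gp if gp != 0 else float("inf"),
                delta0=float(delta0),
            )
        )
    return points


def compute_gstar_curve(
    curve: ForceCurve,
    piezo: Optional[PiezoCharacterization] = None,
    b0: Optional[float] = None,
    rov_window: int = DEFAULT_ROV_WINDOW,
) -> list[ComplexModulusPoint]:
    """Default microrheology routine on a full curve.

    The working indentation delta0 is the approach-segment indentation at
    the end of the approach, referenced to the RoV point of contact.
    """
    approach = curve.approach
    z0, d0 = estimate_poc(approach, rov_window)
    delta0 = float((approach.z[-1] - z0) - (approach.d[-1] - d0))
    return compute_gstar(
        _modulation_segments(curve), delta0, curve.metadata, piezo=piezo, b0=b0
    )


def drag_profile(
    vdrag_curve: ForceCurve,
    piezo: Optional[PiezoCharacterization] = None,
) -> list[DragMeasurement]:
    """Drag coefficient b(h) per modulation segment of a drag sweep.

    Off contact the only force on the cantilever is hydrodynamic,
    F = b * (tip velocity), so the transfer function is purely imaginary,
    H = i 2 pi f b, and b = Im(H) / (2 pi f). The separation h is read from
    each segment's metadata.
    """
    out: list[DragMeasurement] = []
    for seg in _modulation_segments(vdrag_curve):
        f = seg.drive_frequency
        if seg.separation is None:
            raise ValueError("drag-sweep segments need a separation_m annotation")
        phi_pzt, a_corr = (0.0, 1.0)
        if piezo is not None:
            phi_pzt, a_corr = piezo.at(f)
        ppp = seg.sampling_rate / f
        z = detrend_rolling(seg.z * a_corr, ppp)
        d = detrend_rolling(seg.d, ppp)
        z, d, t = _trim_edges(ppp, z, d, seg.t)
        tip = z - d
        force = vdrag_curve.metadata.spring_constant * d
        resp = single_frequency_response(tip, force, f, t)
        H = resp.H * cmath.exp(-1j * phi_pzt)
        b = H.imag / (2.0 * math.pi * f)
        out.append(DragMeasurement(h=float(seg.separation), b=float(b), f=float(f)))
    return out


def drag_model_b(h: np.ndarray, a_eff: float, h_eff: float, eta: float) -> np.ndarray:
    """Scaled-sphere drag model b(h) = 6 pi eta a_eff^2 / (h + h_eff)."""
    return 6.0 * math.pi * eta * a_eff**2 / (np.asarray(h, dtype=float) + h_eff)


def fit_drag_model(
    points: Sequence[DragMeasurement], eta_fluid: float = ETA_WATER_25C
) -> DragModelFit:
    """Fit (a_eff, h_eff) of the scaled-sphere model and extrapolate b(0)."""
    if len(points) < 3:
        raise ValueError("insufficient separations: need >= 3 drag measurements")
    h = np.array([p.h for p in points])
    b = np.array([p.b for p in points])
    # Linearized init: 1/b = (h + h_eff) / (6 pi eta a^2) is linear in h.
    slope, intercept = np.polyfit(h, 1.0 / b, 1)
    a0 = math.sqrt(max(1.0 / (6.0 * math.pi * eta_fluid * slope), 1e-18))
    h0 = max(intercept / slope, 1e-9)

    params = lmfit.Parameters()
    params.add("a_eff", value=a0, min=1e-9)
    params.add("h_eff", value=h0, min=1e-12)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return drag_model_b(h, p["a_eff"].value, p["h_eff"].value, eta_fluid) - b

    out = lmfit.minimize(residual, params, method="leastsq")
    a_eff = float(out.params["a_eff"].value)
    h_eff = float(out.params["h_eff"].value)
    return DragModelFit(
        a_eff=a_eff,
        h_eff=h_eff,
        eta_fluid=eta_fluid,
        b0=float(6.0 * math.pi * eta_fluid * a_eff**2 / h_eff),
    )


def double_power_law(
    f: np.ndarray, A: float, B: float, alpha: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """G'(f) and G''(f) of the double power law.

    G'(f) = A cos(pi alpha/2) f^alpha + B cos(pi beta/2) f^beta
    G''(f) = A sin(pi alpha/2) f^alpha + B sin(pi beta/2) f^beta
    """
    f = np.asarray(f, dtype=float)
    ca, sa = math.cos(math.pi * alpha / 2), math.sin(math.pi * alpha / 2)
    cb, sb = math.cos(math.pi * beta / 2), math.sin(math.pi * beta / 2)
    gp = A * ca * f**alpha + B * cb * f**beta
    gpp = A * sa * f**alpha + B * sb * f**beta
    return gp, gpp


EXPONENT_BOUNDS = (0.0, 1.2)


def fit_double_power_law(points: Sequence[ComplexModulusPoint]) -> PowerLawFit:
    """Simultaneous least squares of G' and G'' to the double power law.

    Four free parameters (A, B, alpha, beta); exponents bounded to
    [0, 1.2]; the two power-law terms are ordered alpha <= beta after the
    fit. Requires >= 4 frequencies with positive moduli.
    """
    if len(points) < 4:
        raise ValueError("need >= 4 frequencies for the double power law")
    f = np.array([p.f for p in points])
    gp = np.array([p.g_storage for p in points])
    gpp = np.array([p.g_loss for p in points])
    if np.any(gp <= 0) or np.any(gpp <= 0):
        raise ValueError("double power law requires positive G' and G''")

    params = lmfit.Parameters()
    params.add("A", value=float(gp[np.argmin(f)]), min=1e-6)
    b_init = float(gpp[np.argmax(f)] / f.max() ** 0.9)
    params.add("B", value=max(b_init, 1e-6), min=1e-6)
    params.add("alpha", value=0.2, min=EXPONENT_BOUNDS[0], max=EXPONENT_BOUNDS[1])
    params.add("beta", value=0.9, min=EXPONENT_BOUNDS[0], max=EXPONENT_BOUNDS[1])

    y = np.concatenate([gp, gpp])

    def residual(p: lmfit.Parameters) -> np.ndarray:
        mp, mpp = double_power_law(
            f, p["A"].value, p["B"].value, p["alpha"].value, p["beta"].value
        )
        return np.concatenate([mp, mpp]) - y

    out = lmfit.minimize(residual, params, method="leastsq")
    A, B = float(out.params["A"].value), float(out.params["B"].value)
    alpha, beta = float(out.params["alpha"].value), float(out.params["beta"].value)
    if alpha > beta:
        A, B, alpha, beta = B, A, beta, alpha
    mp, mpp = double_power_law(f, A, B, alpha, beta)
    return PowerLawFit(
        A=A, B=B, alpha=alpha, beta=beta,
        gof=gof_metrics(y, np.concatenate([mp, mpp]), 4),
    )


def gstar_cell_average(
    maps: Sequence[Sequence[ComplexModulusPoint]],
) -> pd.DataFrame:
    """Per-frequency geometric mean of G' and G'' across curves of one cell.

    All curves must share the frequency set. Returns a DataFrame with
    columns f, g_storage, g_loss (geometric means) and g_storage_se,
    g_loss_se (log-domain standard errors propagated to the mean).
    """
    if not maps:
        raise ValueError("no curves to aggregate")
    freqs = [tuple(p.f for p in m) for m in maps]
    if len(set(freqs)) != 1:
        raise ValueError("all curves must share the same frequency set")
    f = np.array(freqs[0])
    gp = np.array([[p.g_storage for p in m] for m in maps])  # (curves, freqs)
    gpp = np.array([[p.g_loss for p in m] for m in maps])
    if np.any(gp <= 0) or np.any(gpp <= 0):
        raise ValueError("geometric mean requires positive moduli")
    n = gp.shape[0]

    def gm_se(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logs = np.log(x)
        gm = np.exp(logs.mean(axis=0))
        se_log = logs.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(len(f))
        return gm, gm * se_log  # delta-method SE on the linear scale

    gp_gm, gp_se = gm_se(gp)
    gpp_gm, gpp_se = gm_se(gpp)
    return pd.DataFrame(
        {
            "f": f,
            "g_storage": gp_gm,
            "g_loss": gpp_gm,
            "g_storage_se": gp_se,
            "g_loss_se": gpp_se,
        }
    )
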