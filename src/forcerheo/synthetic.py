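"""Forward simulators for every measurement type the analysis consumes.

Each generator produces a :class:`~forcerheo.curves.ForceCurve` (or a
:class:`~forcerheo.calibration.ThermalSpectrum`) from known ground-truth
parameters, so that every estimator in the package can be validated as a
closed loop (generate -> analyze -> recover truth). Defaults emulate a
typical cell-mechanics protocol on a soft sample in liquid: hemispherical
R = 5 um probe, k = 0.192 N/m, 4 um ramp at 20 um/s targeting ~500 nm
indentation; oscillatory measurements with 15 nm amplitude at 0.6, 1, 10,
60, 120 and 200 Hz; drag sweeps at 500 Hz between 0.5 and 3 um from the
surface.

Noise is additive Gaussian on the deflection channel (what the instrument
actually digitizes), with the standard deviation specified as a fraction
of the maximum force and converted through the spring constant. All
generators are bit-reproducible for a fixed seed.

The viscoelastic generator uses the numerical Ting backend, so fits with
the analytic backend are a genuine cross-check rather than an inversion of
the same code path.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

from .calibration import ThermalSpectrum, sho_psd
from .curves import (
    CurveMetadata,
    ForceCurve,
    Segment,
    SegmentKind,
    TipGeometry,
)
from .elastic import ElasticModelParams, elastic_force
from .microrheology import ETA_WATER_25C, drag_model_b
from .viscoelastic import PLRParams, ting_force_numerical

__all__ = [
    "DEFAULT_TIP",
    "DEFAULT_SPRING_CONSTANT",
    "DEFAULT_FREQUENCIES",
    "make_elastic_fdc",
    "make_ting_fdc",
    "make_microrheo_curve",
    "make_glass_piezochar",
    "make_vdrag_sweep",
    "make_thermal",
]

DEFAULT_TIP = TipGeometry("paraboloid", radius=5e-6)
DEFAULT_SPRING_CONSTANT = 0.192  # N/m
DEFAULT_FREQUENCIES = (0.6, 1.0, 10.0, 60.0, 120.0, 200.0)  # Hz
DEFAULT_RAMP_SPEED = 20e-6  # m/s
DEFAULT_RAMP_SIZE = 4e-6  # m


def _meta(tip: TipGeometry, k: float, nu: float, file_id: str) -> CurveMetadata:
    return CurveMetadata(
        spring_constant=k, tip=tip, poisson_ratio=nu, file_id=file_id
    )


def _solve_deflection_elastic(
    u: np.ndarray, p: ElasticModelParams, k: float, n_iter: int = 60
) -> np.ndarray:
    """Solve k d = F_elastic(u - d) for d, per sample, by bisection.

    ``u = z - z0`` is the piezo travel past contact; the force balance is
    monotone in d so bisection on [0, u] always converges.
    """
    u = np.clip(np.asarray(u, dtype=float), 0.0, None)
    lo = np.zeros_like(u)
    hi = u.copy()
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g = elastic_force(u - mid, p) - k * mid  # >0 means d too small
        lo = np.where(g > 0, mid, lo)
        hi = np.where(g > 0, hi, mid)
    return 0.5 * (lo + hi)


def make_elastic_fdc(
    E: float = 1000.0,
    tip: TipGeometry = DEFAULT_TIP,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    poisson_ratio: float = 0.5,
    ramp_size: float = DEFAULT_RAMP_SIZE,
    ramp_speed: float = DEFAULT_RAMP_SPEED,
    contact_fraction: float = 0.875,
    sampling_rate: float = 4096.0,
    force_noise_fraction: float = 0.0,
    drift_slope: float = 0.0,
    seed: Optional[int] = None,
    file_id: str = "synthetic_elastic",
) -> ForceCurve:
    """Approach–retract force curve on a purely elastic (Hertz) sample.

    The piezo runs a triangular ramp; contact sits at ``contact_fraction``
    of the ramp (default leaves ~500 nm of travel past contact).
    ``drift_slope`` (m/s) adds a linear deflection drift.
    """
    rng = np.random.default_rng(seed)
    meta = _meta(tip, spring_constant, poisson_ratio, file_id)
    p = ElasticModelParams(E=E, tip=tip, poisson_ratio=poisson_ratio)
    z0 = contact_fraction * ramp_size
    dur = ramp_size / ramp_speed
    n = int(round(dur * sampling_rate))
    segs = []
    for kind, sgn, t_off in (
        (SegmentKind.APPROACH, 1.0, 0.0),
        (SegmentKind.RETRACT, -1.0, dur),
    ):
        t = t_off + np.arange(n) / sampling_rate
        z = ramp_size * (t - t_off) / dur if sgn > 0 else ramp_size * (
            1.0 - (t - t_off) / dur
        )
        d = _solve_deflection_elastic(z - z0, p, spring_constant)
        f_max = spring_constant * d.max() if d.max() > 0 else 1e-12
        if force_noise_fraction > 0:
            d = d + rng.normal(
                0.0, force_noise_fraction * f_max / spring_constant, size=n
            )
        if drift_slope:
            d = d + drift_slope * t
        segs.append(Segment(kind=kind, t=t, z=z, d=d))
    return ForceCurve(metadata=meta, segments=tuple(segs))


def make_ting_fdc(
    E0: float = 326.0,
    beta: float = 0.18,
    tip: TipGeometry = DEFAULT_TIP,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    poisson_ratio: float = 0.5,
    t0: float = 1.0,
    indentation_speed: float = 20e-6,
    retract_speed: Optional[float] = None,
    max_indentation: float = 5e-7,
    pre_contact: float = 5e-7,
    sampling_rate: float = 20480.0,
    force_noise_fraction: float = 0.0,
    drag_b0: float = 0.0,
    seed: Optional[int] = None,
    file_id: str = "synthetic_ting",
) -> ForceCurve:
    """Approach–retract curve on a power-law-rheology sample (Ting model).

    The indentation history is a constant-velocity triangle; the force is
    computed with the numerical hereditary-integral backend, so analytic
    fits of this output are an independent cross-check. ``drag_b0`` > 0
    contaminates the force with hydrodynamic drag b0 * dz/dt.
    """
    rng = np.random.default_rng(seed)
    meta = _meta(tip, spring_constant, poisson_ratio, file_id)
    v_a = indentation_speed
    v_r = retract_speed if retract_speed is not None else v_a
    t_pre = pre_contact / v_a
    t_m = max_indentation / v_a
    t_ret = max_indentation / v_r + t_pre
    t_end = t_pre + t_m + t_ret
    n = int(round(t_end * sampling_rate))
    t = np.arange(n) / sampling_rate
    delta = np.where(
        t <= t_pre + t_m,
        v_a * (t - t_pre),
        max_indentation - v_r * (t - t_pre - t_m),
    )
    p = PLRParams(E0=E0, beta=beta, tip=tip, poisson_ratio=poisson_ratio, t0=t0)
    F = ting_force_numerical(t, np.clip(delta, 0.0, None), p,
                             t_m=float(t_pre + t_m))
    d = F / spring_constant
    z0 = pre_contact
    z = z0 + delta + d
    if drag_b0 > 0:
        dz_dt = np.gradient(z, t)
        F_meas = F + drag_b0 * dz_dt
        d = F_meas / spring_constant
        z = z0 + delta + d
    if force_noise_fraction > 0:
        f_max = max(F.max(), 1e-15)
        d = d + rng.normal(
            0.0, force_noise_fraction * f_max / spring_constant, size=n
        )
    i_m = int(np.searchsorted(t, t_pre + t_m))
    app = Segment(kind=SegmentKind.APPROACH, t=t[: i_m + 1], z=z[: i_m + 1],
                  d=d[: i_m + 1])
    ret = Segment(kind=SegmentKind.RETRACT, t=t[i_m + 1:], z=z[i_m + 1:],
                  d=d[i_m + 1:])
    return ForceCurve(metadata=meta, segments=(app, ret))


def _default_gstar(G0: float = 1000.0, alpha: float = 0.2,
                   f0: float = 1.0) -> Callable[[float], complex]:
    """Single power-law complex modulus G*(f) = G0 (f/f0)^alpha e^{i pi alpha/2}."""

    def gstar(f: float) -> complex:
        return G0 * (f / f0) ** alpha * complex(
            math.cos(math.pi * alpha / 2), math.sin(math.pi * alpha / 2)
        )

    return gstar


def make_microrheo_curve(
    gstar: Optional[Callable[[float], complex]] = None,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    amplitude: float = 15e-9,
    delta0: float = 5e-7,
    tip: TipGeometry = DEFAULT_TIP,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    poisson_ratio: float = 0.5,
    n_cycles: int = 16,
    points_per_cycle: int = 64,
    deflection_noise: float = 0.0,
    piezo_lag_tau: float = 0.0,
    piezo_amp_quotient: float = 1.0,
    drag_b0: float = 0.0,
    seed: Optional[int] = None,
    file_id: str = "synthetic_microrheo",
) -> ForceCurve:
    """Multi-frequency oscillatory measurement on a viscoelastic sample.

    The response is synthesized from a target complex modulus ``gstar(f)``
    (default: single power law, G0 = 1 kPa at 1 Hz, exponent 0.2) through
    the paraboloid/pyramid contact prefactor. Optional contaminations:
    ``drag_b0`` adds the hydrodynamic i*omega*b0 term to the measured
    transfer function; ``piezo_lag_tau`` (s) and ``piezo_amp_quotient``
    emulate a first-order instrument lag, i.e. the recorded z leads the
    actual motion by atan(2 pi f tau) and over-reads its amplitude by
    1/piezo_amp_quotient (use :func:`make_glass_piezochar` with the same
    values to calibrate it away).
    """
    from .microrheology import _gstar_prefactor  # shared contact prefactor

    rng = np.random.default_rng(seed)
    gstar = gstar or _default_gstar()
    meta = _meta(tip, spring_constant, poisson_ratio, file_id)
    pref = _gstar_prefactor(meta, delta0)

    # Quasi-static approach to delta0 on an equivalent elastic sample.
    E_eq = 2.0 * (1.0 + poisson_ratio) * abs(gstar(1.0))
    p_eq = ElasticModelParams(E=E_eq, tip=tip, poisson_ratio=poisson_ratio)
    z0 = 1e-6
    d_end = _solve_deflection_elastic(np.array([delta0]), p_eq,
                                      spring_constant)[0]
    # travel past contact that yields indentation delta0
    n_app = 512
    fs_app = 2048.0
    t_app = np.arange(n_app) / fs_app
    z_app = np.linspace(0.0, z0 + delta0 + d_end, n_app)
    d_app = _solve_deflection_elastic(z_app - z0, p_eq, spring_constant)
    segs = [Segment(kind=SegmentKind.APPROACH, t=t_app, z=z_app, d=d_app)]

    F_static = elastic_force(np.array([delta0]), p_eq)[0]
    t_cursor = t_app[-1] + 1.0 / fs_app
    for f in frequencies:
        fs = f * points_per_cycle
        n = n_cycles * points_per_cycle
        t = t_cursor + np.arange(n) / fs
        w = 2.0 * math.pi * f
        X_delta = -1j * amplitude  # delta_ac = amplitude * sin(w t)
        H = gstar(f) / pref
        if drag_b0 > 0:
            H = H + 1j * w * drag_b0
        X_force = H * X_delta
        delta_ac = np.real(X_delta * np.exp(1j * w * (t - t_cursor)))
        F = F_static + np.real(X_force * np.exp(1j * w * (t - t_cursor)))
        d = F / spring_constant
        z_actual = z0 + delta0 + delta_ac + d
        z_ac = z_actual - np.mean(z_actual)
        if piezo_lag_tau > 0 or piezo_amp_quotient != 1.0:
            psi = math.atan(2.0 * math.pi * f * piezo_lag_tau)
            Xz = -1j * (amplitude + 0j)  # reconstruct in complex domain
            # recorded z_ac: actual amplitude / quotient, phase advanced psi
            coef = np.exp(1j * psi) / piezo_amp_quotient
            base = np.mean(z_actual)
            Xz_act = _lockin_complex(z_ac, w, t - t_cursor)
            z_rec = base + np.real(coef * Xz_act * np.exp(1j * w * (t - t_cursor)))
        else:
            z_rec = z_actual
        if deflection_noise > 0:
            d = d + rng.normal(0.0, deflection_noise, size=n)
        segs.append(
            Segment(kind=SegmentKind.MODULATION, t=t, z=z_rec, d=d,
                    drive_frequency=float(f))
        )
        t_cursor = t[-1] + 1.0 / fs
    return ForceCurve(metadata=meta, segments=tuple(segs))


def _lockin_complex(x: np.ndarray, w: float, t: np.ndarray) -> complex:
    basis = np.vstack([np.cos(w * t), np.sin(w * t), np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return complex(coef[0], -coef[1])


def make_glass_piezochar(
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    amplitude: float = 15e-9,
    piezo_lag_tau: float = 0.0,
    piezo_amp_quotient: float = 1.0,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    tip: TipGeometry = DEFAULT_TIP,
    n_cycles: int = 16,
    points_per_cycle: int = 64,
    deflection_noise: float = 0.0,
    seed: Optional[int] = None,
    file_id: str = "synthetic_piezochar",
) -> ForceCurve:
    """Oscillatory measurement on glass (rigid substrate).

    The deflection tracks the actual piezo motion exactly; with a
    first-order instrument lag the measured phase between recorded z and d
    is -atan(2 pi f tau) and the amplitude quotient is
    ``piezo_amp_quotient``.
    """
    rng = np.random.default_rng(seed)
    meta = _meta(tip, spring_constant, 0.5, file_id)
    n_app = 64
    t_app = np.arange(n_app) / 1024.0
    z_app = np.linspace(0.0, 1e-7, n_app)
    segs = [Segment(kind=SegmentKind.APPROACH, t=t_app, z=z_app, d=z_app.copy())]
    t_cursor = t_app[-1] + 1e-3
    for f in frequencies:
        fs = f * points_per_cycle
        n = n_cycles * points_per_cycle
        t = t_cursor + np.arange(n) / fs
        w = 2.0 * math.pi * f
        psi = math.atan(2.0 * math.pi * f * piezo_lag_tau)
        z_rec = amplitude * np.sin(w * (t - t_cursor))
        # actual motion: amplitude * quotient, delayed by psi
        d = piezo_amp_quotient * amplitude * np.sin(w * (t - t_cursor) - psi)
        if deflection_noise > 0:
            d = d + rng.normal(0.0, deflection_noise, size=n)
        segs.append(
            Segment(kind=SegmentKind.MODULATION, t=t, z=z_rec, d=d,
                    drive_frequency=float(f))
        )
        t_cursor = t[-1] + 1.0 / fs
    return ForceCurve(metadata=meta, segments=tuple(segs))


def make_vdrag_sweep(
    a_eff: float = 30e-6,
    h_eff: float = 5e-6,
    eta_fluid: float = ETA_WATER_25C,
    separations: Sequence[float] = (0.5e-6, 0.95e-6, 1.4e-6, 1.85e-6,
                                    2.3e-6, 2.75e-6),
    frequency: float = 500.0,
    amplitude: float = 15e-9,
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    tip: TipGeometry = DEFAULT_TIP,
    n_cycles: int = 32,
    points_per_cycle: int = 32,
    deflection_noise: float = 0.0,
    seed: Optional[int] = None,
    file_id: str = "synthetic_vdrag",
) -> ForceCurve:
    """Drag sweep: oscillations at several tip–sample separations.

    At each separation h the fluid exerts F = b(h) * (tip velocity) with
    b(h) from the scaled-sphere model, so the measured transfer function is
    i * 2 pi f * b(h).
    """
    rng = np.random.default_rng(seed)
    meta = _meta(tip, spring_constant, 0.5, file_id)
    n_app = 64
    t_app = np.arange(n_app) / 1024.0
    segs = [Segment(kind=SegmentKind.APPROACH, t=t_app,
                    z=np.linspace(0, 1e-7, n_app),
                    d=np.zeros(n_app))]
    t_cursor = t_app[-1] + 1e-3
    w = 2.0 * math.pi * frequency
    fs = frequency * points_per_cycle
    n = n_cycles * points_per_cycle
    for h in separations:
        b = float(drag_model_b(np.array([h]), a_eff, h_eff, eta_fluid)[0])
        t = t_cursor + np.arange(n) / fs
        tip_pos = amplitude * np.sin(w * (t - t_cursor))
        F = b * amplitude * w * np.cos(w * (t - t_cursor))
        d = F / spring_constant
        z = tip_pos + d
        if deflection_noise > 0:
            d = d + rng.normal(0.0, deflection_noise, size=n)
        segs.append(
            Segment(kind=SegmentKind.MODULATION, t=t, z=z, d=d,
                    drive_frequency=float(frequency), separation=float(h))
        )
        t_cursor = t[-1] + 1.0 / fs
    return ForceCurve(metadata=meta, segments=tuple(segs))


def make_thermal(
    f_R: float = 3000.0,
    Q: float = 2.0,
    B: float = 1e-4,
    a_white: float = 1e-5,
    f_range: tuple[float, float] = (500.0, 10000.0),
    n_bins: int = 1024,
    noise_fraction: float = 0.0,
    medium: str = "liquid",
    temperature: float = 298.0,
    seed: Optional[int] = None,
) -> ThermalSpectrum:
    """Thermal noise spectrum drawn from the SHO model (V^2/Hz).

    ``noise_fraction`` applies multiplicative Gaussian noise per bin.
    """
    rng = np.random.default_rng(seed)
    f = np.linspace(f_range[0], f_range[1], n_bins)
    S = sho_psd(f, a_white, B, f_R, Q)
    if noise_fraction > 0:
        S = S * np.clip(1.0 + rng.normal(0.0, noise_fraction, size=n_bins),
                        0.05, None)
    return ThermalSpectrum(f=f, S=S, unit="V^2/Hz", medium=medium,
                           temperature=temperature)
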