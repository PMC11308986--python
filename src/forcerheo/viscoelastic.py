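"""Time-domain viscoelasticity: power-law rheology and the Ting model.

The sample is a power-law rheology (PLR) half-space with relaxation modulus

    E(t) = E0 * (t / t0)^(-beta),

where ``E0`` is the instantaneous elastic modulus (scaling factor), ``beta``
the fluidity exponent (0 solid-like, 1 fluid-like) and ``t0`` a reference
time fixed at 1 s. Indentation with a rigid axisymmetric tip follows the
Ting hereditary-integral solution: on approach

    F(t) = (1/C) * INT_0^t E(t - xi) d(delta^p)/dxi dxi,

with p = 3/2 (paraboloid) or 2 (cone, pyramid) and C the geometry
coefficient; on retract the upper limit is the auxiliary time t1(t) defined
by the vanishing of INT_{t1}^{t} E(t - xi) d(delta)/dxi dxi. For constant
approach/retract speeds v_a, v_r this gives the closed form

    t1(t) = t - (1 + v_r/v_a)^(1/(1-beta)) * (t - t_m),

floored at zero, with t_m the time of maximum indentation.

Two force backends are provided: ``ting_force_numerical`` evaluates the
hereditary integral on an arbitrary sampled indentation history by exact
product integration of the weakly singular kernel against a
piecewise-linear delta^p, and ``ting_force_analytic`` evaluates the
constant-velocity closed forms (Gauss hypergeometric for the paraboloid
retract). The numerical backend is the oracle for the analytic one; the
two agree to better than 1% on constant-velocity ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma
from scipy.special import hyp2f1

from .contact import DEFAULT_ROV_WINDOW, estimate_poc
from .curves import ForceCurve, SegmentKind, TipGeometry, TipShape, force_indentation
from .elastic import ElasticModelParams, fit_elastic
from .stats import GofMetrics, gof_metrics

__all__ = [
    "PLRParams",
    "ViscoFitResult",
    "geometry_coefficient",
    "geometry_power",
    "plr_modulus",
    "t1_analytic",
    "t1_numerical",
    "ting_force_numerical",
    "ting_force_analytic",
    "drag_correct_fdc",
    "fit_viscoelastic",
    "BETA_MAX",
]

BETA_MAX = 0.9  # fit bound; retract kernels blow up toward beta -> 1


@dataclass(frozen=True)
class PLRParams:
    """Power-law rheology material plus tip geometry (strict SI)."""

    E0: float  # Pa
    beta: float  # fluidity exponent in [0, 1)
    tip: TipGeometry
    poisson_ratio: float = 0.5
    t0: float = 1.0  # s, reference time

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be > 0")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must be in [0, 1)")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")


@dataclass(frozen=True)
class ViscoFitResult:
    E0: float  # Pa
    beta: float
    poc_refined: float  # m
    force_offset: float  # N
    drag_b0: float  # N s/m correction applied (0 if none)
    gof: Optional[GofMetrics]
    model_name: str
    success: bool
    message: str = ""


def geometry_coefficient(tip: TipGeometry, nu: float) -> float:
    """Geometry coefficient C such that F_elastic = E * delta^p / C.

    Paraboloid: 3(1-nu^2)/(4 sqrt(R)); cone: pi(1-nu^2)/(2 tan(theta));
    four-sided pyramid: 1.342 (1-nu^2)/tan(theta).
    """
    one_minus = 1.0 - nu**2
    if tip.shape is TipShape.PARABOLOID:
        return 3.0 * one_minus / (4.0 * math.sqrt(tip.radius))
    if tip.shape is TipShape.CONE:
        return math.pi * one_minus / (2.0 * math.tan(tip.half_angle))
    return 1.342 * one_minus / math.tan(tip.half_angle)


def geometry_power(tip: TipGeometry) -> float:
    """Indentation exponent p: 3/2 for a paraboloid, 2 for cone/pyramid."""
    return 1.5 if tip.shape is TipShape.PARABOLOID else 2.0


def plr_modulus(t: np.ndarray, p: PLRParams) -> np.ndarray:
    """Relaxation modulus E(t) = E0 (t/t0)^(-beta) for t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    return p.E0 * (t / p.t0) ** (-p.beta)


def t1_analytic(
    t: np.ndarray, t_m: float, v_a: float, v_r: float, beta: float
) -> np.ndarray:
    """Closed-form auxiliary time t1 for constant-velocity ramps.

    t1 = t - (1 + v_r/v_a)^(1/(1-beta)) * (t - t_m), floored at 0; defined
    for t >= t_m (t1(t_m) = t_m).
    """
    if beta >= 1:
        raise ValueError("beta must be < 1")
    t = np.asarray(t, dtype=float)
    mult = (1.0 + v_r / v_a) ** (1.0 / (1.0 - beta))
    return np.clip(t - mult * (t - t_m), 0.0, None)


# ---------------------------------------------------------------------------
# Numerical backend: product integration of the weakly singular PLR kernel
# ---------------------------------------------------------------------------


def _segment_integral(tj: float, xi: np.ndarray, slopes: np.ndarray,
                      beta: float, upper: float) -> float:
    """INT_0^upper (tj - xi)^(-beta) g'(xi) dxi with g' piecewise constant.

    ``slopes`` holds g' on the cells of the grid ``xi``; each cell integral
    of the kernel is evaluated in closed form, so the weak singularity at
    xi -> tj is handled exactly.
    """
    lo = xi[:-1]
    hi = np.minimum(xi[1:], upper)
    m = (hi > lo) & (lo < tj)
    if not np.any(m):
        return 0.0
    a = tj - lo[m]
    b = np.maximum(tj - hi[m], 0.0)
    omb = 1.0 - beta
    w = (a**omb - b**omb) / omb
    return float(np.dot(slopes[m], w))


def t1_numerical(
    tj: float,
    xi: np.ndarray,
    delta: np.ndarray,
    beta: float,
    t_m: float,
    xtol_factor: float = 1e-3,
) -> float:
    """Auxiliary time t1 at retract time ``tj`` from the integral condition.

    Root of G(u) = INT_u^tj (tj - xi)^(-beta) delta'(xi) dxi, located by
    bisection (brentq) on [0, t_m] to ``xtol_factor`` of a sample interval.
    Returns 0 when the tip has fully unloaded (G(0) <= 0).
    """
    dxi = np.diff(xi)
    slopes = np.diff(delta) / dxi

    def g(u: float) -> float:
        total = _segment_integral(tj, xi, slopes, beta, tj)
        part = _segment_integral(tj, xi, slopes, beta, u)
        return total - part

    if g(0.0) <= 0.0:
        return 0.0
    g_tm = g(t_m)
    if g_tm >= 0.0:
        return t_m
    return float(brentq(g, 0.0, t_m, xtol=xtol_factor * float(dxi[0])))


def ting_force_numerical(
    t: np.ndarray,
    delta: np.ndarray,
    p: PLRParams,
    t_m: Optional[float] = None,
) -> np.ndarray:
    """Ting force on a uniformly sampled indentation history (both phases).

    ``delta`` is clipped at zero (out of contact); ``t_m`` defaults to the
    time of maximum indentation. For samples past ``t_m`` the auxiliary
    time t1 is found from the integral condition and the hereditary
    integral is truncated there; the force vanishes once t1 reaches 0.
    """
    t = np.asarray(t, dtype=float)
    delta = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    dt = np.diff(t)
    if dt.size == 0:
        raise ValueError("need at least 2 samples")
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("non-uniform time grid; resample first")
    i_m = int(np.argmax(delta))
    if t_m is None:
        t_m = float(t[i_m])
    C = geometry_coefficient(p.tip, p.poisson_ratio)
    power = geometry_power(p.tip)
    phi = delta**power
    slopes = np.diff(phi) / dt
    scale = p.E0 * p.t0**p.beta / C

    F = np.zeros_like(t)
    for j in range(1, len(t)):
        tj = float(t[j])
        if tj <= t_m:
            F[j] = scale * _segment_integral(tj, t, slopes, p.beta, tj)
        else:
            t1 = t1_numerical(tj, t, delta, p.beta, t_m)
            if t1 <= 0.0:
                F[j] = 0.0
            else:
                F[j] = scale * _segment_integral(tj, t, slopes, p.beta, t1)
    return F


# ---------------------------------------------------------------------------
# Analytic backend: constant-velocity closed forms
# ---------------------------------------------------------------------------


def ting_force_analytic(
    t: np.ndarray,
    p: PLRParams,
    v_a: float,
    v_r: float,
    t_m: float,
) -> np.ndarray:
    """Closed-form Ting force for a constant-velocity triangular ramp.

    Time is measured from contact (delta = v_a * t on approach). Paraboloid
    approach:

        F(t) = (v_a^{3/2}/C) E0 t0^beta (3 sqrt(pi) Gamma(1-beta))
               / (4 Gamma(5/2-beta)) t^{3/2-beta}

    paraboloid retract:

        F(t) = (1/C) E0 v_a^{3/2} (t/t0)^{-beta} t1^{3/2}
               2F1(3/2, beta; 5/2; t1/t)

    cone/pyramid approach:

        F(t) = (2 v_a^2/C) E0 t0^beta Gamma(2) Gamma(1-beta)/Gamma(3-beta)
               t^{2-beta}

    cone/pyramid retract (closed form of the hereditary integral; continuous
    with the approach branch at t = t_m and vanishing at t1 = 0):

        F(t) = 2 v_a^2 E0 t0^beta / (C (2-3beta+beta^2))
               [t^{2-beta} - (t-t1)^{1-beta} (t + (1-beta) t1)]
    """
    t = np.asarray(t, dtype=float)
    beta, E0, t0 = p.beta, p.E0, p.t0
    C = geometry_coefficient(p.tip, p.poisson_ratio)
    F = np.zeros_like(t)
    pos = t > 0
    app = pos & (t <= t_m)
    ret = t > t_m

    if p.tip.shape is TipShape.PARABOLOID:
        pref = (
            (v_a**1.5 / C) * E0 * t0**beta
            * 3.0 * math.sqrt(math.pi) * _gamma(1.0 - beta)
            / (4.0 * _gamma(2.5 - beta))
        )
        F[app] = pref * t[app] ** (1.5 - beta)
        if np.any(ret):
            tr = t[ret]
            t1 = t1_analytic(tr, t_m, v_a, v_r, beta)
            Fr = np.zeros_like(tr)
            inc = t1 > 0
            if np.any(inc):
                x = t1[inc] / tr[inc]
                Fr[inc] = (
                    (E0 * v_a**1.5 / C)
                    * (tr[inc] / t0) ** (-beta)
                    * t1[inc] ** 1.5
                    * hyp2f1(1.5, beta, 2.5, x)
                )
            F[ret] = Fr
    else:
        pref = (
            (2.0 * v_a**2 / C) * E0 * t0**beta
            * _gamma(2.0) * _gamma(1.0 - beta) / _gamma(3.0 - beta)
        )
        F[app] = pref * t[app] ** (2.0 - beta)
        if np.any(ret):
            tr = t[ret]
            t1 = t1_analytic(tr, t_m, v_a, v_r, beta)
            Fr = np.zeros_like(tr)
            inc = t1 > 0
            if np.any(inc):
                denom = 2.0 - 3.0 * beta + beta**2  # (1-beta)(2-beta)
                bracket = tr[inc] ** (2.0 - beta) - (
                    (tr[inc] - t1[inc]) ** (1.0 - beta)
                    * (tr[inc] + (1.0 - beta) * t1[inc])
                )
                Fr[inc] = 2.0 * v_a**2 * E0 * t0**beta / (C * denom) * bracket
            F[ret] = Fr
    return F


def drag_correct_fdc(
    force: np.ndarray, dz_dt: np.ndarray, b0: float
) -> np.ndarray:
    """Remove the hydrodynamic drag force b0 * (dz/dt) from a force trace.

    The correction changes sign automatically between approach and retract
    because the piezo velocity does.
    """
    if b0 < 0:
        raise ValueError("b0 must be >= 0")
    return np.asarray(force, dtype=float) - b0 * np.asarray(dz_dt, dtype=float)


# ---------------------------------------------------------------------------
# Default viscoelastic routine
# ---------------------------------------------------------------------------

N_RESAMPLE = 512  # uniform grid size for the numerical backend


def _estimate_speed(t: np.ndarray, x: np.ndarray) -> float:
    """Least-squares slope of x(t)."""
    A = np.vstack([t - t.mean(), np.ones_like(t)]).T
    sol, *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(sol[0])


def fit_viscoelastic(
    curve: ForceCurve,
    model: str = "analytic",
    b0: float = 0.0,
    rov_window: int = DEFAULT_ROV_WINDOW,
    t0: float = 1.0,
    beta_max: float = BETA_MAX,
) -> ViscoFitResult:
    """Default viscoelastic routine on an approach–retract cycle.

    1.–3. preprocess and estimate the point of contact (RoV); 4. elastic
    pre-fit of the approach seeds E0 and refines the PoC; 5. least squares
    of (E0, beta, contact-time/PoC shift, force offset) on the force vs
    time trace over the full cycle, with either the analytic
    (constant-velocity) or the numerical (measured-history) Ting backend.
    If ``b0`` > 0 the viscous drag force b0*dz/dt is subtracted from the
    measured force before fitting.
    """
    if model not in ("analytic", "numerical"):
        raise ValueError(f"unknown backend {model!r}")
    meta = curve.metadata
    approach = curve.approach
    retracts = curve.get_segments(SegmentKind.RETRACT)
    if not retracts:
        raise ValueError("viscoelastic routine needs approach + retract")
    retract = retracts[0]

    z0, d0 = estimate_poc(approach, rov_window)
    fi_app = force_indentation(approach, meta, (z0, d0))
    pre = fit_elastic(
        fi_app,
        ElasticModelParams(E=1000.0, tip=meta.tip, poisson_ratio=meta.poisson_ratio),
        model_name={
            TipShape.PARABOLOID: "hertz_paraboloid",
            TipShape.CONE: "hertz_cone",
            TipShape.PYRAMID: "hertz_pyramid",
        }[meta.tip.shape],
    )
    E0_init = pre.E if pre.success and np.isfinite(pre.E) else 1000.0
    shift0 = pre.poc_refined - z0 if pre.success else 0.0

    # Full-cycle arrays referenced to the RoV PoC.
    t_full = np.concatenate([approach.t, retract.t])
    z_full = np.concatenate([approach.z, retract.z])
    d_full = np.concatenate([approach.d, retract.d])
    order = np.argsort(t_full)
    t_full, z_full, d_full = t_full[order], z_full[order], d_full[order]
    delta_meas = (z_full - z0) - (d_full - d0)
    F_meas = meta.spring_constant * (d_full - d0)
    if b0 > 0:
        dz_dt = np.gradient(z_full, t_full)
        F_meas = drag_correct_fdc(F_meas, dz_dt, b0)

    # Resample to a uniform grid.
    tu = np.linspace(t_full[0], t_full[-1], N_RESAMPLE)
    delta_u = np.interp(tu, t_full, delta_meas)
    F_u = np.interp(tu, t_full, F_meas)
    tu = tu - tu[0]

    i_m = int(np.argmax(delta_u))
    t_m = float(tu[i_m])
    contact_app = (delta_u > 0) & (tu <= t_m)
    if contact_app.sum() >= 4:
        v_a = abs(_estimate_speed(tu[contact_app], delta_u[contact_app]))
    else:
        v_a = abs(_estimate_speed(tu[: max(i_m, 4)], delta_u[: max(i_m, 4)]))
    post = tu > t_m
    v_r = abs(_estimate_speed(tu[post], delta_u[post])) if post.sum() >= 4 else v_a

    dspan = float(np.ptp(delta_u))
    # contact time implied by the RoV PoC + elastic refinement
    above = delta_u - shift0 > 0
    t_c0 = float(tu[np.argmax(above)]) if np.any(above) else 0.5 * t_m
    params = lmfit.Parameters()
    params.add("E0", value=max(E0_init, 1e-2), min=1e-2, max=1e9)
    params.add("beta", value=0.2, min=0.0, max=beta_max)
    if model == "numerical":
        params.add("dshift", value=shift0, min=shift0 - 0.25 * dspan,
                   max=shift0 + 0.25 * dspan)
    else:
        params.add("t_c", value=t_c0, min=0.0, max=0.95 * t_m)
        # the apex time is only known to the sample grid; refining it keeps
        # the auxiliary-time map (and hence E0) unbiased
        params.add("t_m", value=t_m, min=0.9 * t_m, max=1.1 * t_m)
    params.add("offset", value=0.0)

    def model_force(pars: lmfit.Parameters) -> np.ndarray:
        p = PLRParams(
            E0=pars["E0"].value, beta=pars["beta"].value, tip=meta.tip,
            poisson_ratio=meta.poisson_ratio, t0=t0,
        )
        if model == "numerical":
            dmod = np.clip(delta_u - pars["dshift"].value, 0.0, None)
            Fm = ting_force_numerical(tu, dmod, p)
        else:
            # constant-velocity idealization: time measured from contact
            t_c = pars["t_c"].value
            Fm = ting_force_analytic(tu - t_c, p, v_a, v_r,
                                     pars["t_m"].value - t_c)
        return Fm + pars["offset"].value

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        return model_force(pars) - F_u

    try:
        out = lmfit.minimize(residual, params, method="leastsq")
    except Exception as exc:  # pragma: no cover
        return ViscoFitResult(
            E0=float("nan"), beta=float("nan"), poc_refined=z0,
            force_offset=float("nan"), drag_b0=b0, gof=None,
            model_name=model, success=False, message=str(exc),
        )
    if not out.success:
        return ViscoFitResult(
            E0=float("nan"), beta=float("nan"), poc_refined=z0,
            force_offset=float("nan"), drag_b0=b0, gof=None,
            model_name=model, success=False, message=out.message,
        )
    F_hat = model_force(out.params)
    if model == "numerical":
        poc_shift = float(out.params["dshift"].value)
    else:
        # indentation offset at the fitted contact time
        poc_shift = float(np.interp(out.params["t_c"].value, tu, delta_u))
    return ViscoFitResult(
        E0=float(out.params["E0"].value),
        beta=float(out.params["beta"].value),
        poc_refined=z0 + poc_shift,
        force_offset=float(out.params["offset"].value),
        drag_b0=b0,
        gof=gof_metrics(F_u, F_hat, sum(p.vary for p in out.params.values())),
        model_name=model,
        success=True,
    )
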