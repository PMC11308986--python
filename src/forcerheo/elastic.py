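"""Elastic contact models and the default elastic fitting routine.

Closed-form force–indentation laws for the standard AFM tip geometries
(Hertz paraboloid, cone, four-sided pyramid, DMT adhesion), the
Garcia–Garcia bottom-effect corrections for samples of finite thickness h
bonded to a rigid support, and the Kontomaris spherical approximation.

The default routine mirrors standard AFM practice: estimate the point of
contact by ratio-of-variances, build force vs indentation, then refine
(E, contact-point shift, force offset) by Levenberg–Marquardt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

from .contact import DEFAULT_ROV_WINDOW, estimate_poc
from .curves import (
    CurveMetadata,
    ForceCurve,
    ForceIndentation,
    TipGeometry,
    TipShape,
    force_indentation,
)
from .stats import GofMetrics, gof_metrics

__all__ = [
    "ElasticModelParams",
    "ElasticFitResult",
    "elastic_force",
    "bottom_effect_force",
    "kontomaris_force",
    "fit_elastic",
    "fit_elastic_curve",
    "PYRAMID_PREFACTOR_BILODEAU",
]

# Pyramid prefactor constant c in F = c * tan(theta) * E/(1-nu^2) * delta^2.
# The Bilodeau four-sided pyramid gives c = 1/sqrt(2); some sources print 1/2.
PYRAMID_PREFACTOR_BILODEAU = 1.0 / math.sqrt(2.0)

# Garcia–Garcia bottom-effect bracket coefficients, F = F0 * (1 + sum a_i x^i)
# with x = sqrt(R*delta)/h (paraboloid) or x = delta*tan(theta)/h (cone and
# pyramid share one bracket).
_BEC_PARABOLOID = (1.133, 1.497, 1.469, 0.755)
_BEC_CONE = (0.721, 0.650, 0.491, 0.225)

# Kontomaris spherical-indenter series coefficients.
_KONTOMARIS_C = (1.01, -0.07303, -0.1357, 0.03598, -0.004024, 0.0001653)


@dataclass(frozen=True)
class ElasticModelParams:
    """Parameters of an elastic force–indentation law (strict SI)."""

    E: float  # Pa
    tip: TipGeometry
    poisson_ratio: float = 0.5
    delta0_shift: float = 0.0  # m, contact-point refinement offset
    force_offset: float = 0.0  # N
    thickness: Optional[float] = None  # m, bottom-effect models
    adhesion_force: float = 0.0  # N, DMT
    pyramid_prefactor: float = PYRAMID_PREFACTOR_BILODEAU

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("thickness must be > 0")


@dataclass(frozen=True)
class ElasticFitResult:
    E: float  # Pa (NaN if the fit failed)
    poc_refined: float  # m, refined contact z-position
    force_offset: float  # N
    gof: Optional[GofMetrics]
    n_points: int
    model_name: str
    success: bool
    message: str = ""


def _hertz_prefactor(tip: TipGeometry, nu: float, pyramid_prefactor: float) -> tuple[float, float]:
    """Return (C, p) such that F = C * E * delta**p."""
    one_minus = 1.0 - nu**2
    if tip.shape is TipShape.PARABOLOID:
        return 4.0 * math.sqrt(tip.radius) / (3.0 * one_minus), 1.5
    if tip.shape is TipShape.CONE:
        return 2.0 * math.tan(tip.half_angle) / (math.pi * one_minus), 2.0
    return pyramid_prefactor * math.tan(tip.half_angle) / one_minus, 2.0


def elastic_force(delta: np.ndarray, p: ElasticModelParams) -> np.ndarray:
    """Elastic contact force at indentation ``delta`` (negative delta -> 0).

    Paraboloid: F = 4 sqrt(R) E delta^{3/2} / (3 (1 - nu^2))
    Cone:       F = 2 tan(theta) E delta^2 / (pi (1 - nu^2))
    Pyramid:    F = tan(theta) E delta^2 / (sqrt(2) (1 - nu^2))

    A constant DMT adhesion force is added everywhere (in contact it adds to
    the Hertz force, out of contact the tip feels adhesion alone); the fitted
    ``force_offset`` is added on top.
    """
    delta = np.asarray(delta, dtype=float)
    C, power = _hertz_prefactor(p.tip, p.poisson_ratio, p.pyramid_prefactor)
    dc = np.clip(delta, 0.0, None)
    return C * p.E * dc**power + p.adhesion_force + p.force_offset


def bottom_effect_force(delta: np.ndarray, p: ElasticModelParams) -> np.ndarray:
    """Garcia–Garcia bottom-effect corrected force for finite thickness h.

    F = F0(delta) * (1 + a1 x + a2 x^2 + a3 x^3 + a4 x^4) with
    x = sqrt(R delta)/h (paraboloid, a = 1.133, 1.497, 1.469, 0.755) or
    x = delta tan(theta)/h (cone and pyramid share a = 0.721, 0.650, 0.491,
    0.225); F0 is the corresponding infinite-thickness law. The correction
    is >= 1 and tends to 1 as h -> inf.
    """
    if p.thickness is None or p.thickness <= 0:
        raise ValueError("bottom-effect model requires thickness > 0")
    delta = np.asarray(delta, dtype=float)
    dc = np.clip(delta, 0.0, None)
    if p.tip.shape is TipShape.PARABOLOID:
        x = np.sqrt(p.tip.radius * dc) / p.thickness
        a = _BEC_PARABOLOID
    else:
        x = dc * math.tan(p.tip.half_angle) / p.thickness
        a = _BEC_CONE
    bracket = 1.0 + a[0] * x + a[1] * x**2 + a[2] * x**3 + a[3] * x**4
    C, power = _hertz_prefactor(p.tip, p.poisson_ratio, p.pyramid_prefactor)
    return C * p.E * dc**power * bracket + p.force_offset


def kontomaris_force(delta: np.ndarray, p: ElasticModelParams) -> np.ndarray:
    """Kontomaris approximation for a spherical indenter (deep indentation).

    F = 2 E R / (1 - nu^2) * [ (2/3) c1 (delta/R)^{1/2} delta
        + sum_{n=2..6} (1/n) c_n (delta/R)^{n-1} delta ]
    with the printed coefficients c1..c6. Small-indentation limit is
    c1 * Hertz (c1 = 1.01).
    """
    if p.tip.shape is not TipShape.PARABOLOID:
        raise ValueError("Kontomaris model applies to spherical (paraboloid) tips")
    delta = np.asarray(delta, dtype=float)
    dc = np.clip(delta, 0.0, None)
    R = p.tip.radius
    c = _KONTOMARIS_C
    series = (2.0 / 3.0) * c[0] * R ** (-0.5) * dc**1.5
    for n in range(2, 7):
        series = series + (1.0 / n) * c[n - 1] * R ** (1 - n) * dc**n
    return 2.0 * p.E * R / (1.0 - p.poisson_ratio**2) * series + p.force_offset


_MODEL_FUNCS = {
    "hertz_paraboloid": elastic_force,
    "hertz_cone": elastic_force,
    "hertz_pyramid": elastic_force,
    "dmt": elastic_force,
    "bec_paraboloid": bottom_effect_force,
    "bec_cone": bottom_effect_force,
    "bec_pyramid": bottom_effect_force,
    "kontomaris": kontomaris_force,
}

_MODEL_SHAPES = {
    "hertz_paraboloid": TipShape.PARABOLOID,
    "hertz_cone": TipShape.CONE,
    "hertz_pyramid": TipShape.PYRAMID,
    "dmt": TipShape.PARABOLOID,
    "bec_paraboloid": TipShape.PARABOLOID,
    "bec_cone": TipShape.CONE,
    "bec_pyramid": TipShape.PYRAMID,
    "kontomaris": TipShape.PARABOLOID,
}

E_BOUNDS = (1e-2, 1e9)  # Pa


def fit_elastic(
    fi: ForceIndentation,
    p0: ElasticModelParams,
    fit_range: Optional[tuple[float, float]] = None,
    model_name: str = "hertz_paraboloid",
    fit_adhesion: bool = False,
) -> ElasticFitResult:
    """Fit an elastic model to a force–indentation curve.

    Free parameters: E, a contact-point shift ``delta0_shift`` and a force
    offset, minimized by Levenberg–Marquardt. Samples that fall below the
    (shifted) contact point contribute the offset only, so the refinement
    can move through them. ``fit_range`` is (delta_min, delta_max) in m on
    the incoming indentation axis; default is the full contact region.

    Non-convergence returns a flagged result with NaN E, never a silent
    value.
    """
    if model_name not in _MODEL_FUNCS:
        raise ValueError(f"unknown elastic model {model_name!r}")
    if _MODEL_SHAPES[model_name] is not p0.tip.shape:
        raise ValueError(
            f"model {model_name!r} expects a "
            f"{_MODEL_SHAPES[model_name].value} tip, got {p0.tip.shape.value}"
        )
    func = _MODEL_FUNCS[model_name]

    delta = np.asarray(fi.delta, dtype=float)
    force = np.asarray(fi.force, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        mask = (delta >= lo) & (delta <= hi)
    else:
        mask = np.ones_like(delta, dtype=bool)
    delta, force = delta[mask], force[mask]
    n_free = 4 if fit_adhesion else 3
    if delta.size < max(10, n_free + 1):
        raise ValueError("fewer than 10 points in the fit range")

    params = lmfit.Parameters()
    params.add("E", value=max(p0.E, E_BOUNDS[0]), min=E_BOUNDS[0], max=E_BOUNDS[1])
    dspan = max(delta.max() - delta.min(), 1e-12)
    params.add("shift", value=p0.delta0_shift, min=-dspan, max=dspan)
    params.add("offset", value=p0.force_offset)
    if fit_adhesion:
        params.add("f_adh", value=p0.adhesion_force)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        p = ElasticModelParams(
            E=pars["E"].value,
            tip=p0.tip,
            poisson_ratio=p0.poisson_ratio,
            force_offset=pars["offset"].value,
            thickness=p0.thickness,
            adhesion_force=pars["f_adh"].value if fit_adhesion else p0.adhesion_force,
            pyramid_prefactor=p0.pyramid_prefactor,
        )
        return func(delta - pars["shift"].value, p) - force

    try:
        out = lmfit.minimize(residual, params, method="leastsq")
    except Exception as exc:  # pragma: no cover - lmfit raises rarely
        return ElasticFitResult(
            E=float("nan"), poc_refined=fi.poc_z, force_offset=float("nan"),
            gof=None, n_points=delta.size, model_name=model_name,
            success=False, message=str(exc),
        )
    if not out.success:
        return ElasticFitResult(
            E=float("nan"), poc_refined=fi.poc_z, force_offset=float("nan"),
            gof=None, n_points=delta.size, model_name=model_name,
            success=False, message=out.message,
        )
    y_hat = residual(out.params) + force
    return ElasticFitResult(
        E=float(out.params["E"].value),
        poc_refined=fi.poc_z + float(out.params["shift"].value),
        force_offset=float(out.params["offset"].value),
        gof=gof_metrics(force, y_hat, n_free),
        n_points=delta.size,
        model_name=model_name,
        success=True,
    )


def fit_elastic_curve(
    curve: ForceCurve,
    model_name: str = "hertz_paraboloid",
    rov_window: int = DEFAULT_ROV_WINDOW,
    fit_range: Optional[tuple[float, float]] = None,
    thickness: Optional[float] = None,
    E_init: float = 1000.0,
) -> ElasticFitResult:
    """Default elastic routine on a full force curve.

    1. preprocess z, d to tip position; 2. RoV point of contact; 3. build
    force vs indentation from the approach segment; 4.–5. model fit refining
    (E, PoC, force offset).
    """
    seg = curve.approach
    meta: CurveMetadata = curve.metadata
    poc = estimate_poc(seg, rov_window)
    fi = force_indentation(seg, meta, poc)
    p0 = ElasticModelParams(
        E=E_init, tip=meta.tip, poisson_ratio=meta.poisson_ratio,
        thickness=thickness,
    )
    return fit_elastic(fi, p0, fit_range=fit_range, model_name=model_name)
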