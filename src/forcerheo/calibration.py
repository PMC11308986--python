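"""Non-contact cantilever calibration from thermal noise spectra.

Three steps: (1) a simple-harmonic-oscillator (SHO) fit to the first
eigenmode peak of the thermal power spectral density,

    S_SHO(f) = A_white^2 + B^2 f_R^4 / (Q^2 [(f^2 - f_R^2)^2 + f^2 f_R^2 / Q^2]),

yielding the white-noise floor, peak amplitude B, resonance frequency f_R
and quality factor Q; (2) the Sader spring constant for rectangular
cantilevers,

    k = 0.1906 rho b^2 L Gamma_i(omega_R) omega_R^2 Q,

with rho the fluid density, b and L the plan-view width and length and
Gamma_i the imaginary part of the hydrodynamic function of an oscillating
beam (circular-cylinder kernel with a modified-Bessel-function ratio times
the standard rational correction in Reynolds number Re = rho omega b^2 /
(4 eta)); (3) the thermal (non-contact) deflection sensitivity: equating
the equipartition mean-square displacement k_B T / k to the fitted peak's
integrated power pi B^2 f_R / (2 Q) in V^2 gives

    invOLS = sqrt(k_B T / k) / sqrt(pi B^2 f_R / (2 Q)) * correction_factor

with default shape correction factors 0.90 (rectangular) and 0.87
(V-shaped) accounting for static-vs-dynamic deflection and the fundamental
mode shape.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np
from scipy.constants import k as K_BOLTZMANN
from scipy.special import kv

from .stats import GofMetrics, gof_metrics

__all__ = [
    "Medium",
    "CantileverShape",
    "ThermalSpectrum",
    "SHOFit",
    "CantileverPlan",
    "CalibrationResult",
    "read_thermal_spectrum",
    "sho_psd",
    "fit_sho",
    "hydrodynamic_function",
    "sader_spring_constant",
    "thermal_invols",
    "calibrate",
]


class Medium(str, enum.Enum):
    AIR = "air"
    LIQUID = "liquid"


class CantileverShape(str, enum.Enum):
    RECTANGULAR = "rectangular"
    V_SHAPED = "v_shaped"


#: Default beta/chi correction factors for the thermal deflection sensitivity.
DEFAULT_CORRECTION = {
    CantileverShape.RECTANGULAR: 0.90,
    CantileverShape.V_SHAPED: 0.87,
}


@dataclass(frozen=True)
class ThermalSpectrum:
    f: np.ndarray  # Hz, increasing
    S: np.ndarray  # PSD
    unit: str = "V^2/Hz"  # or "m^2/Hz"
    medium: Medium = Medium.LIQUID
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        S = np.asarray(self.S, dtype=float)
        if np.any(np.diff(f) <= 0) or np.any(f <= 0):
            raise ValueError("f must be positive and increasing")
        if np.any(S < 0):
            raise ValueError("PSD must be >= 0")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "medium", Medium(self.medium))


@dataclass(frozen=True)
class SHOFit:
    a_white: float  # sqrt-PSD white noise floor
    B: float  # peak amplitude parameter
    f_R: float  # Hz
    Q: float
    gof: Optional[GofMetrics]
    success: bool
    message: str = ""


@dataclass(frozen=True)
class CantileverPlan:
    """Cantilever plan-view geometry and fluid properties for Sader."""

    shape: CantileverShape
    width: float  # m, plan-view width b
    length: float  # m
    fluid_density: float = 997.0  # kg/m^3
    fluid_viscosity: float = 8.9e-4  # Pa s
    correction_factor: Optional[float] = None  # default per shape

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", CantileverShape(self.shape))
        if self.width <= 0 or self.length <= 0:
            raise ValueError("width and length must be > 0")
        cf = self.correction_factor
        if cf is not None and not 0.5 < cf < 1.1:
            raise ValueError("correction_factor must be in (0.5, 1.1)")

    @property
    def effective_correction(self) -> float:
        if self.correction_factor is not None:
            return self.correction_factor
        return DEFAULT_CORRECTION[self.shape]


@dataclass(frozen=True)
class CalibrationResult:
    spring_constant: float  # N/m
    invols: float  # m/V
    sho: SHOFit
    method: str


def read_thermal_spectrum(path: str | os.PathLike) -> ThermalSpectrum:
    """Read a two-column (f, PSD) text file with '# key: value' headers.

    Recognized header keys: unit (V^2/Hz or m^2/Hz), medium (air/liquid),
    temperature_K.
    """
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, val = line.lstrip("#").strip().partition(":")
                if sep:
                    header[key.strip()] = val.strip()
            else:
                a, b = line.split()[:2]
                rows.append((float(a), float(b)))
    arr = np.asarray(rows)
    return ThermalSpectrum(
        f=arr[:, 0],
        S=arr[:, 1],
        unit=header.get("unit", "V^2/Hz"),
        medium=header.get("medium", "liquid"),
        temperature=float(header.get("temperature_K", 298.0)),
    )


def sho_psd(
    f: np.ndarray, a_white: float, B: float, f_R: float, Q: float
) -> np.ndarray:
    """SHO thermal power spectral density (peak height above floor is B^2)."""
    f = np.asarray(f, dtype=float)
    denom = (f**2 - f_R**2) ** 2 + (f * f_R / Q) ** 2
    return a_white**2 + B**2 * f_R**4 / (Q**2 * denom)


def fit_sho(
    spec: ThermalSpectrum,
    f_window: Optional[tuple[float, float]] = None,
) -> SHOFit:
    """Fit the SHO model to the first eigenmode peak of a thermal spectrum.

    Initial f_R is the maximum bin inside the window; Q starts at 3 in
    liquid, 100 in air. A peak lower than 3x the white floor raises a
    no-resolvable-peak error.
    """
    f, S = spec.f, spec.S
    if f_window is not None:
        m = (f >= f_window[0]) & (f <= f_window[1])
        f, S = f[m], S[m]
    if len(f) < 50:
        raise ValueError("need >= 50 spectral bins in the fit window")
    floor = float(np.median(S))
    i_pk = int(np.argmax(S))
    peak = float(S[i_pk])
    if peak < 3.0 * floor:
        raise ValueError("no resolvable peak (peak < 3x white-noise floor)")
    f_R0 = float(f[i_pk])
    Q0 = 3.0 if spec.medium is Medium.LIQUID else 100.0
    B0 = math.sqrt(max(peak - floor, 1e-30))
    aw0 = math.sqrt(max(floor, 1e-30))

    params = lmfit.Parameters()
    params.add("a_white", value=aw0, min=0.0)
    params.add("B", value=B0, min=1e-30)
    params.add("f_R", value=f_R0, min=f[0], max=f[-1])
    params.add("Q", value=Q0, min=0.1, max=1e5)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return sho_psd(f, p["a_white"].value, p["B"].value,
                       p["f_R"].value, p["Q"].value) - S

    out = lmfit.minimize(residual, params, method="leastsq")
    ok = bool(out.success)
    y_hat = residual(out.params) + S
    return SHOFit(
        a_white=float(out.params["a_white"].value),
        B=float(out.params["B"].value),
        f_R=float(out.params["f_R"].value),
        Q=float(out.params["Q"].value),
        gof=gof_metrics(S, y_hat, 4) if ok else None,
        success=ok,
        message="" if ok else out.message,
    )


# Rational correction Omega(tau), tau = log10(Re), turning the circular
# cylinder hydrodynamic function into the rectangular-beam one.
_OMEGA_RE_NUM = (0.91324, -0.48274, 0.46842, -0.12886, 0.044055, -0.0035117,
                 0.00069085)
_OMEGA_RE_DEN = (1.0, -0.56964, 0.48690, -0.13444, 0.045155, -0.0035862,
                 0.00069085)
_OMEGA_IM_NUM = (-0.024134, -0.029256, 0.016294, -0.00010961, 0.000064577,
                 -0.000044510, 0.0)
_OMEGA_IM_DEN = (1.0, -0.59702, 0.55182, -0.18357, 0.079156, -0.014369,
                 0.0028361)


def _poly(coeffs: tuple[float, ...], x: float) -> float:
    return sum(c * x**i for i, c in enumerate(coeffs))


def hydrodynamic_function(omega: float, width: float,
                          rho: float, eta: float) -> complex:
    """Hydrodynamic function Gamma(omega) of a rectangular beam in fluid.

    Circular-cylinder kernel Gamma_circ = 1 + 4 i K1(-i sqrt(i Re)) /
    (sqrt(i Re) K0(-i sqrt(i Re))) with Re = rho omega width^2 / (4 eta),
    multiplied by the standard rational correction Omega(log10 Re) for the
    rectangular plan view.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    re = rho * omega * width**2 / (4.0 * eta)
    z = np.sqrt(1j * re)
    gamma_circ = 1.0 + 4.0j * kv(1, -1j * z) / (z * kv(0, -1j * z))
    tau = math.log10(re)
    omega_corr = complex(
        _poly(_OMEGA_RE_NUM, tau) / _poly(_OMEGA_RE_DEN, tau),
        _poly(_OMEGA_IM_NUM, tau) / _poly(_OMEGA_IM_DEN, tau),
    )
    return complex(omega_corr * gamma_circ)


def sader_spring_constant(
    plan: CantileverPlan,
    f_R: float,
    Q: float,
    gamma_imag: Optional[float] = None,
) -> float:
    """Sader spring constant of a rectangular cantilever.

    k = 0.1906 rho b^2 L Gamma_i(omega_R) omega_R^2 Q with omega_R = 2 pi
    f_R. ``gamma_imag`` overrides the computed imaginary hydrodynamic
    function (test hook). Only the rectangular formula is implemented; for
    other shapes use an externally supplied spring constant (e.g. the GCI
    virtual instrument).
    """
    if plan.shape is not CantileverShape.RECTANGULAR:
        raise ValueError(
            "Sader rectangular formula does not apply to this shape; "
            "supply an external spring constant instead"
        )
    if Q <= 0.5:
        raise ValueError("Sader method needs Q > 0.5")
    omega_r = 2.0 * math.pi * f_R
    if gamma_imag is None:
        gamma_imag = hydrodynamic_function(
            omega_r, plan.width, plan.fluid_density, plan.fluid_viscosity
        ).imag
    return (
        0.1906 * plan.fluid_density * plan.width**2 * plan.length
        * gamma_imag * omega_r**2 * Q
    )


def thermal_invols(
    sho: SHOFit,
    k: float,
    temperature: float,
    plan: CantileverPlan,
) -> float:
    """Thermal (non-contact) deflection sensitivity in m/V.

    Equipartition fixes the mean-square thermal displacement at k_B T / k
    (m^2); the SHO fit measures the same quantity in V^2 as the integrated
    peak power pi B^2 f_R / (2 Q). Their square-root ratio, times the
    shape correction factor, is the deflection sensitivity.
    """
    if k <= 0:
        raise ValueError("spring constant must be > 0")
    power_v2 = math.pi * sho.B**2 * sho.f_R / (2.0 * sho.Q)
    raw = math.sqrt(K_BOLTZMANN * temperature / k) / math.sqrt(power_v2)
    return raw * plan.effective_correction


def calibrate(
    spec: ThermalSpectrum,
    plan: CantileverPlan,
    f_window: Optional[tuple[float, float]] = None,
    external_k: Optional[float] = None,
) -> CalibrationResult:
    """Full non-contact calibration: SHO fit, spring constant, invOLS.

    ``external_k`` (e.g. from the GCI virtual instrument) bypasses the
    Sader formula and is required for non-rectangular cantilevers.
    """
    if spec.unit != "V^2/Hz":
        raise ValueError("thermal invOLS needs a volt-calibrated spectrum (V^2/Hz)")
    sho = fit_sho(spec, f_window)
    if external_k is not None:
        k, method = external_k, "external"
    else:
        k, method = sader_spring_constant(plan, sho.f_R, sho.Q), "sader"
    invols = thermal_invols(sho, k, spec.temperature, plan)
    return CalibrationResult(spring_constant=k, invols=invols, sho=sho,
                             method=method)
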