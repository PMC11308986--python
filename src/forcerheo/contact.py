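"""Contact-point detection by the ratio-of-variances (RoV) statistic.

Before the tip touches the sample the deflection signal is flat (noise
only); after contact it rises steeply. At each sample i the ratio of the
deflection variance in a short window just after i to the variance in a
short window just before i therefore peaks at the point of contact:

    RoV_i = var(d[i+1 .. i+N]) / var(d[i-N .. i-1])

with N the window size. Population (1/N) variance is used throughout; the
ratio is unaffected but the choice is fixed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import Segment

__all__ = ["RovResult", "rov_series", "estimate_poc", "DEFAULT_ROV_WINDOW"]

DEFAULT_ROV_WINDOW = 20
#: Denominator guard (m^2): windows with variance below this yield RoV = 0.
EPS_VAR = 1e-24


@dataclass(frozen=True)
class RovResult:
    rov: np.ndarray  # RoV_i for N <= i < len(d) - N, else 0
    index: int  # argmax (smallest index on ties)
    z0: float  # m
    d0: float  # m
    window: int


def rov_series(d: np.ndarray, window: int = DEFAULT_ROV_WINDOW) -> np.ndarray:
    """Ratio-of-variances series of a deflection signal.

    Entries outside the valid range ``window <= i < len(d) - window`` and
    entries whose trailing-window variance falls below the guard are 0.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    N = int(window)
    if N < 2:
        raise ValueError("window must be >= 2")
    if n < 2 * N + 2:
        raise ValueError(
            f"signal too short for RoV: need >= {2 * N + 2} samples, got {n}"
        )
    # Rolling population variances via cumulative sums.
    c1 = np.concatenate(([0.0], np.cumsum(d)))
    c2 = np.concatenate(([0.0], np.cumsum(d * d)))

    def win_var(start: np.ndarray) -> np.ndarray:
        # population variance of d[start : start+N]
        s1 = c1[start + N] - c1[start]
        s2 = c2[start + N] - c2[start]
        return np.maximum(s2 / N - (s1 / N) ** 2, 0.0)

    idx = np.arange(N, n - N)
    var_after = win_var(idx + 1)
    var_before = win_var(idx - N)
    rov = np.zeros(n)
    ok = var_before >= EPS_VAR
    rov[idx[ok]] = var_after[ok] / var_before[ok]
    return rov


def estimate_poc(
    approach: Segment, window: int = DEFAULT_ROV_WINDOW
) -> tuple[float, float]:
    """Estimate the point of contact (z0, d0) of an approach segment.

    Returns the piezo position and deflection at the RoV maximum; ties break
    to the smallest index (earliest contact).
    """
    res = rov_result(approach, window)
    return res.z0, res.d0


def rov_result(approach: Segment, window: int = DEFAULT_ROV_WINDOW) -> RovResult:
    """Full RoV diagnostics for an approach segment."""
    rov = rov_series(approach.d, window)
    i_star = int(np.argmax(rov))  # argmax returns first occurrence on ties
    return RovResult(
        rov=rov,
        index=i_star,
        z0=float(approach.z[i_star]),
        d0=float(approach.d[i_star]),
        window=int(window),
    )
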