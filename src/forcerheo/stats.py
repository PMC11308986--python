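"""Goodness-of-fit metrics and bootstrap uncertainty for fit results."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GofMetrics", "gof_metrics", "bootstrap_median_ci"]


@dataclass(frozen=True)
class GofMetrics:
    """Regression diagnostics in the data's native units.

    chi2 uses unit weights unless a per-point noise estimate was supplied to
    :func:`gof_metrics`; chi2_reduced divides by nu = n - n_params.
    """

    r2: float
    chi2: float
    chi2_reduced: float
    mae: float
    mse: float
    rmse: float


def gof_metrics(
    y: np.ndarray,
    y_hat: np.ndarray,
    n_params: int,
    sigma: float | np.ndarray | None = None,
) -> GofMetrics:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    n = y.size
    if n <= n_params:
        raise ValueError("need more points than free parameters")
    resid = y - y_hat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    w = resid if sigma is None else resid / np.asarray(sigma, dtype=float)
    chi2 = float(np.sum(w**2))
    mse = ss_res / n
    return GofMetrics(
        r2=r2,
        chi2=chi2,
        chi2_reduced=chi2 / (n - n_params),
        mae=float(np.mean(np.abs(resid))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
    )


def bootstrap_median_ci(
    values: np.ndarray,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Median with bootstrap standard error and percentile CI.

    Resamples with replacement ``n_resamples`` times; SE is the standard
    deviation of the resampled medians, CI the percentile interval at
    ``level``. Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values to bootstrap a median")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, n, size=(int(n_resamples), n))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(medians, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(np.median(values)), float(medians.std()), (float(lo), float(hi))
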