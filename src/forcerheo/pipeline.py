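"""Batch orchestration: run a routine over many curves, export CSV.

Each input file is processed independently; a failing curve produces a
flagged row instead of aborting the batch. The settings snapshot travels
with the results (``DataFrame.attrs`` and a comment header in the CSV) so
every number can be traced back to the parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import CantileverPlan, calibrate, read_thermal_spectrum
from .contact import DEFAULT_ROV_WINDOW
from .curves import ForceCurve, parse_uff_text
from .elastic import fit_elastic_curve
from .microrheology import (
    ETA_WATER_25C,
    PiezoCharacterization,
    compute_gstar_curve,
    drag_profile,
    fit_drag_model,
    piezo_characterize,
)
from .viscoelastic import fit_viscoelastic

__all__ = ["BatchConfig", "run_batch", "write_results_csv"]

logger = logging.getLogger("forcerheo")

ROUTINES = ("elastic", "visco", "microrheo", "piezochar", "vdrag", "calibrate")


@dataclass
class BatchConfig:
    """Settings for one batch run; routine-specific fields are optional."""

    routine: str
    inputs: Sequence[str] = ()
    model: str = "hertz_paraboloid"
    backend: str = "analytic"  # visco: analytic | numerical
    rov_window: int = DEFAULT_ROV_WINDOW
    vdrag_b0: float = 0.0
    piezochar_file: Optional[str] = None
    eta_fluid: float = ETA_WATER_25C
    seed: int = 0
    fit_range: Optional[tuple[float, float]] = None
    thickness: Optional[float] = None
    # calibration-only
    cantilever_shape: str = "rectangular"
    cantilever_width: float = 30e-6
    cantilever_length: float = 200e-6
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.routine not in ROUTINES:
            raise ValueError(f"unknown routine {self.routine!r}")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = list(d["inputs"])
        return d


def _expand_inputs(inputs: Sequence[str]) -> list[str]:
    paths: list[str] = []
    for pat in inputs:
        hits = sorted(_glob.glob(pat))
        paths.extend(hits if hits else [pat])
    if not paths:
        raise ValueError("empty input set")
    return paths


def _load_piezochar(cfg: BatchConfig) -> Optional[PiezoCharacterization]:
    if cfg.piezochar_file is None:
        return None
    return piezo_characterize(parse_uff_text(cfg.piezochar_file))


def _gof_cols(gof) -> dict:
    if gof is None:
        return {k: np.nan for k in ("r2", "chi2", "chi2_reduced", "mae", "mse", "rmse")}
    return dataclasses.asdict(gof)


def _process_one(cfg: BatchConfig, curve: ForceCurve,
                 piezo: Optional[PiezoCharacterization]) -> list[dict]:
    fid = curve.metadata.file_id
    base = {"file_id": fid, "status": "ok"}
    if cfg.routine == "elastic":
        r = fit_elastic_curve(
            curve, model_name=cfg.model, rov_window=cfg.rov_window,
            fit_range=cfg.fit_range, thickness=cfg.thickness,
        )
        row = {**base, "E_Pa": r.E, "poc_m": r.poc_refined,
               "force_offset_N": r.force_offset, "model": r.model_name,
               **_gof_cols(r.gof)}
        if not r.success:
            row["status"] = "failed: " + r.message
        return [row]
    if cfg.routine == "visco":
        r = fit_viscoelastic(curve, model=cfg.backend, b0=cfg.vdrag_b0,
                             rov_window=cfg.rov_window)
        row = {**base, "E0_Pa": r.E0, "beta": r.beta, "poc_m": r.poc_refined,
               "force_offset_N": r.force_offset, "drag_b0": r.drag_b0,
               "model": r.model_name, **_gof_cols(r.gof)}
        if not r.success:
            row["status"] = "failed: " + r.message
        return [row]
    if cfg.routine == "microrheo":
        pts = compute_gstar_curve(curve, piezo=piezo,
                                  b0=cfg.vdrag_b0 or None,
                                  rov_window=cfg.rov_window)
        return [
            {**base, "frequency_Hz": p.f, "G_storage_Pa": p.g_storage,
             "G_loss_Pa": p.g_loss, "loss_tangent": p.loss_tangent,
             "delta0_m": p.delta0}
            for p in pts
        ]
    if cfg.routine == "piezochar":
        pc = piezo_characterize(curve)
        return [
            {**base, "frequency_Hz": float(f), "phase_lag_rad": float(ph),
             "amp_quotient": float(a)}
            for f, ph, a in zip(pc.f, pc.phase_lag, pc.amp_quotient)
        ]
    if cfg.routine == "vdrag":
        pts = drag_profile(curve, piezo=piezo)
        fit = fit_drag_model(pts, eta_fluid=cfg.eta_fluid)
        return [
            {**base, "separation_m": p.h, "b_Ns_per_m": p.b,
             "frequency_Hz": p.f, "a_eff_m": fit.a_eff, "h_eff_m": fit.h_eff,
             "b0_Ns_per_m": fit.b0}
            for p in pts
        ]
    raise ValueError(f"routine {cfg.routine!r} not handled here")


def run_batch(
    cfg: BatchConfig,
    curves: Optional[Sequence[ForceCurve]] = None,
) -> pd.DataFrame:
    """Run a routine over all inputs; one row per curve (per frequency for
    spectral routines). Pass ``curves`` to bypass file loading.

    A failure on one curve is logged and recorded as a flagged row; the
    batch always completes. Deterministic given the config seed.
    """
    piezo = _load_piezochar(cfg)
    rows: list[dict] = []

    if cfg.routine == "calibrate":
        plan = CantileverPlan(
            shape=cfg.cantilever_shape, width=cfg.cantilever_width,
            length=cfg.cantilever_length,
        )
        for path in _expand_inputs(cfg.inputs):
            try:
                spec = read_thermal_spectrum(path)
                r = calibrate(spec, plan)
                rows.append({
                    "file_id": os.path.basename(path), "status": "ok",
                    "k_N_per_m": r.spring_constant, "invOLS_m_per_V": r.invols,
                    "f_R_Hz": r.sho.f_R, "Q": r.sho.Q, "method": r.method,
                })
                logger.info("calibrated %s: k=%.3g N/m", path, r.spring_constant)
            except Exception as exc:
                logger.warning("calibration failed for %s: %s", path, exc)
                rows.append({"file_id": os.path.basename(path),
                             "status": f"failed: {exc}"})
        df = pd.DataFrame(rows)
        df.attrs["settings"] = cfg.snapshot()
        return df

    if curves is None:
        sources: list[tuple[str, Optional[ForceCurve]]] = []
        for path in _expand_inputs(cfg.inputs):
            try:
                sources.append((path, parse_uff_text(path)))
            except Exception as exc:
                logger.warning("could not load %s: %s", path, exc)
                sources.append((path, None))
    else:
        sources = [(c.metadata.file_id, c) for c in curves]

    for name, curve in sources:
        if curve is None:
            rows.append({"file_id": os.path.basename(str(name)),
                         "status": "failed: unreadable input"})
            continue
        try:
            rows.extend(_process_one(cfg, curve, piezo))
            logger.info("processed %s", name)
        except Exception as exc:
            logger.warning("processing failed for %s: %s", name, exc)
            rows.append({"file_id": curve.metadata.file_id,
                         "status": f"failed: {exc}"})
    df = pd.DataFrame(rows)
    df.attrs["settings"] = cfg.snapshot()
    return df


def write_results_csv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write results with the settings snapshot as a leading comment line."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        settings = df.attrs.get("settings")
        if settings is not None:
            fh.write("# settings: " + json.dumps(settings, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)
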