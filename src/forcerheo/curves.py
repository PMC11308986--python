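"""Force-curve data model and plain-text (UFF-TXT) I/O.

A force curve is an ordered list of segments (approach, pause, modulation,
retract), each a time series of piezo position ``z`` and cantilever vertical
deflection ``d``, plus the metadata needed to turn deflection into force
(spring constant) and piezo motion into indentation (tip geometry, Poisson
ratio). Everything downstream — contact-point detection, elastic and
viscoelastic fits, microrheology — consumes these objects.

Internal units are strict SI (m, N, s, Hz, Pa); any unit conversion happens
at the I/O boundary. Sign convention: ``z`` grows toward the sample during
approach and deflection is positive for repulsive contact.
"""

from __future__ import annotations

import enum
import io
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TipShape",
    "SegmentKind",
    "TipGeometry",
    "CurveMetadata",
    "Segment",
    "ForceCurve",
    "ForceIndentation",
    "parse_uff_text",
    "write_uff_text",
    "force_indentation",
]


class TipShape(str, enum.Enum):
    PARABOLOID = "paraboloid"
    CONE = "cone"
    PYRAMID = "pyramid"


class SegmentKind(str, enum.Enum):
    APPROACH = "approach"
    PAUSE = "pause"
    MODULATION = "modulation"
    RETRACT = "retract"


@dataclass(frozen=True)
class TipGeometry:
    """Indenter geometry.

    Parameters
    ----------
    shape
        ``paraboloid`` (needs ``radius``), ``cone`` or ``pyramid``
        (need ``half_angle``, the semi-opening angle of the cone or of the
        pyramid face, in radians).
    radius
        Tip radius R in m (paraboloid only).
    half_angle
        Semi-opening angle θ in rad (cone/pyramid only).
    """

    shape: TipShape
    radius: Optional[float] = None
    half_angle: Optional[float] = None

    def __post_init__(self) -> None:
        shape = TipShape(self.shape)
        object.__setattr__(self, "shape", shape)
        if shape is TipShape.PARABOLOID:
            if self.radius is None or self.radius <= 0:
                raise ValueError("paraboloid tip requires radius > 0")
        else:
            if self.half_angle is None or not 0 < self.half_angle < math.pi / 2:
                raise ValueError(
                    f"{shape.value} tip requires 0 < half_angle < pi/2"
                )


@dataclass(frozen=True)
class CurveMetadata:
    """Per-curve metadata: spring constant, tip, Poisson ratio, identity."""

    spring_constant: float  # N/m
    tip: TipGeometry
    poisson_ratio: float = 0.5
    deflection_sensitivity: Optional[float] = None  # m/V
    file_id: str = ""
    position: Optional[tuple[float, float]] = None  # (x, y) in m

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")


@dataclass(frozen=True)
class Segment:
    """One contiguous recording: time, piezo position, deflection (all SI).

    ``drive_frequency`` is set iff ``kind == modulation``.  ``separation``
    (optional, m) records the tip–sample distance of a drag-sweep modulation
    segment.
    """

    kind: SegmentKind
    t: np.ndarray  # s, strictly increasing
    z: np.ndarray  # m
    d: np.ndarray  # m
    drive_frequency: Optional[float] = None  # Hz
    separation: Optional[float] = None  # m (drag sweeps)

    def __post_init__(self) -> None:
        kind = SegmentKind(self.kind)
        object.__setattr__(self, "kind", kind)
        t = np.asarray(self.t, dtype=float)
        z = np.asarray(self.z, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if not (len(t) == len(z) == len(d)):
            raise ValueError("t, z, d must have equal length")
        if len(t) < 8:
            raise ValueError("segment needs at least 8 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone time in segment kind={kind.value}")
        if kind is SegmentKind.MODULATION:
            if self.drive_frequency is None or self.drive_frequency <= 0:
                raise ValueError("modulation segment requires drive_frequency > 0")
        elif self.drive_frequency is not None:
            raise ValueError("drive_frequency only allowed on modulation segments")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "d", d)

    @property
    def sampling_rate(self) -> float:
        """Mean sampling rate in Hz."""
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])


@dataclass(frozen=True)
class ForceCurve:
    """A full force curve: metadata plus ordered segments."""

    metadata: CurveMetadata
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("ForceCurve needs at least one segment")

    def get_segments(self, kind: SegmentKind | str) -> list[Segment]:
        kind = SegmentKind(kind)
        return [s for s in self.segments if s.kind is kind]

    @property
    def approach(self) -> Segment:
        segs = self.get_segments(SegmentKind.APPROACH)
        if not segs:
            raise ValueError("curve has no approach segment")
        return segs[0]


@dataclass(frozen=True)
class ForceIndentation:
    """Contact-referenced force vs indentation arrays.

    ``delta[i] = (z[i] - poc_z) - (d[i] - poc_d)`` and
    ``force[i] = k*(d[i] - poc_d) - force_offset`` by construction.
    Negative ``delta`` (pre-contact) is kept; model fits clip it.
    """

    delta: np.ndarray  # m
    force: np.ndarray  # N
    poc_z: float  # m
    poc_d: float  # m
    force_offset: float = 0.0  # N
    t: Optional[np.ndarray] = None  # s, carried along for time-domain fits


def force_indentation(
    segment: Segment,
    meta: CurveMetadata,
    poc: tuple[float, float],
    force_offset: float = 0.0,
) -> ForceIndentation:
    """Convert a segment to force vs indentation about a point of contact.

    ``poc`` is ``(z0, d0)``: the piezo position and deflection at contact.
    Indentation is piezo travel past contact minus the extra cantilever
    bending, ``delta = (z - z0) - (d - d0)``; force is Hooke's law on the
    deflection change.
    """
    z0, d0 = poc
    delta = (segment.z - z0) - (segment.d - d0)
    force = meta.spring_constant * (segment.d - d0) - force_offset
    return ForceIndentation(
        delta=delta,
        force=force,
        poc_z=float(z0),
        poc_d=float(d0),
        force_offset=float(force_offset),
        t=segment.t.copy(),
    )


# ---------------------------------------------------------------------------
# UFF-TXT dialect
# ---------------------------------------------------------------------------
#
# Header lines are "# key: value".  Required keys: file_id,
# spring_constant_N_per_m, tip_shape, tip_radius_m or tip_half_angle_rad,
# poisson_ratio.  Optional: deflection_sensitivity_m_per_V, deflection_unit
# {m|V}, position_x_m, position_y_m, invert_z {0|1} (files whose z axis grows
# away from the sample are normalized at parse time).
# Each segment block starts "## segment: <kind> [frequency_Hz=<f>]
# [separation_m=<h>]" followed by whitespace-separated columns t z d.

_REQUIRED_KEYS = ("file_id", "spring_constant_N_per_m", "tip_shape", "poisson_ratio")


def parse_uff_text(source: str | os.PathLike | io.TextIOBase) -> ForceCurve:
    """Parse a UFF-TXT file (path, text content, or open handle)."""
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        s = os.fspath(source) if isinstance(source, os.PathLike) else str(source)
        if "\n" in s or not os.path.exists(s):
            if "\n" not in s and not s.lstrip().startswith("#"):
                raise FileNotFoundError(s)
            text = s
        else:
            with open(s, "r", encoding="utf-8") as fh:
                text = fh.read()

    header: dict[str, str] = {}
    segments_raw: list[tuple[str, dict[str, float], list[str]]] = []
    current: Optional[list[str]] = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("## segment:"):
            rest = line[len("## segment:"):].strip().split()
            kind = rest[0]
            opts: dict[str, float] = {}
            for tok in rest[1:]:
                key, _, val = tok.partition("=")
                opts[key] = float(val)
            current = []
            segments_raw.append((kind, opts, current))
        elif line.startswith("#"):
            key, sep, value = line.lstrip("#").strip().partition(":")
            if sep:
                header[key.strip()] = value.strip()
        else:
            if current is None:
                raise ValueError("data line before any segment header")
            current.append(line)

    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if "spring_constant_N_per_m" in missing:
        raise ValueError("missing required metadata: spring_constant_N_per_m")
    if missing:
        raise ValueError(f"missing required metadata: {', '.join(missing)}")

    shape = TipShape(header["tip_shape"])
    if shape is TipShape.PARABOLOID:
        if "tip_radius_m" not in header:
            raise ValueError("missing required metadata: tip_radius_m")
        tip = TipGeometry(shape, radius=float(header["tip_radius_m"]))
    else:
        if "tip_half_angle_rad" not in header:
            raise ValueError("missing required metadata: tip_half_angle_rad")
        tip = TipGeometry(shape, half_angle=float(header["tip_half_angle_rad"]))

    defl_sens = header.get("deflection_sensitivity_m_per_V")
    position = None
    if "position_x_m" in header and "position_y_m" in header:
        position = (float(header["position_x_m"]), float(header["position_y_m"]))
    meta = CurveMetadata(
        spring_constant=float(header["spring_constant_N_per_m"]),
        tip=tip,
        poisson_ratio=float(header.get("poisson_ratio", 0.5)),
        deflection_sensitivity=float(defl_sens) if defl_sens else None,
        file_id=header["file_id"],
        position=position,
    )

    deflection_unit = header.get("deflection_unit", "m")
    if deflection_unit not in ("m", "V"):
        raise ValueError(f"unknown deflection_unit {deflection_unit!r}")
    if deflection_unit == "V" and meta.deflection_sensitivity is None:
        raise ValueError(
            "deflection stored in V requires deflection_sensitivity_m_per_V"
        )
    invert_z = header.get("invert_z", "0") not in ("0", "", "false")

    segments: list[Segment] = []
    for kind, opts, lines in segments_raw:
        try:
            SegmentKind(kind)
        except ValueError:
            raise ValueError(f"unknown segment kind {kind!r}") from None
        data = np.loadtxt(io.StringIO("\n".join(lines)), ndmin=2)
        if data.shape[1] != 3:
            raise ValueError(f"segment {kind!r}: expected 3 columns t z d")
        t, z, d = data.T
        if deflection_unit == "V":
            d = d * meta.deflection_sensitivity
        if invert_z:
            z = -z
        segments.append(
            Segment(
                kind=SegmentKind(kind),
                t=t,
                z=z,
                d=d,
                drive_frequency=opts.get("frequency_Hz"),
                separation=opts.get("separation_m"),
            )
        )
    return ForceCurve(metadata=meta, segments=tuple(segments))


def write_uff_text(curve: ForceCurve, path: str | os.PathLike | io.TextIOBase) -> None:
    """Serialize a ForceCurve to UFF-TXT. Deflection always written in m."""
    if not curve.segments:
        raise ValueError("refusing to write a curve with no segments")
    for seg in curve.segments:
        for name, arr in (("t", seg.t), ("z", seg.z), ("d", seg.d)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"non-finite values in {name} of segment {seg.kind.value}"
                )

    meta = curve.metadata
    lines = [
        f"# file_id: {meta.file_id}",
        f"# spring_constant_N_per_m: {meta.spring_constant!r}",
        f"# tip_shape: {meta.tip.shape.value}",
    ]
    if meta.tip.shape is TipShape.PARABOLOID:
        lines.append(f"# tip_radius_m: {meta.tip.radius!r}")
    else:
        lines.append(f"# tip_half_angle_rad: {meta.tip.half_angle!r}")
    lines.append(f"# poisson_ratio: {meta.poisson_ratio!r}")
    if meta.deflection_sensitivity is not None:
        lines.append(
            f"# deflection_sensitivity_m_per_V: {meta.deflection_sensitivity!r}"
        )
    if meta.position is not None:
        lines.append(f"# position_x_m: {meta.position[0]!r}")
        lines.append(f"# position_y_m: {meta.position[1]!r}")

    for seg in curve.segments:
        head = f"## segment: {seg.kind.value}"
        if seg.drive_frequency is not None:
            head += f" frequency_Hz={seg.drive_frequency!r}"
        if seg.separation is not None:
            head += f" separation_m={seg.separation!r}"
        lines.append(head)
        for ti, zi, di in zip(seg.t, seg.z, seg.d):
            lines.append(f"{float(ti)!r} {float(zi)!r} {float(di)!r}")
    text = "\n".join(lines) + "\n"

    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
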