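import numpy as np
import pytest

from forcerheo.curves import (
    CurveMetadata,
    ForceCurve,
    Segment,
    SegmentKind,
    TipGeometry,
)


@pytest.fixture
def paraboloid_tip() -> TipGeometry:
    return TipGeometry("paraboloid", radius=5e-6)


@pytest.fixture
def meta(paraboloid_tip) -> CurveMetadata:
    return CurveMetadata(
        spring_constant=0.192,
        tip=paraboloid_tip,
        poisson_ratio=0.5,
        file_id="fixture",
    )


def make_segment(
    kind=SegmentKind.APPROACH,
    n=64,
    z=None,
    d=None,
    dt=1e-3,
    drive_frequency=None,
    separation=None,
):
    t = np.arange(n) * dt
    if z is None:
        z = np.linspace(0.0, 1e-6, n)
    if d is None:
        d = np.zeros(n)
    return Segment(kind=kind, t=t, z=z, d=d,
                   drive_frequency=drive_frequency, separation=separation)


@pytest.fixture
def simple_curve(meta) -> ForceCurve:
    app = make_segment(SegmentKind.APPROACH)
    ret = make_segment(SegmentKind.RETRACT, z=np.linspace(1e-6, 0.0, 64))
    return ForceCurve(metadata=meta, segments=(app, ret))
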