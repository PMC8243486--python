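"""Shared fixtures: the calibrated kinematic field and rendered speckle."""

from dataclasses import replace

import numpy as np
import pytest

from lvste.kinematics import KinematicField
from lvste.simulator import PSFModel, render_frame
from lvste.views import make_view


@pytest.fixture(scope="session")
def field():
    return KinematicField()


@pytest.fixture(scope="session")
def desk_sector():
    """Small test sector (reduced resolution, shortened depth range)."""
    return replace(make_view(2), d_min=3.0, d_max=6.0).scaled(0.25)


@pytest.fixture(scope="session")
def desk_psf():
    return PSFModel().scaled(0.25)


@pytest.fixture(scope="session")
def speckle_pair(desk_sector, desk_psf):
    """Speckle frame pair with a known 0.25-sample axial (radial) shift."""
    rng = np.random.default_rng(11)
    n = 40000
    x = rng.uniform(-40, 40, n)
    y = rng.uniform(25, 70, n)
    amp = rng.standard_normal(n)
    shift_mm = 0.25 * desk_psf.sample_spacing_mm
    beta = np.arctan2(x, y)
    r = np.hypot(x, y)
    frame_a = render_frame(np.column_stack([x, y]), amp, desk_sector, desk_psf)
    r2 = r + shift_mm
    frame_b = render_frame(np.column_stack([r2 * np.sin(beta),
                                            r2 * np.cos(beta)]), amp,
                           desk_sector, desk_psf)
    return dict(frame_a=frame_a, frame_b=frame_b, shift_mm=shift_mm,
                shift_samples=0.25)


@pytest.fixture(scope="session")
def view8_context(field):
    """A2C partial view of segment 7 at desk scale, with reference maps."""
    from lvste.study import build_view_context, reference_maps

    ctx = build_view_context(field, 8, scale=0.25)
    ref = reference_maps(ctx)
    return ctx, ref
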