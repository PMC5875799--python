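import numpy as np
import pytest

from coleokin import GenConfig, RunConfig
from coleokin.geometry import MidlineFrame, MidlineSeries
from coleokin.synthetic import generate_coleoptile_series


def line_midlines(angle=0.0, length=10.0, n_pts=51, n_frames=3, dt=0.25):
    """Straight-organ midline series at a fixed zenith angle.

    The base sits at the origin; the apex points along the zenith
    direction ``angle`` (0 = up, +pi/2 = +x).  Points are apex-first.
    """
    direction = np.array([np.sin(angle), np.cos(angle)])
    s = np.linspace(0.0, length, n_pts)
    pts = s[:, None] * direction  # base -> apex
    frames = [MidlineFrame(k * dt, pts[::-1].copy()) for k in range(n_frames)]
    return MidlineSeries(frames, dt)


def arc_midlines(radius=20.0, span=np.pi / 2, n_pts=201, n_frames=2, dt=0.25):
    """Circular-arc organ: vertical at the base, turning clockwise apexward.

    The tangent angle goes linearly from 0 at the base to ``span`` at the
    apex; total arc length is radius * span.
    """
    phi = np.linspace(0.0, span, n_pts)  # base -> apex tangent angles
    x = radius * (1 - np.cos(phi))
    y = radius * np.sin(phi)
    pts = np.column_stack([x, y])[::-1]  # apex first
    frames = [MidlineFrame(k * dt, pts.copy()) for k in range(n_frames)]
    return MidlineSeries(frames, dt)


@pytest.fixture(scope="session")
def default_plant():
    """One tilted synthetic coleoptile at the default stated world."""
    return generate_coleoptile_series(GenConfig(seed=1))


@pytest.fixture(scope="session")
def default_plant_fields(default_plant):
    from coleokin.pipeline import extract_fields

    midlines, markers, truth = default_plant
    return extract_fields(midlines, markers, RunConfig()), truth
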