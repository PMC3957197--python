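"""Shared fixtures: hand-constructed reference tracks and generators."""

import numpy as np
import pytest

from rotarena.arena_geometry import SectorSpec
from rotarena.io_formats import TrackFile


def make_track(
    t_s,
    x_cm,
    y_cm,
    shock_flag=None,
    omega=6.0,
    sector_center=0.0,
    duration=None,
    phase="acquisition",
):
    t_s = np.asarray(t_s, dtype=float)
    if shock_flag is None:
        shock_flag = np.zeros(t_s.size, dtype=int)
    return TrackFile(
        arena_diameter_cm=82.0,
        rotation_speed_deg_per_s=omega,
        sector_center_deg=sector_center,
        sector_width_deg=60.0,
        session_duration_s=float(
            duration if duration is not None else (t_s[-1] if t_s[-1] > 0 else 1.0)
        ),
        phase_label=phase,
        rat_id="r01",
        group_label="control",
        session_index=1,
        t_s=t_s,
        x_cm=np.asarray(x_cm, dtype=float),
        y_cm=np.asarray(y_cm, dtype=float),
        shock_flag=shock_flag,
    )


def immobile_track(
    theta_arena_deg=180.375,
    radius_cm=30.0,
    dt=0.125,
    duration=1200.0,
    omega=6.0,
    phase="acquisition",
):
    """A subject fully immobile in the arena frame: the rotation carries it
    on a circle through the room frame.

    The default dt is a binary fraction and the start angle is offset by
    half an angular sample step, so sector-boundary crossings fall exactly
    midway between samples: occupancy times are exact and immune to the
    ~1-ulp angle noise of the Cartesian round trip.
    """
    t = np.arange(0.0, duration + dt / 2.0, dt)
    theta_room = np.radians(theta_arena_deg + omega * t)
    return make_track(
        t,
        radius_cm * np.cos(theta_room),
        radius_cm * np.sin(theta_room),
        omega=omega,
        duration=duration,
        phase=phase,
    )


def room_fixed_track(theta_room_deg=180.0, radius_cm=30.0, dt=0.1, duration=1200.0):
    """A subject holding a fixed room-frame position (walking against the
    rotation); never enters a sector centred away from it."""
    t = np.arange(0.0, duration + dt / 2.0, dt)
    theta = np.radians(theta_room_deg)
    return make_track(
        t,
        np.full(t.size, radius_cm * np.cos(theta)),
        np.full(t.size, radius_cm * np.sin(theta)),
        duration=duration,
    )


@pytest.fixture
def sector():
    return SectorSpec(0.0, 60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
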