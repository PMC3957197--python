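"""Reference-frame transforms and sector geometry for the rotating arena.

The place-avoidance task separates two coordinate frames: the *room frame*
(fixed laboratory coordinates, where the punished sector lives) and the
*arena frame* (co-rotating with the arena surface the animal stands on).
With arena angular speed ``omega`` (deg/s, signed, positive =
counter-clockwise) the frames are related by

    theta_arena = theta_room - omega * t   (mod 360)

A rat sitting still on the arena floor is stationary in the arena frame but
is carried through the room frame at ``omega``; solving the task requires
controlling room-frame position, which is why every sector computation here
is explicit about its frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import TrackFile

__all__ = ["SectorSpec", "AngularState", "to_polar", "in_sector", "angular_speed_arena"]

#: Radius below which the polar angle is undefined (degenerate centre point).
CENTER_EPS_CM = 1e-9


@dataclass(frozen=True)
class SectorSpec:
    """An angular sector, by default the 60-degree punished region.

    ``frame`` records whether ``center_deg`` is a room-frame or arena-frame
    angle; the to-be-avoided sector is fixed in the room frame.
    """

    center_deg: float
    width_deg: float = 60.0
    frame: str = "room"

    def __post_init__(self) -> None:
        if not 0 < self.width_deg < 360:
            raise ValueError("sector width must lie in (0, 360) degrees")
        if self.frame not in ("room", "arena"):
            raise ValueError("frame must be 'room' or 'arena'")

    def opposite(self) -> "SectorSpec":
        """Sector of the same width displaced 180 degrees."""
        return SectorSpec((self.center_deg + 180.0) % 360.0, self.width_deg, self.frame)


@dataclass
class AngularState:
    """Per-sample polar state of a track in both frames."""

    t_s: np.ndarray
    theta_room_deg: np.ndarray
    theta_arena_deg: np.ndarray
    radius_cm: np.ndarray
    at_center: np.ndarray  # True where the angle is degenerate (r ~ 0)
    omega_deg_per_s: float


def to_polar(track: TrackFile) -> AngularState:
    """Room- and arena-frame polar coordinates for every sample.

    The angle of the exact centre is defined as 0 and flagged in
    ``at_center`` rather than raising.
    """
    r = np.hypot(track.x_cm, track.y_cm)
    at_center = r < CENTER_EPS_CM
    theta_room = np.degrees(np.arctan2(track.y_cm, track.x_cm)) % 360.0
    theta_room[at_center] = 0.0
    omega = track.rotation_speed_deg_per_s
    theta_arena = (theta_room - omega * track.t_s) % 360.0
    return AngularState(
        t_s=track.t_s,
        theta_room_deg=theta_room,
        theta_arena_deg=theta_arena,
        radius_cm=r,
        at_center=at_center,
        omega_deg_per_s=omega,
    )


def in_sector(theta_deg, sector: SectorSpec):
    """Half-open sector membership test.

    A point is inside iff its circular offset from the sector's lower
    boundary is in ``[0, width)`` — i.e. the lower boundary
    ``center - width/2`` is inside, the upper boundary ``center + width/2``
    is not, so entrance events are unambiguous at boundaries.
    """
    theta = np.asarray(theta_deg, dtype=float)
    lower = sector.center_deg - sector.width_deg / 2.0
    offset = (theta - lower) % 360.0
    return offset < sector.width_deg


def angular_speed_arena(state: AngularState) -> np.ndarray:
    """Per-sample signed angular speed (deg/s) in the arena frame.

    The arena frame is the right frame for reading immobility: a rat frozen
    on the arena floor has arena-frame speed 0 even though the rotation
    carries it through the room at ``omega``.  The angle is unwrapped before
    differencing (avoids spurious ±360 spikes) and a two-point forward
    difference is taken at the native sample rate; the last sample repeats
    the final difference so the output aligns with the input.
    """
    if state.t_s.size < 2:
        raise ValueError("angular speed needs at least 2 samples")
    theta = np.unwrap(state.theta_arena_deg, period=360.0)
    dt = np.diff(state.t_s)
    rate = np.diff(theta) / dt
    return np.concatenate([rate, rate[-1:]])
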