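"""Per-session place-avoidance measures and the shock-schedule logic.

The five session measures are:

* ``total_distance_m`` — path length over points resampled every 1 s
  (locomotion; only this measure uses the 1-s resample),
* ``max_time_avoided_s`` — longest continuous interval without an entrance
  into the to-be-avoided sector (avoidance ability),
* ``mean_dist_center_cm`` — time-weighted mean distance from the arena
  centre (thigmotaxis; bounded below the 41-cm arena radius),
* ``entrances`` and ``time_in_sector_s`` — sector contact,
* ``prop_time_opposite`` — time in the sector 180 degrees opposite, as a
  proportion of all time *not* spent in the to-be-avoided sector
  (perseverance; excluding sector time keeps it independent of avoidance
  ability),
* ``median_abs_speed_after_shock_deg_s`` — mean over shocks of the median
  absolute arena-frame angular speed in the 1 s following each shock
  (distinguishes an active escape response from freezing).

Occupancy is accumulated sample-and-hold over native sample intervals; a
sample's state is held until the next sample (the last until session end).
Undefined values (no shocks; never left the sector) are returned as NaN and
propagate as missingness into the cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .arena_geometry import SectorSpec, angular_speed_arena, in_sector, to_polar
from .io_formats import TrackFile

__all__ = [
    "ShockEvent",
    "SessionMetrics",
    "resample_1s",
    "total_distance",
    "max_time_avoided",
    "mean_dist_center",
    "prop_time_opposite",
    "time_in_sector",
    "count_entrances",
    "shock_schedule",
    "get_shocks",
    "median_abs_speed_after_shock",
    "compute_session_metrics",
    "sector_from_track",
]

SHOCK_DURATION_S = 0.5
SHOCK_CYCLE_S = 2.0  # 0.5 s shock + 1.5 s gap while the animal stays inside
SHOCKFREE_PHASES = ("habituation", "retrieval")


@dataclass(frozen=True)
class ShockEvent:
    onset_s: float
    duration_s: float = SHOCK_DURATION_S
    kind: str = "entrance"  # entrance | repeat


@dataclass
class SessionMetrics:
    """All per-session measures for one rat in one session."""

    rat_id: str
    group_label: str
    phase_label: str
    session_index: int
    total_distance_m: float
    max_time_avoided_s: float
    mean_dist_center_cm: float
    entrances: int
    time_in_sector_s: float
    prop_time_opposite: float
    median_abs_speed_after_shock_deg_s: float
    n_shocks: int
    defecation: Optional[float] = None

    METRIC_NAMES = (
        "total_distance_m",
        "max_time_avoided_s",
        "mean_dist_center_cm",
        "entrances",
        "time_in_sector_s",
        "prop_time_opposite",
        "median_abs_speed_after_shock_deg_s",
        "n_shocks",
        "defecation",
    )

    def as_dict(self) -> dict:
        out = {
            "rat_id": self.rat_id,
            "group": self.group_label,
            "phase": self.phase_label,
            "session_index": self.session_index,
        }
        for name in self.METRIC_NAMES:
            out[name] = getattr(self, name)
        return out


def sector_from_track(track: TrackFile) -> SectorSpec:
    """The to-be-avoided sector declared in the track header (room frame)."""
    return SectorSpec(track.sector_center_deg, track.sector_width_deg, frame="room")


# --------------------------------------------------------------------------
# Sampling helpers


def resample_1s(track: TrackFile) -> np.ndarray:
    """Indices of one sample per whole second: at each tick 0, 1, 2, ... s
    the nearest sample at or before the tick; the first sample is included.
    """
    if track.n_samples == 0 or track.t_s[-1] < 0:
        raise ValueError("resampling needs at least one sample")
    ticks = np.arange(0.0, np.floor(track.t_s[-1] - track.t_s[0]) + 0.5)
    idx = np.searchsorted(track.t_s - track.t_s[0], ticks, side="right") - 1
    return np.maximum(idx, 0)


def _hold_durations(track: TrackFile) -> np.ndarray:
    """Sample-and-hold interval length per sample; the last extends to
    session end (but never negative)."""
    tail = max(track.session_duration_s - track.t_s[-1], 0.0)
    return np.concatenate([np.diff(track.t_s), [tail]])


def _membership(track: TrackFile, sector: SectorSpec) -> np.ndarray:
    state = to_polar(track)
    theta = state.theta_room_deg if sector.frame == "room" else state.theta_arena_deg
    return in_sector(theta, sector)


# --------------------------------------------------------------------------
# The five measures


def total_distance(track: TrackFile) -> float:
    """Sum of room-frame Euclidean distances over the 1-s resampled path, m."""
    idx = resample_1s(track)
    if idx.size < 2:
        return 0.0
    x = track.x_cm[idx]
    y = track.y_cm[idx]
    return float(np.hypot(np.diff(x), np.diff(y)).sum() / 100.0)


def max_time_avoided(track: TrackFile, sector: SectorSpec) -> float:
    """Longest continuous time interval without an entrance into ``sector``.

    Runs of consecutive outside samples are measured sample-and-hold: a run
    from sample i to sample j lasts from t[i] to t[j+1] (session end for the
    final sample).  Runs touching session start/end count.
    """
    inside = _membership(track, sector)
    n = inside.size
    if n == 0:
        return 0.0
    # boundaries of runs of outside samples in sample index space
    outside = ~inside
    padded = np.concatenate([[False], outside, [False]])
    run_start = np.flatnonzero(~padded[:-1] & padded[1:])
    run_end = np.flatnonzero(padded[:-1] & ~padded[1:])  # one past last index
    if run_start.size == 0:
        return 0.0
    t_ext = np.concatenate([track.t_s, [max(track.session_duration_s, track.t_s[-1])]])
    durations = t_ext[run_end] - t_ext[run_start]
    return float(durations.max())


def mean_dist_center(track: TrackFile) -> float:
    """Time-weighted mean radius, cm (thigmotaxis measure)."""
    r = np.hypot(track.x_cm, track.y_cm)
    w = _hold_durations(track)
    if w.sum() <= 0:
        return float(r.mean())
    return float(np.average(r, weights=w))


def time_in_sector(track: TrackFile, sector: SectorSpec) -> float:
    """Sample-and-hold occupancy time of ``sector``, seconds."""
    inside = _membership(track, sector)
    return float(_hold_durations(track)[inside].sum())


def prop_time_opposite(track: TrackFile, sector: SectorSpec) -> float:
    """Time in the opposite sector over all time not spent in ``sector``.

    NaN when the animal never leaves the to-be-avoided sector (denominator
    zero).
    """
    duration = _hold_durations(track).sum()
    t_in = time_in_sector(track, sector)
    denom = duration - t_in
    if denom <= 0:
        return float("nan")
    t_opp = time_in_sector(track, sector.opposite())
    return float(t_opp / denom)


def count_entrances(track: TrackFile, sector: SectorSpec) -> int:
    """Outside-to-inside transitions; starting inside counts as an entrance."""
    inside = _membership(track, sector)
    if inside.size == 0:
        return 0
    prev = np.concatenate([[False], inside[:-1]])
    return int((inside & ~prev).sum())


# --------------------------------------------------------------------------
# Shocks


def shock_schedule(track: TrackFile, sector: SectorSpec) -> list[ShockEvent]:
    """Reconstruct the shock sequence the arena hardware would deliver.

    A shock fires at each entrance; while the animal stays inside, shocks
    repeat on a 2.0-s cycle (0.5 s shock + 1.5 s gap), timed from the last
    delivered shock; the cycle resets on exit.  Habituation and retrieval
    sessions are shock-free by protocol and return an empty list.
    """
    if track.phase_label in SHOCKFREE_PHASES:
        return []
    inside = _membership(track, sector)
    events: list[ShockEvent] = []
    prev_inside = False
    next_due = np.inf
    for t, is_in in zip(track.t_s, inside):
        if is_in:
            if not prev_inside:
                events.append(ShockEvent(float(t), kind="entrance"))
                next_due = t + SHOCK_CYCLE_S
            elif t >= next_due - 1e-9:
                events.append(ShockEvent(float(t), kind="repeat"))
                next_due = t + SHOCK_CYCLE_S
        else:
            next_due = np.inf
        prev_inside = is_in
    return events


def get_shocks(track: TrackFile, sector: SectorSpec) -> list[ShockEvent]:
    """Shock events for a session.

    Shock flags present in the track file (the hardware log) take precedence;
    reconstruction via :func:`shock_schedule` is used only when the file
    carries no flags (synthetic data, validation).
    """
    if track.shock_flag.any():
        onsets = track.t_s[track.shock_flag == 1]
        events = []
        prev = -np.inf
        for t in onsets:
            kind = "repeat" if t - prev <= SHOCK_CYCLE_S + 0.5 else "entrance"
            events.append(ShockEvent(float(t), kind=kind))
            prev = t
        return events
    return shock_schedule(track, sector)


def median_abs_speed_after_shock(track: TrackFile, shocks: list[ShockEvent]) -> float:
    """Mean over shocks of the median absolute arena-frame angular speed
    (deg/s) over samples in the 1 s following each shock onset.

    NaN when there are no shocks.  The arena frame makes freezing read as
    ~0 deg/s even though the rotation carries the animal through the room.
    """
    if not shocks:
        return float("nan")
    if track.n_samples < 2:
        raise ValueError("speed needs at least 2 samples")
    speed = np.abs(angular_speed_arena(to_polar(track)))
    per_shock = []
    for ev in shocks:
        sel = (track.t_s > ev.onset_s) & (track.t_s <= ev.onset_s + 1.0)
        if sel.any():
            per_shock.append(float(np.median(speed[sel])))
    if not per_shock:
        return float("nan")
    return float(np.mean(per_shock))


# --------------------------------------------------------------------------


def compute_session_metrics(
    track: TrackFile,
    sector: SectorSpec | None = None,
    defecation: Optional[float] = None,
) -> SessionMetrics:
    """All session measures for one track; ``sector`` defaults to the header."""
    if sector is None:
        sector = sector_from_track(track)
    shocks = get_shocks(track, sector)
    return SessionMetrics(
        rat_id=track.rat_id,
        group_label=track.group_label,
        phase_label=track.phase_label,
        session_index=track.session_index,
        total_distance_m=total_distance(track),
        max_time_avoided_s=max_time_avoided(track, sector),
        mean_dist_center_cm=mean_dist_center(track),
        entrances=count_entrances(track, sector),
        time_in_sector_s=time_in_sector(track, sector),
        prop_time_opposite=prop_time_opposite(track, sector),
        median_abs_speed_after_shock_deg_s=median_abs_speed_after_shock(track, shocks),
        n_shocks=len(shocks),
        defecation=defecation,
    )
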