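"""File formats for rotating-arena tracking, cohort annotations, and actigraphy.

Three plain-text CSV dialects are defined here:

* **Track CSV** — one place-avoidance session: ``#``-prefixed ``key=value``
  header lines describing the arena and session, then a column header and one
  row per tracked sample (``t_s,x_cm,y_cm,shock_flag``).  Coordinates are in
  the fixed room frame with the origin at the arena centre; angles elsewhere
  in the package are measured in degrees, counter-clockwise from +x.
* **Activity CSV** — a per-minute (configurable bin width) activity-count
  series with a light-schedule annotation (``light``/``dark`` intervals that
  must tile the recording).
* **Annotations CSV** — a flat table with one row per rat × session carrying
  group/litter labels, defecation counts, two-bottle masses and step-through
  latencies.

All readers validate and raise :class:`TrackFormatError` /
:class:`TrackValidationError` naming the offending row or field.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrackFile",
    "ActivityFile",
    "CohortAnnotations",
    "TrackFormatError",
    "TrackValidationError",
    "read_track",
    "write_track",
    "read_activity",
    "write_activity",
    "read_annotations",
    "write_annotations",
    "RADIUS_TOLERANCE_CM",
]

#: Allowed tracking overshoot beyond the wall, in cm (tracker jitter).
RADIUS_TOLERANCE_CM = 0.5

PHASES = ("habituation", "acquisition", "retrieval", "reversal")


class TrackFormatError(ValueError):
    """A file does not conform to the documented dialect."""


class TrackValidationError(ValueError):
    """A file parses but violates a documented invariant."""


# --------------------------------------------------------------------------
# Track files


@dataclass
class TrackFile:
    """One tracked session on the rotating arena.

    Positions are room-frame Cartesian coordinates in cm, origin at the
    arena centre.  ``rotation_speed_deg_per_s`` is signed; positive means
    counter-clockwise arena rotation.
    """

    arena_diameter_cm: float
    rotation_speed_deg_per_s: float
    sector_center_deg: float
    sector_width_deg: float
    session_duration_s: float
    phase_label: str
    rat_id: str
    group_label: str
    session_index: int
    t_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    x_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    shock_flag: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.shock_flag = np.asarray(self.shock_flag, dtype=int)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.t_s.size

    @property
    def arena_radius_cm(self) -> float:
        return self.arena_diameter_cm / 2.0

    def validate(self) -> None:
        for key in ("arena_diameter_cm", "sector_width_deg", "session_duration_s"):
            if getattr(self, key) <= 0:
                raise TrackValidationError(f"header field {key!r} must be positive")
        if self.phase_label not in PHASES:
            raise TrackValidationError(
                f"phase_label {self.phase_label!r} not one of {PHASES}"
            )
        n = self.t_s.size
        if not (self.x_cm.size == self.y_cm.size == self.shock_flag.size == n):
            raise TrackValidationError("column lengths differ")
        if n:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise TrackValidationError(
                    f"time not strictly increasing at row {bad}"
                )
            r = np.hypot(self.x_cm, self.y_cm)
            limit = self.arena_radius_cm + RADIUS_TOLERANCE_CM
            if np.any(r > limit):
                bad = int(np.argmax(r > limit))
                raise TrackValidationError(
                    f"row {bad}: radius {r[bad]:.2f} cm exceeds arena radius "
                    f"{self.arena_radius_cm:.1f} + {RADIUS_TOLERANCE_CM} cm tolerance"
                )
            if not np.isin(self.shock_flag, (0, 1)).all():
                bad = int(np.argmax(~np.isin(self.shock_flag, (0, 1))))
                raise TrackValidationError(f"row {bad}: shock_flag not in {{0,1}}")

    def copy(self, **changes) -> "TrackFile":
        return replace(self, **changes)


_TRACK_HEADER_KEYS = (
    "arena_diameter_cm",
    "rotation_speed_deg_per_s",
    "sector_center_deg",
    "sector_width_deg",
    "session_duration_s",
    "phase_label",
    "rat_id",
    "group_label",
    "session_index",
)
_TRACK_FLOAT_KEYS = _TRACK_HEADER_KEYS[:5]


def _parse_header(lines: list[str], path) -> dict:
    header: dict = {}
    for line in lines:
        body = line[1:].strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        header[key.strip()] = value.strip()
    return header


def read_track(path) -> TrackFile:
    """Read a track CSV, validating header, monotone time and the radius bound."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read()
    header_lines = [ln for ln in raw.splitlines() if ln.startswith("#")]
    header = _parse_header(header_lines, path)
    missing = [k for k in _TRACK_HEADER_KEYS if k not in header]
    if missing:
        raise TrackFormatError(f"{path}: missing header key(s) {missing}")
    kwargs = {k: float(header[k]) for k in _TRACK_FLOAT_KEYS}
    kwargs["phase_label"] = header["phase_label"]
    kwargs["rat_id"] = header["rat_id"]
    kwargs["group_label"] = header["group_label"]
    kwargs["session_index"] = int(header["session_index"])

    body = "\n".join(ln for ln in raw.splitlines() if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    expected = ["t_s", "x_cm", "y_cm", "shock_flag"]
    if list(df.columns) != expected:
        raise TrackFormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    declared = header.get("n_rows")
    if declared is not None and int(declared) != len(df):
        raise TrackFormatError(
            f"{path}: header declares n_rows={declared} but found {len(df)} rows"
        )
    try:
        return TrackFile(
            t_s=df["t_s"].to_numpy(),
            x_cm=df["x_cm"].to_numpy(),
            y_cm=df["y_cm"].to_numpy(),
            shock_flag=df["shock_flag"].to_numpy(),
            **kwargs,
        )
    except TrackValidationError as err:
        raise TrackValidationError(f"{path}: {err}") from err


def write_track(track: TrackFile, path):
    """Write a track CSV re-readable by :func:`read_track`."""
    track.validate()
    with open(path, "w", encoding="utf-8") as fh:
        for key in _TRACK_HEADER_KEYS:
            fh.write(f"# {key}={getattr(track, key)}\n")
        fh.write(f"# n_rows={track.n_samples}\n")
        fh.write("t_s,x_cm,y_cm,shock_flag\n")
        for t, x, y, s in zip(track.t_s, track.x_cm, track.y_cm, track.shock_flag):
            fh.write(f"{t:.6g},{x:.6g},{y:.6g},{int(s)}\n")
    return path


# --------------------------------------------------------------------------
# Activity files


@dataclass
class ActivityFile:
    """A per-bin activity-count series with its light schedule.

    ``schedule`` is a list of ``(start_min, end_min, state)`` intervals,
    in minutes since ``start_timestamp``, with ``state`` ``"light"`` or
    ``"dark"``; the intervals must tile the recording exactly.
    """

    start_timestamp: str
    bin_width_min: float
    counts: np.ndarray
    schedule: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration_min(self) -> float:
        return self.n_bins * self.bin_width_min

    def validate(self) -> None:
        if self.bin_width_min <= 0:
            raise TrackValidationError("bin_width_min must be positive")
        if self.counts.size and (
            np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            if np.any(self.counts < 0):
                bad = int(np.argmax(self.counts < 0))
                raise TrackValidationError(f"bin {bad}: negative count")
            raise TrackValidationError("counts must be integers")
        pos = 0.0
        for i, (start, end, state) in enumerate(self.schedule):
            if state not in ("light", "dark"):
                raise TrackValidationError(f"schedule interval {i}: bad state {state!r}")
            if not np.isclose(start, pos):
                raise TrackValidationError(
                    f"schedule interval {i}: starts at {start} min, expected {pos} "
                    "(gap or overlap)"
                )
            if end <= start:
                raise TrackValidationError(f"schedule interval {i}: non-positive length")
            pos = end
        if self.schedule and not np.isclose(pos, self.duration_min):
            raise TrackValidationError(
                f"schedule spans {pos} min but counts span {self.duration_min} min"
            )

    def state_per_bin(self) -> np.ndarray:
        """Light/dark state of each bin as an array of ``"light"``/``"dark"``."""
        states = np.empty(self.n_bins, dtype=object)
        centers = (np.arange(self.n_bins) + 0.5) * self.bin_width_min
        for start, end, state in self.schedule:
            states[(centers >= start) & (centers < end)] = state
        return states


def read_activity(path) -> ActivityFile:
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read()
    header = _parse_header([ln for ln in raw.splitlines() if ln.startswith("#")], path)
    for key in ("start_timestamp", "bin_width_min", "schedule"):
        if key not in header:
            raise TrackFormatError(f"{path}: missing header key {key!r}")
    schedule = []
    for part in header["schedule"].split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            state, _, span = part.partition(":")
            lo, _, hi = span.partition("-")
            schedule.append((float(lo), float(hi), state))
        except ValueError as err:
            raise TrackFormatError(f"{path}: bad schedule entry {part!r}") from err
    body = "\n".join(ln for ln in raw.splitlines() if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    if list(df.columns) != ["count"]:
        raise TrackFormatError(f"{path}: expected a single 'count' column")
    try:
        return ActivityFile(
            start_timestamp=header["start_timestamp"],
            bin_width_min=float(header["bin_width_min"]),
            counts=df["count"].to_numpy(dtype=int),
            schedule=schedule,
        )
    except TrackValidationError as err:
        raise TrackValidationError(f"{path}: {err}") from err


def write_activity(activity: ActivityFile, path):
    activity.validate()
    sched = ";".join(f"{state}:{start:g}-{end:g}" for start, end, state in activity.schedule)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# start_timestamp={activity.start_timestamp}\n")
        fh.write(f"# bin_width_min={activity.bin_width_min:g}\n")
        fh.write(f"# schedule={sched}\n")
        fh.write("count\n")
        for c in activity.counts:
            fh.write(f"{int(c)}\n")
    return path


# --------------------------------------------------------------------------
# Cohort annotations

ANNOTATION_COLUMNS = [
    "rat_id",
    "group_label",
    "litter_id",
    "phase",
    "session_index",
    "defecation_count",
    "saccharin_mass_g",
    "water_mass_g",
    "step_through_latency_s",
    "shock_intensity_mA",
]

#: Step-through trials are capped at this latency (never-crossing subjects).
STEP_THROUGH_CAP_S = 300.0


@dataclass
class CohortAnnotations:
    """Per rat×session annotations: defecation, two-bottle masses, latencies."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise TrackFormatError(f"annotations missing column(s) {missing}")
        t = self.table
        for col in ("saccharin_mass_g", "water_mass_g"):
            bad = t[col].dropna() < 0
            if bad.any():
                raise TrackValidationError(
                    f"{col}: negative mass at row {int(bad.idxmax())}"
                )
        lat = t["step_through_latency_s"].dropna()
        if ((lat < 0) | (lat > STEP_THROUGH_CAP_S)).any():
            bad = lat[(lat < 0) | (lat > STEP_THROUGH_CAP_S)].index[0]
            raise TrackValidationError(
                f"step_through_latency_s out of [0, {STEP_THROUGH_CAP_S}] at row {bad}"
            )
        defe = t["defecation_count"].dropna()
        if (defe < 0).any() or not np.allclose(defe, np.round(defe)):
            raise TrackValidationError("defecation_count must be non-negative integers")


def read_annotations(path) -> CohortAnnotations:
    return CohortAnnotations(pd.read_csv(path))


def write_annotations(annotations: CohortAnnotations, path):
    annotations.validate()
    annotations.table.to_csv(path, index=False)
    return path
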