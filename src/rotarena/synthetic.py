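"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* :func:`simulate_session` — a correlated-random-walk trajectory on the
  rotating arena.  The rat walks on the arena floor (gamma step speeds,
  wrapped-normal turning) while the rotation carries it through the room
  frame; steering terms express thigmotaxis (wall attraction), sector
  avoidance (room-frame steering away from the punished sector) and a
  post-shock escape response; a freezing phenotype suspends walking so the
  animal is immobile in the arena frame and is passively transported
  through the sector.  Shocks are generated online by the arena rule
  (0.5-s shock at entrance, repeated on a 2.0-s cycle while inside).
* :func:`simulate_cohort` — the full study layout (two groups of 9, phases
  habituation/acquisition/retrieval/reversal, 5 daily 20-min sessions per
  phase plus one 5-min retrieval), with per-group phenotype parameters, a
  session-indexed avoidance-skill schedule standing in for learning,
  planted freezers, annotation tables (Poisson defecation, truncated-normal
  bottle masses, patterned step-through latencies) and sparse missingness
  (default 0.6%).  All planted parameters are recorded in a manifest.
* :func:`simulate_activity` — circadian per-minute counts: a square or
  sinusoidal waveform (period 24 h entrained under LD, tau free-running
  under DD), light masking under LD, Poisson noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena_geometry import SectorSpec
from .avoidance_metrics import SHOCK_CYCLE_S, compute_session_metrics
from .io_formats import (
    ActivityFile,
    CohortAnnotations,
    STEP_THROUGH_CAP_S,
    TrackFile,
)

__all__ = [
    "TrajectorySimConfig",
    "CircadianSimConfig",
    "simulate_session",
    "simulate_cohort",
    "simulate_activity",
    "simulate_step_through",
    "simulate_metric_cohort",
    "freezing_config",
    "SimulatedCohort",
]

ARENA_DIAMETER_CM = 82.0
MINUTES_PER_DAY_F = 1440.0
OMEGA_DEG_PER_S = 6.0
SESSION_DURATION_S = 1200.0
RETRIEVAL_DURATION_S = 300.0


@dataclass
class TrajectorySimConfig:
    """Movement and phenotype parameters for one simulated session."""

    dt_s: float = 0.2
    duration_s: float = SESSION_DURATION_S
    speed_mean_cm_s: float = 5.0      # mean walking speed
    speed_shape: float = 2.0          # gamma shape of per-step speeds
    turn_sd_rad: float = 1.2          # heading diffusion per sqrt(s)
    thigmotaxis_bias: float = 0.7     # 0 = centre-preferring, 1 = wall-hugging
    radial_gain: float = 2.0          # steering gain toward the preferred radius
    avoidance_skill: float = 0.0      # 0..1, steering away from the sector
    escape_speed_deg_s: float = 20.0  # arena-frame angular speed of the escape
    escape_duration_s: float = 1.0
    freeze_bout_prob_per_s: float = 0.0
    freeze_bout_mean_s: float = 10.0
    freeze_onset_delay_s: float = 0.0  # no bouts before this time

    def validate(self) -> None:
        if self.dt_s > 1.0:
            raise ValueError("dt_s must be <= 1 s (metrics assume >= 1 Hz)")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("dt_s and duration_s must be positive")
        for name in ("thigmotaxis_bias", "avoidance_skill"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("speed_mean_cm_s", "speed_shape", "turn_sd_rad",
                     "escape_speed_deg_s", "freeze_bout_mean_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def freezing_config(**overrides) -> TrajectorySimConfig:
    """The freezing non-solver preset: the rat stops walking almost
    immediately and never resumes, so it is immobile in the arena frame."""
    cfg = TrajectorySimConfig(
        freeze_bout_prob_per_s=1e9,
        freeze_bout_mean_s=1e9,
        avoidance_skill=0.0,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_session(
    config: TrajectorySimConfig,
    sector: SectorSpec | None = None,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    phase_label: str = "acquisition",
    rat_id: str = "sim",
    group_label: str = "control",
    session_index: int = 1,
    arena_diameter_cm: float = ARENA_DIAMETER_CM,
    omega_deg_per_s: float = OMEGA_DEG_PER_S,
) -> TrackFile:
    """Simulate one session; returns a validated :class:`TrackFile` with
    shock flags set at shock onsets (empty in shock-free phases)."""
    config.validate()
    if sector is None:
        sector = SectorSpec(0.0)
    if rng is None:
        rng = np.random.default_rng(seed)
    dt = config.dt_s
    n_steps = int(round(config.duration_s / dt))
    n = n_steps + 1
    radius_limit = arena_diameter_cm / 2.0 - 1.0  # keep inside the wall
    omega_rad = math.radians(omega_deg_per_s)
    half_w = sector.width_deg / 2.0
    shock_free = phase_label in ("habituation", "retrieval")

    speeds = rng.gamma(config.speed_shape,
                       config.speed_mean_cm_s / config.speed_shape, size=n)
    turns = rng.normal(0.0, config.turn_sd_rad * math.sqrt(dt), size=n)
    freeze_draws = rng.random(size=n)
    bout_draws = rng.exponential(max(config.freeze_bout_mean_s, 1e-12), size=n)

    # start at a uniform-random point, heading uniform
    r0 = radius_limit * math.sqrt(rng.random())
    a0 = 2.0 * math.pi * rng.random()
    x, y = r0 * math.cos(a0), r0 * math.sin(a0)
    heading = 2.0 * math.pi * rng.random()
    r_pref = config.thigmotaxis_bias * radius_limit
    p_freeze = min(config.freeze_bout_prob_per_s * dt, 1.0)

    xs = np.empty(n)
    ys = np.empty(n)
    flags = np.zeros(n, dtype=int)
    ts = np.arange(n) * dt

    frozen_until = -1.0
    escape_until = -1.0
    escape_dir = 1.0
    prev_inside = False
    next_due = math.inf

    for i in range(n):
        t = ts[i]
        xs[i], ys[i] = x, y

        # --- shock logic on the current sample (room frame) ---
        if not shock_free:
            theta_room = math.degrees(math.atan2(y, x)) % 360.0
            offset = (theta_room - (sector.center_deg - half_w)) % 360.0
            inside = offset < sector.width_deg
            shock = False
            if inside:
                if not prev_inside:
                    shock = True
                elif t >= next_due - 1e-9:
                    shock = True
                if shock:
                    flags[i] = 1
                    next_due = t + SHOCK_CYCLE_S
                    if t >= frozen_until:  # freezers do not escape
                        escape_until = t + config.escape_duration_s
                        d = (theta_room - sector.center_deg + 180.0) % 360.0 - 180.0
                        escape_dir = 1.0 if d >= 0 else -1.0
            else:
                next_due = math.inf
            prev_inside = inside

        if i == n - 1:
            break

        # --- movement step (room frame), then arena rotation ---
        frozen = t < frozen_until
        if (not frozen and p_freeze > 0 and t >= config.freeze_onset_delay_s
                and freeze_draws[i] < p_freeze):
            frozen_until = t + bout_draws[i]
            frozen = True
        if frozen:
            pass
        elif t < escape_until:
            # escape: tangential arc at escape_speed in the arena frame
            dphi = escape_dir * math.radians(config.escape_speed_deg_s) * dt
            c, s = math.cos(dphi), math.sin(dphi)
            x, y = c * x - s * y, s * x + c * y
            heading += dphi
        else:
            pos_angle = math.atan2(y, x) if (x or y) else 0.0
            r = math.hypot(x, y)
            # avoidance weight: skilled rats counter the rotation that would
            # otherwise transport them into the room-frame sector
            avoid_w = 0.0
            if config.avoidance_skill > 0 and not shock_free:
                theta_room = math.degrees(pos_angle) % 360.0
                d = (theta_room - sector.center_deg + 180.0) % 360.0 - 180.0
                # skilled rats react earlier (wider warning zone) and harder
                react_deg = half_w + 15.0 + 100.0 * config.avoidance_skill
                avoid_w = config.avoidance_skill * min(
                    max((react_deg - abs(d)) / 60.0, 0.0), 1.0
                )
            heading += turns[i] * (1.0 - 0.7 * avoid_w)
            # thigmotaxis: relax toward the preferred radius (fractional
            # correction clamped for stability at any dt)
            target = pos_angle if r < r_pref else pos_angle + math.pi
            frac = min(config.radial_gain * dt * min(abs(r - r_pref) / 10.0, 1.0), 1.0)
            heading += frac * _wrap_pi(target - heading)
            # avoidance: steer tangentially toward the far side of the arena
            if avoid_w > 0:
                away = pos_angle + (math.pi / 2.0 if d >= 0 else -math.pi / 2.0)
                heading += min(2.5 * avoid_w * dt, 1.0) * _wrap_pi(away - heading)
            step = speeds[i] * dt
            x += step * math.cos(heading)
            y += step * math.sin(heading)
            r = math.hypot(x, y)
            if r > radius_limit:
                # reflect off the wall: clip the radius, mirror the heading
                alpha = math.atan2(y, x)
                x = radius_limit * math.cos(alpha)
                y = radius_limit * math.sin(alpha)
                heading = _wrap_pi(math.pi + 2.0 * alpha - heading)
        # arena rotation carries the rat (and its heading) through the room
        drot = omega_rad * dt
        c, s = math.cos(drot), math.sin(drot)
        x, y = c * x - s * y, s * x + c * y
        heading += drot

    return TrackFile(
        arena_diameter_cm=arena_diameter_cm,
        rotation_speed_deg_per_s=omega_deg_per_s,
        sector_center_deg=sector.center_deg,
        sector_width_deg=sector.width_deg,
        session_duration_s=config.duration_s,
        phase_label=phase_label,
        rat_id=rat_id,
        group_label=group_label,
        session_index=session_index,
        t_s=ts,
        x_cm=xs,
        y_cm=ys,
        shock_flag=flags,
    )


# --------------------------------------------------------------------------
# Full cohort


#: Default per-group phenotypes.  The avoidance-skill schedule stands in for
#: learning across the 5 daily sessions of a phase.
DEFAULT_GROUP_PARAMS = {
    "control": {
        "thigmotaxis_bias": 0.8,
        "skill_schedule": (0.2, 0.3, 0.35, 0.4, 0.45),
        "defecation_rate": 3.0,
        "speed_mean_cm_s": 4.0,
        "step_through_means": (60.0, 40.0, 20.0),
        "saccharin_mean_g": 9.0,
        "water_mean_g": 5.0,
    },
    "knockdown": {
        "thigmotaxis_bias": 0.6,
        "skill_schedule": (0.2, 0.3, 0.35, 0.4, 0.45),
        "defecation_rate": 1.5,
        "speed_mean_cm_s": 5.5,
        "step_through_means": (60.0, 75.0, 95.0),
        "saccharin_mean_g": 9.0,
        "water_mean_g": 5.0,
    },
}

PHASE_PLAN = (
    ("habituation", 5, SESSION_DURATION_S),
    ("acquisition", 5, SESSION_DURATION_S),
    ("retrieval", 1, RETRIEVAL_DURATION_S),
    ("reversal", 5, SESSION_DURATION_S),
)

#: Reversal moves the punished sector 180 degrees, so the old opposite
#: sector becomes the new punished one.
ACQUISITION_SECTOR_DEG = 0.0
REVERSAL_SECTOR_DEG = 180.0

_MISSABLE_METRICS = (
    "total_distance_m",
    "max_time_avoided_s",
    "mean_dist_center_cm",
    "prop_time_opposite",
    "median_abs_speed_after_shock_deg_s",
)


@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    annotations: CohortAnnotations
    manifest: dict
    tracks: list = field(default_factory=list)


def simulate_cohort(
    n_per_group: int = 9,
    *,
    seed: int | None = None,
    group_params: dict | None = None,
    n_freezers: dict | None = None,
    missing_rate: float = 0.006,
    dt_s: float = 0.5,
    phases=PHASE_PLAN,
    return_tracks: bool = False,
) -> SimulatedCohort:
    """Simulate the full two-group study and compute all session metrics.

    ``n_freezers`` maps group -> number of rats in that group whose
    acquisition/reversal sessions use the freezing preset (default none).
    Missing values are planted at ``missing_rate`` over the five tracked
    measures.  Returns the long cohort metric table, the annotations table,
    a manifest of every planted parameter, and optionally the raw tracks.
    """
    rng = np.random.default_rng(seed)
    params = {g: dict(DEFAULT_GROUP_PARAMS[g]) for g in DEFAULT_GROUP_PARAMS}
    if group_params:
        for g, upd in group_params.items():
            params.setdefault(g, {}).update(upd)
    n_freezers = dict(n_freezers or {})

    rats = []
    for group in params:
        p = params[group]
        freezer_count = n_freezers.get(group, 0)
        for j in range(n_per_group):
            # stable per-rat phenotype jitter around the group means
            rats.append(
                {
                    "rat_id": f"{group[:2]}{j + 1:02d}",
                    "group": group,
                    "litter_id": f"L{j % 3 + 1}",
                    "freezer": j < freezer_count,
                    "bias": float(np.clip(
                        p["thigmotaxis_bias"] + rng.normal(0.0, 0.04), 0.0, 1.0
                    )),
                    "speed": float(max(
                        p["speed_mean_cm_s"] + rng.normal(0.0, 0.5), 1.0
                    )),
                    "skill_mult": float(np.clip(rng.normal(1.0, 0.12), 0.6, 1.4)),
                }
            )

    metric_rows = []
    ann_rows = []
    tracks = []
    for rat in rats:
        p = params[rat["group"]]
        for phase, n_sessions, duration in phases:
            sector_deg = (
                REVERSAL_SECTOR_DEG if phase == "reversal" else ACQUISITION_SECTOR_DEG
            )
            sector = SectorSpec(sector_deg)
            for s in range(1, n_sessions + 1):
                use_freeze = rat["freezer"] and phase in ("acquisition", "reversal")
                if use_freeze:
                    # freezers settle at a small radius, then stop for good:
                    # low passive-transport distance, near-zero post-shock speed
                    cfg = freezing_config(
                        dt_s=dt_s, duration_s=duration,
                        thigmotaxis_bias=0.25, freeze_onset_delay_s=20.0,
                    )
                else:
                    skill = (
                        0.0
                        if phase == "habituation"
                        else p["skill_schedule"][min(s - 1, len(p["skill_schedule"]) - 1)]
                        * rat["skill_mult"]
                    )
                    cfg = TrajectorySimConfig(
                        dt_s=dt_s,
                        duration_s=duration,
                        thigmotaxis_bias=rat["bias"],
                        speed_mean_cm_s=rat["speed"],
                        avoidance_skill=min(skill, 1.0),
                    )
                track = simulate_session(
                    cfg,
                    sector,
                    rng=rng,
                    phase_label=phase,
                    rat_id=rat["rat_id"],
                    group_label=rat["group"],
                    session_index=s,
                )
                defecation = float(rng.poisson(p["defecation_rate"]))
                metrics = compute_session_metrics(track, sector, defecation=defecation)
                for name, value in metrics.as_dict().items():
                    if name in ("rat_id", "group", "phase", "session_index"):
                        continue
                    metric_rows.append(
                        {
                            "rat_id": rat["rat_id"],
                            "group": rat["group"],
                            "phase": phase,
                            "session_index": s,
                            "metric": name,
                            "value": value,
                        }
                    )
                ann_rows.append(
                    {
                        "rat_id": rat["rat_id"],
                        "group_label": rat["group"],
                        "litter_id": rat["litter_id"],
                        "phase": phase,
                        "session_index": s,
                        "defecation_count": defecation,
                        "saccharin_mass_g": np.nan,
                        "water_mass_g": np.nan,
                        "step_through_latency_s": np.nan,
                        "shock_intensity_mA": round(float(rng.uniform(0.4, 0.7)), 2),
                    }
                )
                if return_tracks:
                    tracks.append(track)

        # two-bottle sessions and step-through trials ride along as extra rows
        for s in (1, 2):
            ann_rows.append(
                {
                    "rat_id": rat["rat_id"],
                    "group_label": rat["group"],
                    "litter_id": rat["litter_id"],
                    "phase": "two_bottle",
                    "session_index": s,
                    "defecation_count": np.nan,
                    "saccharin_mass_g": max(0.0, float(rng.normal(p["saccharin_mean_g"], 2.0))),
                    "water_mass_g": max(0.0, float(rng.normal(p["water_mean_g"], 1.5))),
                    "step_through_latency_s": np.nan,
                    "shock_intensity_mA": np.nan,
                }
            )
        for trial, mean in enumerate(p["step_through_means"], start=1):
            lat = float(np.clip(rng.normal(mean, 15.0), 0.0, STEP_THROUGH_CAP_S))
            ann_rows.append(
                {
                    "rat_id": rat["rat_id"],
                    "group_label": rat["group"],
                    "litter_id": rat["litter_id"],
                    "phase": "step_through",
                    "session_index": trial,
                    "defecation_count": np.nan,
                    "saccharin_mass_g": np.nan,
                    "water_mass_g": np.nan,
                    "step_through_latency_s": lat,
                    "shock_intensity_mA": np.nan,
                }
            )

    cohort = pd.DataFrame(metric_rows)
    if missing_rate > 0:
        mask = cohort["metric"].isin(_MISSABLE_METRICS) & (
            rng.random(len(cohort)) < missing_rate
        )
        cohort.loc[mask, "value"] = np.nan

    manifest = {
        "seed": seed,
        "n_per_group": n_per_group,
        "dt_s": dt_s,
        "missing_rate": missing_rate,
        "n_freezers": n_freezers,
        "group_params": {g: {k: list(v) if isinstance(v, tuple) else v
                             for k, v in p.items()} for g, p in params.items()},
        "phases": [list(p) for p in phases],
    }
    return SimulatedCohort(
        cohort=cohort,
        annotations=CohortAnnotations(pd.DataFrame(ann_rows)),
        manifest=manifest,
        tracks=tracks,
    )


def simulate_step_through(
    n_per_group: int = 9,
    *,
    seed: int | None = None,
    group_means: dict | None = None,
    sd: float = 15.0,
    never_cross_groups: tuple = (),
) -> pd.DataFrame:
    """Step-through latency table (rat_id, group, trial, latency_s).

    Groups named in ``never_cross_groups`` never enter the dark compartment,
    so every trial scores the 300-s cap.
    """
    rng = np.random.default_rng(seed)
    if group_means is None:
        group_means = {
            g: p["step_through_means"] for g, p in DEFAULT_GROUP_PARAMS.items()
        }
    rows = []
    for group, means in group_means.items():
        for j in range(n_per_group):
            for trial, mean in enumerate(means, start=1):
                if group in never_cross_groups:
                    lat = STEP_THROUGH_CAP_S
                else:
                    lat = float(np.clip(rng.normal(mean, sd), 0.0, STEP_THROUGH_CAP_S))
                rows.append(
                    {"rat_id": f"{group[:2]}{j + 1:02d}", "group": group,
                     "trial": trial, "latency_s": lat}
                )
    return pd.DataFrame(rows)


def simulate_metric_cohort(
    n_per_group: int = 9,
    n_sessions: int = 5,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    phases=("acquisition", "reversal"),
    metric: str = "total_distance_m",
    group_shift: dict | None = None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Metric-level cohort table drawn directly from normal session scores.

    The lightweight generator for statistical-pipeline studies (null
    calibration, power): values are iid standard normal per rat × session,
    with an optional per-phase mean shift (in SD units) added to the
    knockdown group.  No trajectories are involved.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    group_shift = group_shift or {}
    rows = []
    for group in ("control", "knockdown"):
        for j in range(n_per_group):
            rat = f"{group[:2]}{j + 1:02d}"
            for phase in phases:
                shift = group_shift.get(phase, 0.0) if group == "knockdown" else 0.0
                vals = rng.normal(shift, 1.0, size=n_sessions)
                for s, v in enumerate(vals, start=1):
                    rows.append(
                        {"rat_id": rat, "group": group, "phase": phase,
                         "session_index": s, "metric": metric, "value": v}
                    )
    df = pd.DataFrame(rows)
    if missing_rate > 0:
        mask = rng.random(len(df)) < missing_rate
        df.loc[mask, "value"] = np.nan
    return df


# --------------------------------------------------------------------------
# Circadian counts


@dataclass
class CircadianSimConfig:
    """Generative parameters for a circadian activity-count series."""

    tau_h: float = 24.2               # free-running period under DD
    waveform: str = "square"          # "square" | "sinusoid"
    mesor: float = 6.0                # counts/bin midline
    amplitude: float = 5.0            # counts/bin modulation depth
    masking_coefficient: float = 0.8  # light suppression of activity under LD
    ld_days: int = 29
    dd_days: int = 16
    bin_width_min: float = 1.0
    onset_phase_h: float = 12.0       # activity onset = lights-off under LD

    def validate(self) -> None:
        if not 20.0 < self.tau_h < 28.0:
            raise ValueError("tau_h must lie in (20, 28) h")
        if self.amplitude < 0 or self.mesor < 0:
            raise ValueError("mesor and amplitude must be non-negative")
        if self.waveform not in ("square", "sinusoid"):
            raise ValueError("waveform must be 'square' or 'sinusoid'")
        if not 0.0 <= self.masking_coefficient <= 1.0:
            raise ValueError("masking_coefficient must lie in [0, 1]")


def simulate_activity(
    config: CircadianSimConfig, *, seed: int | None = None
) -> ActivityFile:
    """Poisson counts about a circadian waveform, with the study's
    LD-then-DD schedule annotated."""
    config.validate()
    rng = np.random.default_rng(seed)
    bw_h = config.bin_width_min / 60.0
    bins_per_day = int(round(24.0 / bw_h))
    n_ld = config.ld_days * bins_per_day
    n_dd = config.dd_days * bins_per_day
    n = n_ld + n_dd
    t_h = (np.arange(n) + 0.5) * bw_h  # bin centres, hours since start
    ld_end_h = config.ld_days * 24.0

    phase = np.where(
        t_h < ld_end_h,
        (t_h - config.onset_phase_h) % 24.0 / 24.0,
        (t_h - ld_end_h - config.onset_phase_h % config.tau_h)
        % config.tau_h / config.tau_h,
    )
    if config.waveform == "square":
        drive = np.where(phase < 0.5, config.mesor + config.amplitude,
                         config.mesor - config.amplitude)
    else:
        drive = config.mesor + config.amplitude * np.cos(
            2.0 * np.pi * (phase - 0.25)
        )
    drive = np.clip(drive, 0.0, None)

    schedule = []
    for d in range(config.ld_days):
        start = d * MINUTES_PER_DAY_F
        schedule.append((start, start + 720.0, "light"))
        schedule.append((start + 720.0, start + 1440.0, "dark"))
        light = (t_h >= d * 24.0) & (t_h < d * 24.0 + 12.0)
        drive[light] *= 1.0 - config.masking_coefficient
    if config.dd_days:
        schedule.append(
            (config.ld_days * MINUTES_PER_DAY_F,
             (config.ld_days + config.dd_days) * MINUTES_PER_DAY_F, "dark")
        )
    counts = rng.poisson(drive)
    return ActivityFile(
        start_timestamp="2000-01-01T00:00:00",
        bin_width_min=config.bin_width_min,
        counts=counts,
        schedule=schedule,
    )
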