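"""Run configuration: every constant the protocol leaves open lives here.

The arena geometry (82-cm diameter, 60-degree sector, 20-min sessions) is
documented by the protocol; the rotation speed (6 deg/s), the non-solver
thresholds (total-distance z-cut −1.0; post-shock speed bounds 2 and
8 deg/s) and the periodogram settings (20–28 h search, chi-square
significance at alpha = 0.001) are package defaults, user-overridable via a
YAML file that round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # arena
    arena_diameter_cm: float = 82.0
    omega_deg_per_s: float = 6.0
    sector_center_deg: float = 0.0
    sector_width_deg: float = 60.0
    session_duration_s: float = 1200.0
    # cohort analysis thresholds
    z_cut: float = -1.0
    speed_cut_deg_s: float = 2.0           # below: no escape response (freezing)
    active_speed_deg_s: float = 8.0        # above: clear active response
    # periodogram
    period_range_h: tuple = (20.0, 28.0)
    periodogram_step_h: float | None = None  # None = one bin
    periodogram_alpha: float = 0.001
    # reproducibility
    seed: int | None = None
    out_dir: str = "rotarena_out"

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["period_range_h"] = list(self.period_range_h)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "period_range_h" in data:
            data["period_range_h"] = tuple(data["period_range_h"])
        return cls(**data)
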