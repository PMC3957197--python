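"""Actigraphy: actograms, LD profiles, chi-square periodogram, summaries.

Per-minute infrared activity counts from singly housed rats are analyzed in
two regimes: entrained (LD12:12, light masking present) and free-running
(constant darkness, DD), where the endogenous circadian period tau is
expressed.  tau is estimated with the Sokolove–Bushell chi-square
periodogram: for each candidate period P (in bins) the series is folded into
P columns and

    Q_P = sum_h K_h * (M_h - M)^2 / s^2

where ``M_h`` is the column mean over its ``K_h`` contributing bins, ``M``
the grand mean and ``s^2`` the population variance of the series.  Under an
iid null Q_P ~ chi-square(P-1), giving the per-period significance line; the
period estimate is the significant candidate with maximal Q_P.

Group comparisons mirror a conventional actigraphy workup: Student's
equal-variance t for total activity and activity/rest ratio, an exact
Mann–Whitney U for tau (small samples, coarse tie-prone values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ActivityFile

__all__ = [
    "Actogram",
    "PeriodogramResult",
    "ActivitySummary",
    "build_actogram",
    "ld_profile",
    "chi2_periodogram",
    "onset_estimate",
    "activity_summary",
    "compare_groups",
    "split_by_regime",
    "plot_actogram",
]

MINUTES_PER_DAY = 1440.0


@dataclass
class Actogram:
    """Double-plotted raster: row d holds days d and d+1 side by side, so a
    non-24-h rhythm shows as drifting onsets; the final row is single-plotted
    with NaN padding."""

    matrix: np.ndarray  # (n_days, 2 * bins_per_day); NaN pads the last row
    bin_width_min: float
    n_days: int

    @property
    def bins_per_day(self) -> int:
        return self.matrix.shape[1] // 2


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    Q: np.ndarray
    significance_line: np.ndarray
    alpha: float
    tau_hat_h: Optional[float]
    method: str = "chi-square (Sokolove-Bushell)"


@dataclass
class ActivitySummary:
    total_activity: float  # mean counts per 24 h
    activity_rest_ratio: float  # night/day counts (subjective in DD); NaN if undefined
    regime: str  # "LD" | "DD"


def _bins_per_day(activity: ActivityFile) -> int:
    bpd = MINUTES_PER_DAY / activity.bin_width_min
    if abs(bpd - round(bpd)) > 1e-9:
        raise ValueError("bin width must divide 24 h")
    return int(round(bpd))


def split_by_regime(activity: ActivityFile):
    """Split a recording into its entrained (LD) and free-running (DD)
    segments by whole days.

    A day is LD when it contains both light and dark, DD when fully dark.
    Returns ``(ld, dd)``; either can be None when absent.  The free-running
    period is a DD quantity, so periodograms should be run on the DD
    segment of a mixed recording.
    """
    bpd = _bins_per_day(activity)
    n_days = activity.n_bins // bpd
    states = activity.state_per_bin()[: n_days * bpd].reshape(n_days, bpd)
    is_ld = np.array([("light" in day) and ("dark" in day) for day in states])

    def _segment(day_sel: np.ndarray) -> ActivityFile | None:
        days = np.flatnonzero(day_sel)
        if days.size == 0:
            return None
        # contiguous block expected (the study design: LD then DD)
        lo, hi = days[0], days[-1] + 1
        counts = activity.counts[lo * bpd : hi * bpd]
        offset = lo * bpd * activity.bin_width_min
        span = (hi - lo) * bpd * activity.bin_width_min
        schedule = []
        for start, end, state in activity.schedule:
            s, e = max(start - offset, 0.0), min(end - offset, span)
            if e > s:
                schedule.append((s, e, state))
        return ActivityFile(activity.start_timestamp, activity.bin_width_min,
                            counts, schedule)

    return _segment(is_ld), _segment(~is_ld)


def build_actogram(activity: ActivityFile, bin_width_min: float | None = None) -> Actogram:
    """Double-plotted actogram matrix; needs at least 2 full days."""
    bw = activity.bin_width_min if bin_width_min is None else bin_width_min
    counts = activity.counts.astype(float)
    if bw != activity.bin_width_min:
        factor = bw / activity.bin_width_min
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError("bin_width_min must be an integer multiple of the native width")
        factor = int(round(factor))
        n = (counts.size // factor) * factor
        counts = counts[:n].reshape(-1, factor).sum(axis=1)
    bpd = int(round(MINUTES_PER_DAY / bw))
    n_days = counts.size // bpd
    if n_days < 2:
        raise ValueError("actogram needs at least 2 full days of data")
    days = counts[: n_days * bpd].reshape(n_days, bpd)
    matrix = np.full((n_days, 2 * bpd), np.nan)
    matrix[:, :bpd] = days
    matrix[:-1, bpd:] = days[1:]
    return Actogram(matrix, bw, n_days)


def ld_profile(activity: ActivityFile):
    """Mean 24-h activity waveform over LD days, aligned to lights-on = 0.

    Returns (profile_mean, profile_sd), one value per bin of the day.  Days
    are LD when they contain both light and dark; raises if none exist.
    """
    bpd = _bins_per_day(activity)
    states = activity.state_per_bin()
    n_days = activity.n_bins // bpd
    day_states = states[: n_days * bpd].reshape(n_days, bpd)
    counts = activity.counts[: n_days * bpd].reshape(n_days, bpd).astype(float)
    ld_days = [
        d for d in range(n_days)
        if ("light" in day_states[d]) and ("dark" in day_states[d])
    ]
    if not ld_days:
        raise ValueError("no LD days in recording")
    # align to lights-on of the first LD day
    first = day_states[ld_days[0]]
    light_idx = np.flatnonzero(first == "light")
    onset = int(light_idx[0]) if light_idx.size else 0
    aligned = np.roll(counts[ld_days], -onset, axis=1)
    return aligned.mean(axis=0), aligned.std(axis=0, ddof=1)


def chi2_periodogram(
    activity: ActivityFile,
    period_range_h: tuple[float, float] = (20.0, 28.0),
    step_h: float | None = None,
    alpha: float = 0.001,
) -> PeriodogramResult:
    """Sokolove–Bushell chi-square periodogram over candidate periods.

    Candidate periods are integer multiples of the bin width within
    ``period_range_h`` (the natural resolution of the folding statistic;
    ``step_h`` may coarsen this).  ``tau_hat_h`` is the candidate with the
    maximal Q among those exceeding the chi-square(P-1) quantile at
    ``alpha``; None when nothing is significant (e.g. an all-zero or
    arrhythmic series).
    """
    x = activity.counts.astype(float)
    n = x.size
    bw_h = activity.bin_width_min / 60.0
    if n * bw_h / 24.0 < 7:
        raise ValueError("periodogram needs at least 7 days of data")
    lo, hi = period_range_h
    if hi * 1 > n * bw_h:
        raise ValueError("period range exceeds the data span")
    step_bins = 1 if step_h is None else max(1, int(round(step_h / bw_h)))
    p_lo = int(np.ceil(lo / bw_h))
    p_hi = int(np.floor(hi / bw_h))
    var = x.var()
    periods = []
    qs = []
    sig = []
    idx_all = np.arange(n)
    for p_bins in range(p_lo, p_hi + 1, step_bins):
        idx = idx_all % p_bins
        col_n = np.bincount(idx, minlength=p_bins)
        col_mean = np.bincount(idx, weights=x, minlength=p_bins) / col_n
        grand = x.mean()
        q = float(np.sum(col_n * (col_mean - grand) ** 2) / var) if var > 0 else 0.0
        periods.append(p_bins * bw_h)
        qs.append(q)
        sig.append(float(stats.chi2.ppf(1.0 - alpha, p_bins - 1)))
    periods = np.array(periods)
    qs = np.array(qs)
    sig = np.array(sig)
    above = qs > sig
    tau = float(periods[np.argmax(np.where(above, qs, -np.inf))]) if above.any() else None
    return PeriodogramResult(periods, qs, sig, alpha, tau)


def _moving_average(x: np.ndarray, window_bins: int) -> np.ndarray:
    if window_bins % 2 == 0:
        window_bins += 1  # centered smoothing needs odd width
    kernel = np.ones(window_bins) / window_bins
    pad = window_bins // 2
    xp = np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]]) if pad else x
    return np.convolve(xp, kernel, mode="valid")


def onset_estimate(
    activity: ActivityFile,
    tau_h: float,
    smooth_min: float = 29.0,
    sustain_min: float = 30.0,
) -> np.ndarray:
    """Activity-onset time (minutes since recording start) per tau cycle.

    Within each cycle of length tau, the smoothed counts (centred moving
    average, default 29-min window) are scanned for the first bin that rises
    above the cycle mean and stays above it for at least ``sustain_min``.
    Cycles without such a bin (arrhythmic) give NaN.
    """
    bw = activity.bin_width_min
    cycle_bins = int(round(tau_h * 60.0 / bw))
    if cycle_bins < 2:
        raise ValueError("tau too short for the bin width")
    smoothed = _moving_average(activity.counts.astype(float), int(round(smooth_min / bw)))
    sustain_bins = max(1, int(round(sustain_min / bw)))
    n_cycles = activity.n_bins // cycle_bins
    onsets = np.full(n_cycles, np.nan)
    for c in range(n_cycles):
        seg = smoothed[c * cycle_bins : (c + 1) * cycle_bins]
        mean = seg.mean()
        if seg.max() <= mean or np.allclose(seg, seg[0]):
            continue
        above = seg > mean
        for i in range(cycle_bins - sustain_bins + 1):
            if above[i : i + sustain_bins].all():
                onsets[c] = (c * cycle_bins + i) * bw
                break
    return onsets


def activity_summary(
    activity: ActivityFile,
    regime: str,
    tau_h: float | None = None,
    onset_min: float | None = None,
) -> ActivitySummary:
    """Total 24-h activity and activity/rest ratio.

    LD: ratio = counts in dark / counts in light per the schedule (absolute
    clock time is irrelevant, only the schedule matters).  DD: subjective
    night is [onset, onset + tau/2), advancing by tau per cycle; requires
    ``tau_h`` and either an explicit ``onset_min`` or a detectable onset.
    Zero denominator gives a NaN ratio.
    """
    counts = activity.counts.astype(float)
    total = counts.sum() / (activity.duration_min / MINUTES_PER_DAY)
    if regime == "LD":
        states = activity.state_per_bin()
        dark = counts[states == "dark"].sum()
        light = counts[states == "light"].sum()
        ratio = dark / light if light > 0 else float("nan")
        return ActivitySummary(float(total), float(ratio), "LD")
    if regime != "DD":
        raise ValueError("regime must be 'LD' or 'DD'")
    if tau_h is None:
        raise ValueError("DD summary requires tau_h")
    if onset_min is None:
        onsets = onset_estimate(activity, tau_h)
        valid = onsets[~np.isnan(onsets)]
        if valid.size == 0:
            return ActivitySummary(float(total), float("nan"), "DD")
        onset_min = float(valid[0]) % (tau_h * 60.0)
    cycle_min = tau_h * 60.0
    centers = (np.arange(activity.n_bins) + 0.5) * activity.bin_width_min
    phase = (centers - onset_min) % cycle_min
    night = phase < cycle_min / 2.0
    night_sum = counts[night].sum()
    day_sum = counts[~night].sum()
    ratio = night_sum / day_sum if day_sum > 0 else float("nan")
    return ActivitySummary(float(total), float(ratio), "DD")


def compare_groups(summaries: pd.DataFrame) -> pd.DataFrame:
    """Between-genotype comparison table.

    ``summaries`` has one row per animal with columns ``group`` plus any of
    ``total_activity``, ``activity_rest_ratio`` (Student's equal-variance t)
    and ``tau_h`` (exact Mann–Whitney U).  Returns one row per measure with
    the statistic, p, and effect size (r for t-tests; U reported with its
    exact p).
    """
    labels = sorted(summaries["group"].unique())
    if len(labels) != 2:
        raise ValueError("compare_groups needs exactly two groups")
    g1 = summaries[summaries["group"] == labels[0]]
    g2 = summaries[summaries["group"] == labels[1]]
    rows = []
    for col in ("total_activity", "activity_rest_ratio"):
        if col not in summaries.columns:
            continue
        x = g1[col].dropna().to_numpy()
        y = g2[col].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            raise ValueError(f"{col}: need at least 2 values per group")
        res = stats.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
        t = float(res.statistic)
        rows.append(
            {"measure": col, "test": "student_t", "statistic": t, "df": df,
             "p": float(res.pvalue),
             "effect": float(np.sign(t) * np.sqrt(t * t / (t * t + df)))}
        )
    if "tau_h" in summaries.columns:
        x = g1["tau_h"].dropna().to_numpy()
        y = g2["tau_h"].dropna().to_numpy()
        if x.size and y.size:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            rows.append(
                {"measure": "tau_h", "test": "mann_whitney_exact",
                 "statistic": float(res.statistic), "df": np.nan,
                 "p": float(res.pvalue), "effect": np.nan}
            )
    return pd.DataFrame(rows)


def plot_actogram(actogram: Actogram, ax=None, title: str | None = None):
    """Render a double-plotted actogram as a bar raster (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * actogram.n_days + 1))
    m = actogram.matrix
    scale = np.nanmax(m) or 1.0
    hours = np.arange(m.shape[1]) * actogram.bin_width_min / 60.0
    for d in range(actogram.n_days):
        base = actogram.n_days - d
        row = np.nan_to_num(m[d] / scale) * 0.9
        ax.bar(hours, row, width=actogram.bin_width_min / 60.0,
               bottom=base, color="k", align="edge", linewidth=0)
    ax.set_xlim(0, 48)
    ax.set_xticks(range(0, 49, 12))
    ax.set_xlabel("time (h, double-plotted)")
    ax.set_ylabel("day")
    if title:
        ax.set_title(title)
    return ax
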