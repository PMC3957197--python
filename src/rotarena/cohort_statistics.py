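"""The cohort statistical pipeline for place-avoidance metrics.

The pipeline mirrors a small-cohort within/between design with sparse
missingness (~0.6% of values, e.g. tracking dropouts):

1. **Standardize per session** — within each phase × session, metric values
   are z-scored across rats (both groups pooled).  This removes the
   day-to-day performance drift so that averaging over sessions is not
   biased by *which* sessions a rat happens to be missing.
2. **Average per phase, re-standardize** — per rat × phase, the session
   z-values are averaged over available sessions, and the averages are
   z-scored again across rats, giving one score per rat per phase.  With no
   exclusions each phase column then has mean 0 and sample SD 1 by
   construction.
3. **Non-solver exclusion** — rats whose dominant response is freezing
   cannot express avoidance regardless of cognition.  They are flagged by a
   dual criterion: combined-phase total-distance z below a cut (default −1)
   AND mean median absolute post-shock speed below 2 deg/s (no escape
   response).  An equal number of worst-avoidance rats (by combined-phase
   max-time-avoided score) is removed from the other group so the design
   stays balanced.
4. **Mixed ANOVA** — group (between) × phase (within, 2 levels), with
   generalized eta squared effect sizes.  The final standardization forces
   the phase means to zero, so the phase factor is only carried to test the
   group × phase interaction.  Welch's t (with the r effect size
   ``sqrt(t^2/(t^2+df))`` signed by t) serves the single-phase comparisons.

Missing values are never imputed for analysis; :func:`impute_for_plot`
produces a separate plot-only table using the nearest-valid-session rule.
No multiple-testing correction is applied across metrics (documented
limitation).

Sample SD (``ddof=1``) is used in every standardization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "WelchResult",
    "ExclusionResult",
    "standardize_sessions",
    "phase_average",
    "phase_scores",
    "impute_for_plot",
    "flag_nonsolvers",
    "matched_exclusion",
    "mixed_anova_group_by_phase",
    "welch_t",
    "trial_contrasts",
    "preference_ratio",
    "preference_anova",
    "metric_correlations",
    "PlaceAvoidanceAnalysis",
    "PlaceAvoidanceResults",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["rat_id", "group", "phase", "session_index", "metric", "value"]
ANALYSIS_PHASES = ("acquisition", "reversal")


def _effect_r(t: float, df: float) -> float:
    """Correlation effect size for a t statistic: sqrt(t²/(t²+df)), signed."""
    if df <= 0:
        return float("nan")
    return float(np.sign(t) * np.sqrt(t * t / (t * t + df)))


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    ges: float


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    r: float


# --------------------------------------------------------------------------
# Standardization and phase scores


def _check_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s) {missing}")


def standardize_sessions(cohort: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Z-score one metric within each phase × session across rats.

    Missing values are preserved.  Raises if a session has fewer than two
    non-missing values or zero variance (the z-score is undefined), naming
    the session.
    """
    _check_cohort(cohort)
    sub = cohort[cohort["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    for (phase, session), grp in sub.groupby(["phase", "session_index"]):
        vals = grp["value"]
        ok = vals.dropna()
        label = f"{phase} session {session} ({metric})"
        if len(ok) < 2:
            raise ValueError(f"{label}: fewer than 2 non-missing values")
        sd = ok.std(ddof=1)
        if sd == 0:
            raise ValueError(f"{label}: zero variance, z-scores undefined")
        sub.loc[grp.index, "value"] = (vals - ok.mean()) / sd
    return sub


def phase_average(z_table: pd.DataFrame, phases=ANALYSIS_PHASES) -> pd.DataFrame:
    """Average session z-values per rat × phase, then re-standardize across
    rats within each phase.

    Returns a long table (rat_id, group, phase, metric, score).  Rats with a
    fully missing phase are dropped from that metric with a log entry.
    """
    _check_cohort(z_table)
    sub = z_table[z_table["phase"].isin(phases)]
    rows = []
    for (metric, phase), grp in sub.groupby(["metric", "phase"]):
        means = grp.groupby("rat_id")["value"].mean()  # NaN-skipping
        dropped = means[means.isna()].index.tolist()
        for rat in dropped:
            logger.warning(
                "rat %s has no valid %s sessions for %s; dropped from this metric",
                rat, phase, metric,
            )
        means = means.dropna()
        z = (means - means.mean()) / means.std(ddof=1)
        groups = grp.drop_duplicates("rat_id").set_index("rat_id")["group"]
        for rat, score in z.items():
            rows.append(
                {"rat_id": rat, "group": groups[rat], "phase": phase,
                 "metric": metric, "score": score}
            )
    return pd.DataFrame(rows)


def phase_scores(cohort: pd.DataFrame, metric: str, phases=ANALYSIS_PHASES) -> pd.DataFrame:
    """Standardize per session, then average and re-standardize per phase."""
    return phase_average(standardize_sessions(cohort, metric), phases=phases)


def combined_phase_score(scores: pd.DataFrame, metric: str) -> pd.Series:
    """Mean of the two phase scores per rat, re-standardized across rats."""
    sub = scores[scores["metric"] == metric]
    means = sub.groupby("rat_id")["score"].mean()
    return (means - means.mean()) / means.std(ddof=1)


# --------------------------------------------------------------------------
# Plot-only imputation


def impute_for_plot(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fill missing values for plotting only; analysis never consumes these.

    Rule: a missing session takes the closest valid value from the same
    phase for that rat; when both immediately adjacent sessions are valid,
    their average; equidistant-at-larger-distance ties prefer the earlier
    session.  A fully missing phase stays missing.  Adds an ``imputed``
    flag column.
    """
    _check_cohort(cohort)
    out = cohort.copy()
    out["imputed"] = False
    for (rat, phase, metric), grp in out.groupby(["rat_id", "phase", "metric"]):
        grp = grp.sort_values("session_index")
        vals = grp["value"].to_numpy(dtype=float)
        sessions = grp["session_index"].to_numpy()
        valid = ~np.isnan(vals)
        if valid.all() or not valid.any():
            continue
        filled = vals.copy()
        for i in np.flatnonzero(~valid):
            left_ok = i > 0 and valid[i - 1]
            right_ok = i + 1 < len(vals) and valid[i + 1]
            if left_ok and right_ok:
                filled[i] = 0.5 * (vals[i - 1] + vals[i + 1])
                continue
            dist = np.abs(sessions[valid] - sessions[i])
            # stable argmin prefers the earlier session on ties
            j = np.flatnonzero(valid)[int(np.argmin(dist))]
            filled[i] = vals[j]
        out.loc[grp.index, "value"] = filled
        out.loc[grp.index[~valid], "imputed"] = True
    return out


# --------------------------------------------------------------------------
# Non-solver flagging and matched exclusion


def flag_nonsolvers(
    cohort: pd.DataFrame,
    z_cut: float = -1.0,
    speed_cut_deg_s: float = 2.0,
    phases=ANALYSIS_PHASES,
    distance_metric: str = "total_distance_m",
    speed_metric: str = "median_abs_speed_after_shock_deg_s",
) -> pd.DataFrame:
    """Identify freezing non-solvers by the dual criterion.

    A rat is flagged when BOTH its combined-phase standardized total
    distance is below ``z_cut`` (a guard for low locomotion) and its mean
    median absolute post-shock speed is below ``speed_cut_deg_s`` (no escape
    response — the discriminating criterion).  Returns one row per rat with
    both statistics and the flag.
    """
    scores = phase_scores(cohort, distance_metric, phases=phases)
    z = combined_phase_score(scores, distance_metric)
    speeds = (
        cohort[(cohort["metric"] == speed_metric) & cohort["phase"].isin(phases)]
        .groupby("rat_id")["value"]
        .mean()
    )
    groups = cohort.drop_duplicates("rat_id").set_index("rat_id")["group"]
    table = pd.DataFrame(
        {
            "group": groups.reindex(z.index),
            "z_total_distance": z,
            "mean_speed_after_shock": speeds.reindex(z.index),
        }
    )
    table["flagged"] = (table["z_total_distance"] < z_cut) & (
        table["mean_speed_after_shock"] < speed_cut_deg_s
    )
    return table.reset_index().rename(columns={"index": "rat_id"})


@dataclass
class ExclusionResult:
    flagged: list
    matched: list
    analysis_rats: list
    log: list = field(default_factory=list)


def matched_exclusion(
    flags: pd.DataFrame | list,
    cohort: pd.DataFrame,
    phases=ANALYSIS_PHASES,
    avoidance_metric: str = "max_time_avoided_s",
) -> ExclusionResult:
    """Remove flagged rats plus an equal count of worst avoiders from the
    other group, so both groups shrink equally.

    The matched rats are those with the lowest mean of the (acquisition,
    reversal) standardized max-time-avoided scores; ties break by rat_id
    order and are logged.
    """
    if isinstance(flags, pd.DataFrame):
        flagged = flags.loc[flags["flagged"], "rat_id"].tolist()
    else:
        flagged = list(flags)
    groups = cohort.drop_duplicates("rat_id").set_index("rat_id")["group"]
    all_rats = sorted(groups.index)
    unknown = set(flagged) - set(all_rats)
    if unknown:
        raise ValueError(f"flagged rat(s) not in cohort: {sorted(unknown)}")
    if not flagged:
        return ExclusionResult([], [], all_rats, ["no rats flagged; identity"])
    flagged_groups = {groups[r] for r in flagged}
    if len(flagged_groups) > 1:
        raise ValueError(
            "flagged rats span both groups; matched exclusion is defined for "
            "flags confined to one group"
        )
    (flag_group,) = flagged_groups
    other_rats = [r for r in all_rats if groups[r] != flag_group]
    k = len(flagged)
    if k > len(other_rats):
        raise ValueError(f"cannot remove {k} rats from a group of {len(other_rats)}")
    scores = phase_scores(cohort, avoidance_metric, phases=phases)
    mean_score = (
        scores[scores["rat_id"].isin(other_rats)]
        .groupby("rat_id")["score"]
        .mean()
        .sort_index()  # rat_id order is the documented tie-break
    )
    order = mean_score.sort_values(kind="stable").index.tolist()
    matched = order[:k]
    log = [f"flagged (non-solver): {sorted(flagged)}",
           f"matched removal from {groups[matched[0]]}: {matched}"]
    ties = mean_score[mean_score == mean_score.loc[matched[-1]]]
    if len(ties) > 1:
        log.append(f"tie at cutoff score {ties.iloc[0]:.6g} broken by rat_id order")
    keep = [r for r in all_rats if r not in set(flagged) | set(matched)]
    return ExclusionResult(sorted(flagged), matched, keep, log)


# --------------------------------------------------------------------------
# Mixed ANOVA (one between factor × one 2-level within factor)


def _mixed_anova_arrays(y: np.ndarray, groups: np.ndarray, within_name: str = "phase"):
    """Sums-of-squares mixed ANOVA for an (n_subjects, 2) response matrix.

    Exact for a 2-level within factor (no sphericity correction needed).
    Generalized eta squared follows the additive-error formulation:
    SS_effect / (SS_effect + SS_subjects-within-groups + SS_residual).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("response must be (n_subjects, 2)")
    if np.isnan(y).any():
        raise ValueError("mixed ANOVA requires both within-factor levels per subject")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n = y.shape[0]
    b = y.shape[1]
    a = labels.size
    if a < 2:
        raise ValueError("need at least two groups")
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_bs = b * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_int = 0.0
    phase_means = y.mean(axis=0)
    ss_within_factor = n * np.sum((phase_means - grand) ** 2)
    for g in labels:
        sel = groups == g
        ng = sel.sum()
        gmean = y[sel].mean()
        ss_group += b * ng * (gmean - grand) ** 2
        cell = y[sel].mean(axis=0)
        ss_int += ng * np.sum((cell - gmean - phase_means + grand) ** 2)
    ss_subj_w = ss_bs - ss_group
    ss_total = np.sum((y - grand) ** 2)
    ss_err_w = ss_total - ss_bs - ss_within_factor - ss_int
    df_group, df_subj = a - 1, n - a
    df_within, df_int, df_err = b - 1, (a - 1) * (b - 1), (n - a) * (b - 1)
    ss_err_all = ss_subj_w + ss_err_w

    def _res(name, ss, df1, ms_err, df2):
        F = (ss / df1) / ms_err if ms_err > 0 else float("nan")
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else float("nan")
        ges = ss / (ss + ss_err_all) if (ss + ss_err_all) > 0 else 0.0
        return AnovaResult(name, float(F), df1, df2, p, float(ges))

    ms_subj = ss_subj_w / df_subj if df_subj else np.nan
    ms_err = ss_err_w / df_err if df_err else np.nan
    return {
        "group": _res("group", ss_group, df_group, ms_subj, df_subj),
        within_name: _res(within_name, ss_within_factor, df_within, ms_err, df_err),
        f"group:{within_name}": _res(f"group:{within_name}", ss_int, df_int, ms_err, df_err),
    }


def mixed_anova_group_by_phase(
    scores: pd.DataFrame,
    within: str = "phase",
    value: str = "score",
    include_within_main: bool = False,
) -> list[AnovaResult]:
    """Group (between) × 2-level within-factor mixed ANOVA on a long table.

    ``scores`` needs columns rat_id, group, ``within`` and ``value``.  By
    default the within-factor main effect is suppressed: after the final
    standardization both within-level means are zero by construction, so the
    factor is carried only to test the interaction.
    """
    wide = scores.pivot(index="rat_id", columns=within, values=value)
    if wide.shape[1] != 2:
        raise ValueError(f"expected exactly 2 {within} levels, got {wide.shape[1]}")
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"rats missing a {within} level: {bad}")
    groups = scores.drop_duplicates("rat_id").set_index("rat_id")["group"]
    res = _mixed_anova_arrays(wide.to_numpy(), groups.reindex(wide.index).to_numpy(),
                              within_name=within)
    out = [res["group"]]
    if include_within_main:
        out.append(res[within])
    out.append(res[f"group:{within}"])
    return out


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance t-test with fractional df and r effect size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs at least 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            df = float(x.size + y.size - 2)
            return WelchResult(0.0, df, 1.0, 0.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    t, df = float(res.statistic), float(res.df)
    return WelchResult(t, df, float(res.pvalue), _effect_r(t, df))


# --------------------------------------------------------------------------
# Polynomial trial contrasts (step-through avoidance)

#: Orthonormal polynomial contrasts over 3 ordered trials.
LINEAR_CONTRAST = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
QUADRATIC_CONTRAST = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)


@dataclass
class TrialContrastResults:
    """Contrast main effects, group interactions, per-group follow-ups and
    per-trial Welch tests, each as (t, df, p, r) rows."""

    tests: pd.DataFrame
    per_trial: pd.DataFrame
    scores: pd.DataFrame
    dropped: list


def trial_contrasts(latencies: pd.DataFrame) -> TrialContrastResults:
    """Polynomial (linear, quadratic) contrasts over 3 ordered trials.

    ``latencies`` is long: rat_id, group, trial (1..3), latency_s.  Per-rat
    contrast scores use orthonormalized weights; contrast tests pool the
    within-subject error over both contrasts (df = 2·(n − n_groups)),
    per-group follow-ups pool within the group (df = 2·(n_g − 1)).  Rats
    missing a trial are dropped with a log entry.
    """
    wide = latencies.pivot(index="rat_id", columns="trial", values="latency_s")
    wide = wide.reindex(columns=sorted(wide.columns))
    if wide.shape[1] != 3:
        raise ValueError("trial_contrasts expects exactly 3 ordered trials")
    dropped = wide[wide.isna().any(axis=1)].index.tolist()
    for rat in dropped:
        logger.warning("rat %s missing a trial; dropped from contrasts", rat)
    wide = wide.dropna()
    groups = latencies.drop_duplicates("rat_id").set_index("rat_id")["group"]
    groups = groups.reindex(wide.index)
    y = wide.to_numpy()
    scores = pd.DataFrame(
        {
            "rat_id": wide.index,
            "group": groups.to_numpy(),
            "linear": y @ LINEAR_CONTRAST,
            "quadratic": y @ QUADRATIC_CONTRAST,
        }
    )
    labels = sorted(scores["group"].unique())
    n = len(scores)
    n_groups = len(labels)

    # pooled within-group error over both orthonormal contrasts
    ss_err = 0.0
    for c in ("linear", "quadratic"):
        for g in labels:
            vals = scores.loc[scores["group"] == g, c].to_numpy()
            ss_err += np.sum((vals - vals.mean()) ** 2)
    df_err = 2 * (n - n_groups)
    ms_err = ss_err / df_err

    rows = []
    for c in ("linear", "quadratic"):
        vals = scores[c].to_numpy()
        t = vals.mean() / np.sqrt(ms_err / n)
        rows.append(("trial_" + c, t, df_err))
        if n_groups == 2:
            g1 = scores.loc[scores["group"] == labels[0], c].to_numpy()
            g2 = scores.loc[scores["group"] == labels[1], c].to_numpy()
            t_int = (g2.mean() - g1.mean()) / np.sqrt(
                ms_err * (1.0 / g1.size + 1.0 / g2.size)
            )
            rows.append((f"trial_{c}:group", t_int, df_err))
        for g in labels:
            gv = scores.loc[scores["group"] == g]
            ss_g = sum(
                np.sum((gv[cc] - gv[cc].mean()) ** 2) for cc in ("linear", "quadratic")
            )
            df_g = 2 * (len(gv) - 1)
            ms_g = ss_g / df_g
            t_g = gv[c].mean() / np.sqrt(ms_g / len(gv))
            rows.append((f"trial_{c}[{g}]", t_g, df_g))
    tests = pd.DataFrame(rows, columns=["effect", "t", "df"])
    tests["p"] = 2 * stats.t.sf(np.abs(tests["t"]), tests["df"])
    tests["r"] = [_effect_r(t, df) for t, df in zip(tests["t"], tests["df"])]

    per_trial_rows = []
    if n_groups == 2:
        for trial in wide.columns:
            g1 = wide.loc[groups == labels[0], trial]
            g2 = wide.loc[groups == labels[1], trial]
            w = welch_t(g2, g1)
            per_trial_rows.append(
                {"trial": trial, "t": w.t, "df": w.df, "p": w.p, "r": w.r}
            )
    return TrialContrastResults(tests, pd.DataFrame(per_trial_rows), scores, dropped)


# --------------------------------------------------------------------------
# Taste preference


def preference_ratio(annotations: pd.DataFrame) -> pd.DataFrame:
    """Saccharin preference per rat × session: saccharin/(saccharin+water).

    Sessions with zero total intake yield NaN (undefined preference).
    """
    need = {"rat_id", "group_label", "session_index", "saccharin_mass_g", "water_mass_g"}
    missing = need - set(annotations.columns)
    if missing:
        raise ValueError(f"annotations missing column(s) {sorted(missing)}")
    sub = annotations.dropna(subset=["saccharin_mass_g", "water_mass_g"]).copy()
    total = sub["saccharin_mass_g"] + sub["water_mass_g"]
    ratio = np.where(total > 0, sub["saccharin_mass_g"] / total, np.nan)
    return pd.DataFrame(
        {
            "rat_id": sub["rat_id"],
            "group": sub["group_label"],
            "session_index": sub["session_index"],
            "ratio": ratio,
        }
    ).reset_index(drop=True)


def preference_anova(ratios: pd.DataFrame) -> list[AnovaResult]:
    """Group × session mixed ANOVA on the preference ratio (2 sessions)."""
    df = ratios.rename(columns={"session_index": "session", "ratio": "score"})
    return mixed_anova_group_by_phase(
        df, within="session", include_within_main=True
    )


# --------------------------------------------------------------------------
# Correlations


def metric_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between phase-level metric scores.

    ``scores`` is the long phase-score table; columns of the result are
    ``metric @ phase`` pairs.  Constant columns give NaN cells.
    """
    wide = scores.pivot_table(
        index="rat_id", columns=["metric", "phase"], values="score"
    )
    wide.columns = [f"{m} @ {p}" for m, p in wide.columns]
    return wide.corr()


# --------------------------------------------------------------------------
# Fitted-model style wrapper


class PlaceAvoidanceAnalysis:
    """The full cohort pipeline as a fit-once analysis object.

    Parameters
    ----------
    cohort : long metric table (rat_id, group, phase, session_index, metric,
        value).
    metrics : metrics to run the group × phase ANOVA on; defaults to the
        four phase-analyzed measures.
    z_cut, speed_cut_deg_s : non-solver flagging thresholds.
    exclude : whether to apply non-solver + matched exclusion before the
        "excluded" analyses (both with- and without-exclusion ANOVAs are
        always reported when exclusions exist, mirroring the study design).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        metrics=("total_distance_m", "max_time_avoided_s",
                 "mean_dist_center_cm", "defecation"),
        z_cut: float = -1.0,
        speed_cut_deg_s: float = 2.0,
        exclude: bool = True,
    ):
        _check_cohort(cohort)
        self.cohort = cohort
        self.metrics = tuple(metrics)
        self.z_cut = z_cut
        self.speed_cut_deg_s = speed_cut_deg_s
        self.exclude = exclude

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "PlaceAvoidanceAnalysis":
        return cls(cohort, **kwargs)

    def fit(self) -> "PlaceAvoidanceResults":
        flags = flag_nonsolvers(
            self.cohort, z_cut=self.z_cut, speed_cut_deg_s=self.speed_cut_deg_s
        )
        exclusion = (
            matched_exclusion(flags, self.cohort)
            if self.exclude
            else ExclusionResult([], [], sorted(self.cohort["rat_id"].unique()))
        )
        anovas = {}
        score_tables = {}
        for metric in self.metrics:
            scores_all = phase_scores(self.cohort, metric)
            score_tables[metric] = scores_all
            anovas[(metric, "all")] = mixed_anova_group_by_phase(scores_all)
            if exclusion.flagged:
                kept = self.cohort[self.cohort["rat_id"].isin(exclusion.analysis_rats)]
                scores_kept = phase_scores(kept, metric)
                anovas[(metric, "excluded")] = mixed_anova_group_by_phase(scores_kept)
        all_scores = pd.concat(score_tables.values(), ignore_index=True)
        return PlaceAvoidanceResults(
            flags=flags,
            exclusion=exclusion,
            anovas=anovas,
            phase_score_table=all_scores,
            correlations=metric_correlations(all_scores),
        )


@dataclass
class PlaceAvoidanceResults:
    flags: pd.DataFrame
    exclusion: ExclusionResult
    anovas: dict
    phase_score_table: pd.DataFrame
    correlations: pd.DataFrame

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for (metric, subset), results in self.anovas.items():
            for res in results:
                rows.append(
                    {"metric": metric, "subset": subset, "effect": res.effect,
                     "F": res.F, "df1": res.df1, "df2": res.df2, "p": res.p,
                     "ges": res.ges}
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Place-avoidance cohort analysis", "=" * 32]
        lines.append(f"flagged non-solvers : {self.exclusion.flagged}")
        lines.append(f"matched removals    : {self.exclusion.matched}")
        lines.append(f"analysis set (n={len(self.exclusion.analysis_rats)}): "
                     f"{self.exclusion.analysis_rats}")
        lines.append("")
        tab = self.anova_table()
        if not tab.empty:
            lines.append(tab.to_string(index=False,
                                       float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
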