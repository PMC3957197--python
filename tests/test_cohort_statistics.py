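"""Standardization, exclusion, mixed ANOVA, contrasts, preference ratio."""

import numpy as np
import pandas as pd
import pytest

from rotarena import cohort_statistics as cs
from rotarena.synthetic import simulate_metric_cohort, simulate_step_through

from .oracles import mixed_anova_naive


def long_table(values, metric="m", phases=("acquisition",)):
    """values: dict rat -> list per session (one phase) or nested per phase."""
    rows = []
    for rat, v in values.items():
        group = "knockdown" if rat.startswith("k") else "control"
        per_phase = v if isinstance(v, dict) else {phases[0]: v}
        for phase, sessions in per_phase.items():
            for s, val in enumerate(sessions, start=1):
                rows.append(
                    {"rat_id": rat, "group": group, "phase": phase,
                     "session_index": s, "metric": metric, "value": val}
                )
    return pd.DataFrame(rows)


class TestStandardize:
    def test_three_values_give_unit_z(self):
        df = long_table({"c1": [1.0], "c2": [2.0], "k1": [3.0]})
        z = cs.standardize_sessions(df, "m")
        assert sorted(z["value"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        df = long_table({f"c{i}": rng.normal(5, 3, size=4).tolist() for i in range(8)})
        z = cs.standardize_sessions(df, "m")
        for _, grp in z.groupby("session_index"):
            assert grp["value"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["value"].std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        vals = {f"c{i}": rng.normal(size=3).tolist() for i in range(6)}
        z1 = cs.standardize_sessions(long_table(vals), "m")
        shifted = {r: [7.5 + 3.2 * v for v in vs] for r, vs in vals.items()}
        z2 = cs.standardize_sessions(long_table(shifted), "m")
        np.testing.assert_allclose(z1["value"], z2["value"], atol=1e-12)

    def test_missing_preserved(self):
        df = long_table({"c1": [1.0], "c2": [2.0], "c3": [np.nan], "k1": [3.0]})
        z = cs.standardize_sessions(df, "m")
        assert z["value"].isna().sum() == 1

    def test_zero_variance_names_session(self):
        df = long_table({"c1": [2.0], "c2": [2.0], "k1": [2.0]})
        with pytest.raises(ValueError, match="session 1"):
            cs.standardize_sessions(df, "m")


class TestPhaseScores:
    def _cohort(self, rng, n=9, n_sessions=5):
        return simulate_metric_cohort(n_per_group=n, n_sessions=n_sessions,
                                      rng=rng, metric="m")

    def test_no_exclusion_scores_mean_zero_sd_one(self, rng):
        scores = cs.phase_scores(self._cohort(rng), "m")
        for phase, grp in scores.groupby("phase"):
            assert grp["score"].mean() == pytest.approx(0.0, abs=1e-12)
            assert grp["score"].std(ddof=1) == pytest.approx(1.0)

    def test_identical_sessions_preserve_ranking(self, rng):
        base = rng.normal(size=6)
        vals = {f"c{i}": [base[i]] * 5 for i in range(6)}
        scores = cs.phase_scores(long_table(vals), "m")
        order = scores.sort_values("score")["rat_id"].tolist()
        expected = [f"c{i}" for i in np.argsort(base)]
        assert order == expected

    def test_missingness_does_not_flip_complete_rats(self, rng):
        """Sign of a complete rat's phase score is stable under random
        missingness planted in other rats, against a brute-force
        recomputation from the masked table."""
        cohort = self._cohort(rng)
        masked = cohort.copy()
        others = masked["rat_id"] != "co01"
        idx = masked[others].sample(n=10, random_state=0).index
        masked.loc[idx, "value"] = np.nan
        scores = cs.phase_scores(masked, "m")

        # brute-force recomputation with plain loops
        for phase in ("acquisition", "reversal"):
            sub = masked[masked["phase"] == phase]
            z = {}
            for s, grp in sub.groupby("session_index"):
                v = grp.set_index("rat_id")["value"]
                ok = v.dropna()
                z[s] = (v - ok.mean()) / ok.std(ddof=1)
            per_rat = {}
            for rat in sub["rat_id"].unique():
                vals = [z[s][rat] for s in z if not np.isnan(z[s][rat])]
                per_rat[rat] = np.mean(vals)
            means = pd.Series(per_rat)
            final = (means - means.mean()) / means.std(ddof=1)
            got = scores[(scores["phase"] == phase)
                         & (scores["rat_id"] == "co01")]["score"].iloc[0]
            assert got == pytest.approx(final["co01"], abs=1e-10)


class TestImputeForPlot:
    def _df(self, sessions):
        return long_table({"c1": sessions, "c2": [1.0] * len(sessions)})

    def test_missing_first_copies_second(self):
        out = cs.impute_for_plot(self._df([np.nan, 4.0, 5.0]))
        row = out[(out.rat_id == "c1") & (out.session_index == 1)]
        assert row["value"].iloc[0] == 4.0
        assert row["imputed"].iloc[0]

    def test_middle_with_valid_neighbors_averaged(self):
        out = cs.impute_for_plot(self._df([1.0, 2.0, np.nan, 6.0, 3.0]))
        row = out[(out.rat_id == "c1") & (out.session_index == 3)]
        assert row["value"].iloc[0] == pytest.approx(4.0)

    def test_neighbor_missing_takes_nearest_earlier(self):
        out = cs.impute_for_plot(self._df([1.0, 2.0, np.nan, np.nan, 5.0]))
        s3 = out[(out.rat_id == "c1") & (out.session_index == 3)]["value"].iloc[0]
        assert s3 == 2.0  # session 2 at distance 1 beats session 5 at 2

    def test_equidistant_far_tie_prefers_earlier(self):
        out = cs.impute_for_plot(self._df([1.0, np.nan, np.nan, np.nan, 5.0]))
        s3 = out[(out.rat_id == "c1") & (out.session_index == 3)]["value"].iloc[0]
        assert s3 == 1.0

    def test_fully_missing_phase_left_missing(self):
        out = cs.impute_for_plot(self._df([np.nan, np.nan]))
        assert out[out.rat_id == "c1"]["value"].isna().all()

    def test_analysis_never_sees_imputed_values(self, rng):
        cohort = simulate_metric_cohort(rng=rng, metric="m", missing_rate=0.05)
        imputed = cs.impute_for_plot(cohort)
        # scores from the original table are unchanged by running imputation
        s1 = cs.phase_scores(cohort, "m")
        s2 = cs.phase_scores(cohort, "m")
        pd.testing.assert_frame_equal(s1, s2)
        assert imputed["value"].isna().sum() <= cohort["value"].isna().sum()


class TestMixedAnova:
    def test_identical_groups_null_F(self):
        y = np.array([[1.0, 2.0], [3.0, 1.0], [1.0, 2.0], [3.0, 1.0]])
        res = cs._mixed_anova_arrays(y, np.array(["a", "a", "b", "b"]))
        assert res["group"].F == pytest.approx(0.0, abs=1e-12)
        assert res["group"].ges == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_per_group", [2, 3, 4, 6])
    def test_matches_naive_ss_oracle(self, n_per_group, rng):
        for _ in range(10):
            y = rng.normal(size=(2 * n_per_group, 2))
            groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
            res = cs._mixed_anova_arrays(y, groups)
            oracle = mixed_anova_naive(y, groups)
            for mine, theirs in (
                (res["group"], oracle["group"]),
                (res["phase"], oracle["phase"]),
                (res["group:phase"], oracle["interaction"]),
            ):
                F, df1, df2, ges = theirs
                assert mine.F == pytest.approx(F, rel=1e-9)
                assert (mine.df1, mine.df2) == (df1, df2)
                assert mine.ges == pytest.approx(ges, rel=1e-9)
                assert 0.0 <= mine.ges <= 1.0

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        rows = []
        for g in ("a", "b"):
            for j in range(6):
                for ph in ("acquisition", "reversal"):
                    rows.append({"rat_id": f"{g}{j}", "group": g, "phase": ph,
                                 "score": rng.normal()})
        df = pd.DataFrame(rows)
        mine = cs.mixed_anova_group_by_phase(df, include_within_main=True)
        ref = pingouin.mixed_anova(data=df, dv="score", within="phase",
                                   subject="rat_id", between="group",
                                   effsize="ng2")
        by_name = {r.effect: r for r in mine}
        for source, effect in (("group", "group"), ("phase", "phase"),
                               ("Interaction", "group:phase")):
            row = ref[ref["Source"] == source].iloc[0]
            assert by_name[effect].F == pytest.approx(row["F"], rel=1e-9)
            assert by_name[effect].p == pytest.approx(row["p_unc"], rel=1e-9)
            assert by_name[effect].ges == pytest.approx(row["ng2"], rel=1e-9)

    def test_missing_phase_rejected(self):
        df = pd.DataFrame(
            {"rat_id": ["a1", "a1", "b1"], "group": ["a", "a", "b"],
             "phase": ["acquisition", "reversal", "acquisition"],
             "score": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="b1"):
            cs.mixed_anova_group_by_phase(df)

    def test_planted_interaction_detected(self, rng):
        """A 1-SD group shift on acquisition only shows up as a group x
        phase interaction well above the 5% null rate at n = 6 + 6."""
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            df = simulate_metric_cohort(
                n_per_group=6, rng=rng, metric="m",
                group_shift={"acquisition": 1.0},
            )
            scores = cs.phase_scores(df, "m")
            res = cs.mixed_anova_group_by_phase(scores)
            interaction = [r for r in res if r.effect == "group:phase"][0]
            hits += interaction.p < 0.05
        assert hits / n_rep > 0.2

    def test_planted_group_shift_recovered(self, rng):
        """A 1.5-SD between-group difference on both phases yields a
        significant group effect in > 80% of 6 + 6 cohorts."""
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            df = simulate_metric_cohort(
                n_per_group=6, rng=rng, metric="max_time_avoided_s",
                group_shift={"acquisition": 1.5, "reversal": 1.5},
            )
            scores = cs.phase_scores(df, "max_time_avoided_s")
            res = cs.mixed_anova_group_by_phase(scores)
            hits += res[0].p < 0.05
        assert hits / n_rep > 0.8


class TestWelch:
    def test_identical_groups(self):
        res = cs.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.r == 0.0

    def test_textbook_hand_computation(self):
        # means 2 and 5, each var 1 with n=3: t = -3 / sqrt(2/3), df = 4
        res = cs.welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.df == pytest.approx(4.0, rel=1e-12)
        assert res.r == pytest.approx(
            -np.sqrt(res.t**2 / (res.t**2 + res.df)), rel=1e-12
        )

    def test_welch_df_bounded_by_pooled(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(scale=rng.uniform(0.5, 3), size=8)
            res = cs.welch_t(x, y)
            assert res.df <= 11.0 + 1e-9
            assert abs(res.r) < 1.0

    def test_degenerate_equal_constant_groups(self):
        res = cs.welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0


class TestTrialContrasts:
    def _df(self, per_rat):
        rows = []
        for rat, (group, lat) in per_rat.items():
            for trial, v in enumerate(lat, start=1):
                rows.append({"rat_id": rat, "group": group, "trial": trial,
                             "latency_s": v})
        return pd.DataFrame(rows)

    def test_monotone_latencies_pure_linear(self):
        df = self._df({"c1": ("control", [10, 20, 30]),
                       "c2": ("control", [12, 22, 32]),
                       "k1": ("knockdown", [10, 20, 30]),
                       "k2": ("knockdown", [11, 21, 31])})
        res = cs.trial_contrasts(df)
        assert (res.scores["linear"] > 0).all()
        np.testing.assert_allclose(res.scores["quadratic"], 0.0, atol=1e-12)

    def test_peak_latency_pure_negative_quadratic(self):
        df = self._df({"c1": ("control", [10, 30, 10]),
                       "c2": ("control", [12, 28, 12]),
                       "k1": ("knockdown", [10, 30, 10]),
                       "k2": ("knockdown", [9, 29, 9])})
        res = cs.trial_contrasts(df)
        np.testing.assert_allclose(res.scores["linear"], 0.0, atol=1e-12)
        assert (res.scores["quadratic"] < 0).all()

    def test_planted_group_by_trial_interaction_sign(self):
        """Control-like decreasing vs knockdown-like increasing latencies
        give a positive linear-contrast x group interaction."""
        df = simulate_step_through(seed=3)
        res = cs.trial_contrasts(df)
        inter = res.tests[res.tests["effect"] == "trial_linear:group"].iloc[0]
        assert inter.t > 0 and inter.p < 0.05
        # per-group slopes go opposite ways
        ctl = res.tests[res.tests["effect"] == "trial_linear[control]"].iloc[0]
        kd = res.tests[res.tests["effect"] == "trial_linear[knockdown]"].iloc[0]
        assert ctl.t < 0 < kd.t

    def test_pooled_contrast_df(self):
        # 9 + 9 rats, 3 trials: contrast error df = 2 * (18 - 2) = 32;
        # per-group follow-up df = 2 * (9 - 1) = 16
        df = simulate_step_through(seed=1)
        res = cs.trial_contrasts(df)
        main = res.tests[res.tests["effect"] == "trial_linear"].iloc[0]
        assert main.df == 32
        grp = res.tests[res.tests["effect"] == "trial_linear[control]"].iloc[0]
        assert grp.df == 16

    def test_rat_missing_trial_dropped(self):
        df = self._df({"c1": ("control", [10, 20, 30]),
                       "c2": ("control", [10, 21, 29]),
                       "k1": ("knockdown", [10, np.nan, 30]),
                       "k2": ("knockdown", [12, 20, 28]),
                       "k3": ("knockdown", [11, 20, 29])})
        res = cs.trial_contrasts(df)
        assert res.dropped == ["k1"]
        assert "k1" not in set(res.scores["rat_id"])

    def test_never_crossing_subjects_hit_cap(self):
        df = simulate_step_through(seed=0, never_cross_groups=("knockdown",))
        kd = df[df["group"] == "knockdown"]
        assert (kd["latency_s"] == 300.0).all()


class TestPreference:
    def _ann(self, rows):
        return pd.DataFrame(rows, columns=["rat_id", "group_label",
                                           "session_index", "saccharin_mass_g",
                                           "water_mass_g"])

    def test_equal_masses_half(self):
        df = self._ann([["r1", "control", 1, 5.0, 5.0]])
        assert cs.preference_ratio(df)["ratio"].iloc[0] == 0.5

    def test_water_only_zero(self):
        df = self._ann([["r1", "control", 1, 0.0, 7.0]])
        assert cs.preference_ratio(df)["ratio"].iloc[0] == 0.0

    def test_zero_total_undefined(self):
        df = self._ann([["r1", "control", 1, 0.0, 0.0]])
        assert np.isnan(cs.preference_ratio(df)["ratio"].iloc[0])

    def test_preference_anova_runs(self, rng):
        rows = []
        for g in ("control", "knockdown"):
            for j in range(6):
                for s in (1, 2):
                    rows.append([f"{g[:2]}{j}", g, s,
                                 max(rng.normal(8, 2), 0.1),
                                 max(rng.normal(4, 1), 0.1)])
        ratios = cs.preference_ratio(self._ann(rows))
        res = cs.preference_anova(ratios)
        assert {r.effect for r in res} == {"group", "session", "group:session"}
        assert all(np.isfinite(r.F) for r in res)


class TestCorrelations:
    def test_self_one_negation_minus_one(self, rng):
        scores = []
        vals = rng.normal(size=8)
        for i, v in enumerate(vals):
            for metric, x in (("a", v), ("b", -v)):
                scores.append({"rat_id": f"r{i}", "group": "control",
                               "phase": "acquisition", "metric": metric,
                               "score": x})
        corr = cs.metric_correlations(pd.DataFrame(scores))
        assert corr.loc["a @ acquisition", "a @ acquisition"] == pytest.approx(1.0)
        assert corr.loc["a @ acquisition", "b @ acquisition"] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T)

    def test_independent_metrics_near_zero(self, rng):
        n = 2000
        scores = []
        for i in range(n):
            scores.append({"rat_id": f"r{i}", "group": "c",
                           "phase": "acquisition", "metric": "a",
                           "score": rng.normal()})
            scores.append({"rat_id": f"r{i}", "group": "c",
                           "phase": "acquisition", "metric": "b",
                           "score": rng.normal()})
        corr = cs.metric_correlations(pd.DataFrame(scores))
        assert abs(corr.loc["a @ acquisition", "b @ acquisition"]) < 0.08


class TestExclusion:
    def test_no_flags_identity(self, rng):
        cohort = simulate_metric_cohort(rng=rng, metric="max_time_avoided_s")
        res = cs.matched_exclusion([], cohort)
        assert res.flagged == [] and res.matched == []
        assert len(res.analysis_rats) == 18

    def test_flags_in_both_groups_rejected(self, rng):
        cohort = simulate_metric_cohort(rng=rng, metric="max_time_avoided_s")
        with pytest.raises(ValueError, match="both groups"):
            cs.matched_exclusion(["co01", "kn01"], cohort)

    def test_removal_count_exceeding_group_rejected(self, rng):
        # unequal groups: 4 controls flagged out of 4, only 2 knockdowns
        rows = []
        for rat, group in (("c1", "control"), ("c2", "control"),
                           ("c3", "control"), ("c4", "control"),
                           ("k1", "knockdown"), ("k2", "knockdown")):
            for phase in ("acquisition", "reversal"):
                for s in (1, 2):
                    rows.append({"rat_id": rat, "group": group, "phase": phase,
                                 "session_index": s,
                                 "metric": "max_time_avoided_s",
                                 "value": rng.normal()})
        cohort = pd.DataFrame(rows)
        with pytest.raises(ValueError, match="cannot remove"):
            cs.matched_exclusion(["c1", "c2", "c3"], cohort)

    def test_unknown_flagged_rat_rejected(self, rng):
        cohort = simulate_metric_cohort(rng=rng, metric="max_time_avoided_s")
        with pytest.raises(ValueError, match="not in cohort"):
            cs.matched_exclusion(["nope"], cohort)
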