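# Methods

## The task and its geometry

In active allothetic place avoidance a rat forages on a smooth circular
arena (diameter 82 cm) that rotates at ω while a 60°-wide punished sector
stays fixed in the room frame.  The two frames are related by
θ_arena = θ_room − ω·t (mod 360°); ω is signed, positive counter-clockwise.
ω is not part of the published protocol text, but the immobile-subject
ceiling it forces pins it: a fully immobile subject is carried through the
room frame once per rotation and its longest interval outside a 60° sector
is (360° − 60°)/ω; a 50-s ceiling therefore implies ω = 6°/s (1 rpm), which
is the package default (`omega_deg_per_s`, configurable).

The rotation direction is not documented either; the sign of ω is
configurable and the metrics are invariant under a direction flip combined
with the corresponding mirror of trajectory and sector (tested as the exact
symmetry it is).

Sector membership is half-open — inside iff the circular offset from
`center − width/2` lies in `[0, width)` — so entrance events are
unambiguous at the boundaries.  An initial placement inside the sector
counts as an entrance at t = 0 (the arena hardware shocks on placement;
the protocol text is silent).

## Trajectory measures

Occupancy quantities are accumulated **sample-and-hold** over native sample
intervals: a sample's state persists until the next sample, the last until
session end.  Only *total distance* uses the 1-s resample (the nearest
sample at or before each whole-second tick), matching the stated definition
of that measure; resampling the others would discard occupancy detail for
no benefit.  Maximum time avoided is computed by run-length logic over
outside-sector samples and is required (and tested, 1000 random sessions)
to agree exactly with a literal per-sample scan.

Post-shock speed is measured in the **arena frame**: the median of
|dθ_arena/dt| over samples in the 1 s after each shock onset, averaged over
shocks.  The arena frame is the only frame in which freezing reads as
≈ 0°/s — in the room frame every subject moves at least at ω = 6°/s — which
is what makes the < 2°/s freezing bound and the > 8°/s active-response
bound meaningful.  Angles are unwrapped before two-point forward
differencing to avoid ±360° spikes.  The frame choice is exposed via the
angular-state API for users who want the room-frame rate.

Shock reconstruction follows the hardware cycle: 0.5-s shock at entrance,
repeated 2.0 s after the previous shock while the animal remains inside,
cycle reset on exit.  Shock flags present in a track file (a hardware log)
take precedence over reconstruction.

Undefined values — post-shock speed with no shocks, opposite-sector
proportion when the animal never leaves the punished sector — propagate as
NaN, not zeros, and flow into the cohort table as ordinary missingness.

## Cohort pipeline

Small cohorts (9 + 9), five daily sessions per phase, ~0.6% missing values
from tracking dropouts.  The pipeline: (1) z-score each metric within each
phase × session across all rats, both groups pooled (the protocol does not
state the pooling; pooling is the only choice that leaves the group
contrast in the scores); (2) average the z-values per rat × phase over
available sessions — the prior standardization prevents the average from
depending on *which* sessions are missing; (3) z-score the averages across
rats within phase.  With no exclusions each phase column then has mean 0
and sample SD 1 exactly, so the phase main effect is degenerate by
construction and the within factor is carried only for the group × phase
interaction.  Sample SD (ddof = 1) everywhere.

Missing values are never imputed for analysis.  For plotting, a missing
session takes the nearest valid value in the same phase; when both
immediate neighbors are valid, their average; an equidistant tie at larger
distance takes the earlier session (the rule must be total and
deterministic; the earlier-session preference is the package's choice).

**Non-solver exclusion.**  A freezing animal cannot express avoidance
regardless of cognition.  The published criterion was visual observation
supported by numbers; the package operationalizes it as a dual rule — both
configurable — flagging a rat when its combined-phase standardized total
distance falls below z_cut = −1.0 **and** its mean post-shock speed is
below 2°/s.  The speed criterion is the discriminating one (freezers sit
near 0°/s, active rats above 8°/s); the z-cut is a guard so a merely slow
but responsive animal is never excluded.  Matched exclusion then removes
the same number of rats — those with the lowest mean combined-phase
standardized maximum time avoided — from the other group, keeping the
design balanced; ties break by rat id and are logged.

**Mixed ANOVA.**  One between factor (group) × one 2-level within factor
(phase), computed directly from the sums-of-squares decomposition — exact
here, since a 2-level within factor needs no sphericity correction.
Generalized eta squared uses the additive-error form
ηG² = SS_effect / (SS_effect + SS_subjects-within-groups + SS_residual),
appropriate when no factor is an observed individual-difference variable.
The implementation is verified against a naive loop-based oracle on all
small designs and against pingouin's `mixed_anova` (ng2) to 1e-9.

Welch's t (scipy, Welch–Satterthwaite df) serves the habituation-phase and
single-phase comparisons, with r = sign(t)·√(t²/(t²+df)).  Step-through
latencies (3 ordered trials, 300-s cap) are analyzed with orthonormal
polynomial contrasts (linear (−1,0,1)/√2, quadratic (1,−2,1)/√6) tested
against the within-subject error pooled over both contrasts
(df = (k−1)(n−g), e.g. 32 for 18 rats in 2 groups); per-group follow-ups
pool within the group (df = 2(n_g−1)).  The saccharin preference ratio
saccharin/(saccharin+water) reuses the mixed-ANOVA machinery with session
as the within factor.  No multiple-testing correction is applied across
metrics — a deliberate mirroring of the study design, and a known
limitation for confirmatory use.

## Circadian analysis

Per-minute counts, 29 LD days then 16 DD days.  A recording is split by
whole days into its entrained and free-running segments; the free-running
period τ is estimated only from DD.  The chi-square (Sokolove–Bushell)
periodogram folds the series at each candidate period P (integer bin
multiples over 20–28 h, i.e. 1-min resolution at 1-min bins) and computes
Q_P = Σ_h K_h (M_h − M)² / s²; under an iid null Q_P ~ χ²(P−1), giving the
per-candidate significance line at α = 0.001.  τ̂ is the significant
candidate with maximal Q.  With ~480 candidates, isolated line-crossers on
pure noise occur at the nominal per-candidate rate (≈ 0.5 expected per
periodogram); a genuine rhythm exceeds its line by orders of magnitude, so
the argmax rule is not noise-limited in practice.

The activity/rest ratio under LD is dark-phase counts over light-phase
counts from the schedule (invariant to relabeling absolute clock time).
Under DD the published analysis tool's day/night delimitation is not
documented; the package defines subjective night as [onset, onset + τ/2),
advancing by τ per cycle — a symmetric split anchored at activity onset,
which is the standard convention.  Onset per cycle is the first bin where
the smoothed counts (centered moving average, 29-min window — odd-width at
1-min bins, configurable) rise above the cycle mean and stay above for
≥ 30 min.  Group comparisons use Student's equal-variance t for activity
measures and the exact Mann–Whitney U for τ (small samples, coarse values),
the latter verified against exhaustive enumeration of all rank assignments
at n = (5, 8).

## Synthetic data

The generator defines the conditions all statistical tests run under.

**Sessions** are discrete-time correlated random walks in the arena frame,
expressed in room coordinates: gamma-distributed step speeds (mean
4–5.5 cm/s by group, shape 2), wrapped-normal heading noise
(1.2 rad/√s), a clamped proportional steering term toward a preferred
radius (thigmotaxis_bias × wall radius), wall reflection, and an
avoidance steering term that turns the animal tangentially toward the far
side of the arena, with a reaction zone and gain that grow with
`avoidance_skill` — a skilled rat counters the rotation continuously, an
unskilled one reacts late and weakly.  Shocks are generated online by the
hardware cycle; non-freezing animals respond with a 1-s tangential escape
at 20°/s arena-frame speed.  The freezing phenotype suspends walking
(immediately in the preset used for closed-form checks, after settling at a
small preferred radius in cohort simulations, emulating the low measured
distance of real non-solvers; frozen animals do not escape).  Learning
across the five daily sessions is a per-session schedule of
avoidance_skill (0.2 → 0.45), not in-simulation learning dynamics — the
analysis needs session-level contrasts, not a learning theory.  Per-rat
phenotype jitter (SD 0.04 on bias, 0.5 cm/s on speed, 12% on skill) gives
realistic within-group variance.  Cohort simulations use dt = 0.5 s
(metrics require ≥ 1 Hz; halving dt changes no conclusion); closed-form
checks use binary-fraction steps (0.125 s) dividing the 60-s rotation
period so that sample-and-hold occupancy of the passively rotated subject
is exact.

**Cohorts** follow the study layout — two groups of 9, phases
habituation/acquisition/retrieval/reversal with 5/5/1/5 sessions (the
retrieval session is 5 min and shock-free; reversal moves the sector
180°) — with Poisson defecation counts (rates 3.0 vs 1.5), clipped-normal
two-bottle masses, patterned step-through latencies (decreasing for
controls, increasing for knockdowns, capped at 300 s), planted freezers,
and 0.6% missingness.  Every planted parameter lands in a manifest so
recovery tests can check against ground truth.  A lightweight metric-level
generator (iid standard-normal session values with optional per-phase group
shifts) backs the null-calibration and power studies, where trajectories
would add nothing but runtime.

**Activity series** draw Poisson counts around a square (default) or
sinusoidal waveform — mesor 6, amplitude 5 counts/min, i.e. planted
night/day levels 11 and 1 — entrained at 24 h under LD with multiplicative
light masking (coefficient 0.8), free-running at τ under DD.

What the generator does *not* emulate: tracker noise and dropout bursts,
within-session fatigue, inter-individual correlation structure beyond the
planted phenotype means, ultradian activity bouts, and τ drift over DD
days.  Passing tests therefore demonstrate the correctness and calibration
of the pipeline under the stated generative assumptions, not robustness to
every artifact of real recordings.

## Numerical choices and problem sizes

- Radius validation tolerance 0.5 cm (tracker jitter at the wall); harder
  overshoots are rejected with the row named.
- The exact centre has undefined angle; it is reported as 0° with a
  degenerate-point flag rather than an error.
- Zero-variance standardization cells raise, naming the session; zero-total
  preference sessions and never-left-sector proportions yield NaN markers.
- Monte-Carlo sizes: 2000 replicates for the null-calibration check (the
  rate must fall in the 95% binomial CI of α = 0.05), 100 seeded replicates
  across τ ∈ {23.8, 24.0, 24.2, 24.5} h for periodogram recovery (16-day DD,
  ≥ 95% within one 1-min step), 1000 random sessions for the
  interval-vs-scan equivalence, exhaustive enumeration (C(13,5) = 1287
  assignments) for the Mann–Whitney check.

## Known limitations

- The dual non-solver criterion is a documented operationalization of what
  was originally a visual judgment; the thresholds are config keys, and
  borderline phenotypes (slow but responsive) are deliberately not flagged.
- Generalized eta squared assumes no observed (non-manipulated) factors; if
  litter or sex were modeled, the denominator would change.
- The DD activity/rest ratio depends on the onset estimate; arrhythmic
  records return an undefined marker rather than a ratio.
- The periodogram's candidate grid is bin-width-limited (1 min ≈ 0.017 h);
  sub-bin period differences are not resolvable by construction.
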