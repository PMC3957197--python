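# rotarena

Analysis pipeline for rotating-arena active place avoidance (the "Carousel
maze" / AAPA task) and circadian locomotor actigraphy, with a synthetic-data
generator that emulates both recording types.

## Who this is for

Behavioral neuroscientists running the AAPA task — a circular arena
(82 cm diameter) rotating at ω = 6°/s with an unmarked 60° sector fixed in
the **room frame**; entering the sector triggers a 0.5-s foot shock,
repeated every 2.0 s until the animal leaves.  Solving the task requires
dissociating room-frame from arena-frame cues: a rat that simply sits still
is passively carried into the sector once per rotation.  The same labs
typically also record per-minute locomotor activity counts under a
light/dark cycle (LD12:12) followed by constant darkness (DD) to assess the
circadian clock.

## What it computes

**Reference frames.**  With signed rotation speed ω (positive =
counter-clockwise), θ_arena = θ_room − ω·t (mod 360°).  All sector logic is
room-frame; immobility is read in the arena frame.

**Per-session trajectory measures** (`avoidance_metrics`):

- *total distance* — path length over points resampled every 1 s (m);
- *maximum time avoided* — longest continuous interval without a sector
  entrance (s).  Geometry forces two reference values: an immobile subject
  scores (360° − 60°)/6°s⁻¹ = **50 s**, and a never-entering subject scores
  the **1200 s** session cap;
- *mean distance from center* — time-weighted mean radius (cm), the
  thigmotaxis index, necessarily **< 41 cm**;
- *proportion of time in the opposite sector* — occupancy of the sector
  180° away, divided by all time **not** spent in the punished sector
  (0.2 for an immobile subject);
- *median absolute post-shock speed* — per shock, the median |arena-frame
  angular speed| over the following 1 s, averaged over shocks (deg/s).
  Freezing reads < 2°/s, an active escape > 8°/s;
- entrance counts, occupancy times, shock reconstruction per the
  0.5 s + 1.5 s hardware cycle.

**Cohort statistics** (`cohort_statistics`): per-session z-scoring across
rats → per-phase averaging → re-standardization (so each phase column has
mean 0, SD 1 absent exclusions); freezing "non-solver" exclusion by the
dual criterion (combined-phase total-distance z < −1 **and** post-shock
speed < 2°/s) with matched removal of equally many worst avoiders from the
other group; mixed ANOVA (group × phase) with generalized eta squared;
Welch's t with the r = √(t²/(t²+df)) effect size; orthonormal polynomial
trial contrasts for step-through avoidance; saccharin preference ratio
saccharin/(saccharin+water); metric correlation matrices.  Missing values
are never imputed for analysis; a nearest-valid-session rule produces a
plot-only table.

**Circadian actigraphy** (`circadian`): double-plotted actograms, LD
activity profiles, the Sokolove–Bushell chi-square periodogram
(Q_P = Σ_h K_h (M_h − M)²/s², Q_P ~ χ²(P−1) under the null; search 20–28 h,
α = 0.001) with the free-running period τ̂ taken at the maximal significant
Q, activity-onset estimation, total 24-h activity and the (subjective)
night/day activity ratio, and group comparisons (Student's t; exact
Mann–Whitney U for τ).

**Synthetic data** (`synthetic`): correlated-random-walk sessions with
thigmotaxis, sector-avoidance and freezing phenotypes plus online shock
generation; full 9 vs 9 study layouts (habituation/acquisition/retrieval/
reversal) with annotations and ~0.6% missingness; circadian count series
with configurable τ, waveform, light masking and Poisson noise.

## Worked example

```bash
rotarena run --seed 1 --out demo/
```

simulates a full cohort (three freezing non-solvers planted in the control
group) and a 29-day LD + 16-day DD activity series, then runs both
analysis branches.  Output (abridged):

```
flagged non-solvers : ['co01', 'co02', 'co03']
matched removals    : ['kn05', 'kn02', 'kn07']
analysis set (n=12): ['co04', ..., 'kn09']

             metric   subset      effect        F  df1  df2         p       ges
mean_dist_center_cm      all       group 0.006609    1   16    0.9362 0.0004125
mean_dist_center_cm excluded       group    42.41    1   10 6.791e-05    0.8092
 max_time_avoided_s excluded       group    9.876    1   10   0.01046    0.4865
estimated free-running period: 24.2 h
```

Reading it: the three planted freezers are flagged by the dual criterion
and three matched worst-avoiding knockdowns are removed, leaving 6 vs 6.
The planted thigmotaxis difference is invisible with all subjects included
(the small-radius freezers cancel it; F(1,16) ≈ 0.01) but strong on the
analysis set (F(1,10) = 42.4, ηG² = 0.81); the avoidance deficit appears as
a group effect on maximum time avoided; the periodogram recovers the
planted 24.2-h free-running period exactly (one 1-min bin resolution).

The same steps are available in Python:

```python
from rotarena import synthetic, cohort_statistics as cs

sim = synthetic.simulate_cohort(seed=1, n_freezers={"control": 3})
results = cs.PlaceAvoidanceAnalysis(sim.cohort).fit()
print(results.summary())
```

## File formats

Plain CSV dialects with `#`-prefixed `key=value` headers, documented in
`rotarena.io_formats`: per-session tracks (`t_s,x_cm,y_cm,shock_flag`,
room-frame cm, origin at arena center), per-minute activity counts with a
light/dark schedule annotation, and one-row-per-rat-session annotation
tables.  All readers validate (radius bound, monotone time, schedule
tiling) and name the offending row on failure.
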