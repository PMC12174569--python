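# Methods

This note documents the models, conventions and design decisions behind
`moztrack`: what each stage computes, why the defaults are what they are, and
what the bundled simulator does and does not capture about real flight data.

## Flight simulator (`synthio`)

### Movement model

Flight is a discrete-time correlated random walk at the camera frame rate
(50 fps). Per frame:

* **Speed** follows an AR(1) process around `mean_speed` with marginal
  standard deviation `speed_sd` and lag-1 autocorrelation
  `speed_persistence` (default 0.98), clipped at zero. Real flight speed
  varies smoothly over tenths of a second rather than frame to frame; the
  AR(1) process is the simplest way to get that.
* **Heading** accumulates a von Mises increment with concentration
  `turn_concentration` (higher = straighter flight). On top of the smooth
  meander:
  * a **tremor** term adds `turn_floor`·|N(0,1)| radians to each increment's
    magnitude. The tremor is intermittent — calm spells free of tremor cover
    ~12% of flight in stretches of ~40 frames. A small floor (0.05 rad)
    represents ordinary wingbeat-level jitter; an amplified floor models the
    insecticide-induced inability to hold a straight course. Because the
    tremor is additive in magnitude it lifts the *lower* quantiles of the
    per-frame angle change far more, in relative terms, than the upper ones.
  * **saccades**: casting bouts (stationary fraction `saccade_prob`, mean
    bout 20 frames) during which the heading is redrawn uniformly each frame,
    identical in both regimes.
  * **horizontal reversals**: at Poisson events with rate `reversal_rate`
    the heading is mirrored about the vertical axis (θ → π − θ), flipping the
    sign of the horizontal velocity component. A mirror rather than a π
    rotation is used because the behaviour being modelled is a direction
    reversal *across the camera*: a full π flip would reverse the vertical
    component too and make horizontal and vertical reversal counts
    indistinguishable. The interleaved rotate/mirror sequence is evaluated in
    closed form by composing the affine maps h ↦ σh + φ.
* **Pauses** (hovering or resting on the net) are generated by a two-state
  Markov chain with stationary pause fraction `pause_prob` and mean pause run
  `pause_mean_frames` (6). During a pause the displacement is exactly zero;
  runs of pauses therefore produce runs of *exact-zero* heading changes,
  which is what the zero-crossing count of the angle-change series detects.
* Positions are reflected at the arena boundary (1200 × 1000 mm field of
  view); finite track durations emulate tracks leaving the camera view.

### Individual variability

Each mosquito draws its own parameters: multiplicative log-normal jitter with
log-sd `variability` (0.45) on the behavioural rates (heading concentration,
tremor scale, reversal rate, pause and saccade odds) and a tighter log-sd
`speed_variability` (0.08) on mean speed. This produces overlapping
behavioural distributions between conditions — classification is then
genuinely statistical rather than a table lookup — and is the main source of
the held-out error the benchmark reports.

### Study structure

A trial releases 25 mosquitoes for 2 h; each yields one or more tracks with
uniform start times and log-normal durations (median ~15 s, mean ~22 s,
minimum 1 s, heavy right tail). Observed positions are dropped in runs (the
gap law's run-start probability is solved from a renewal equation so the
marginal dropout fraction equals the nominal rate). Strains cycle through
Kisumu, N'Gousso (susceptible) and VK7, Banfora (resistant). Susceptible
mosquitoes at the treated net receive a 30-minute mortality cutoff: no track
starts after it, and tracks crossing it are truncated; starts drawn past the
cutoff are discarded rather than resampled, so treated-net susceptible trials
also have realistically *fewer* tracks.

### Default behavioural contrast

The untreated regime is directed flight (concentration 8, baseline tremor
0.05 rad, 0.1 reversals/s, 6% pause fraction); the treated regime is
convoluted, irritated flight (concentration 5, tremor 0.20 rad, 7
reversals/s, 0.6% pauses). The flight-speed process is identical in both
regimes; the observed mean speed is still higher at the treated net because
untreated mosquitoes pause. These defaults place the class contrast on three
behavioural axes — minimum turn magnitude, hovering, horizontal reversals —
whose natural readouts are the first quartile of angle change, the zero count
of angle change, and the zero-crossing count of horizontal velocity, the
three features the analysis is expected to surface. The nuisance components
(AR(1) speed, saccade bouts, calm spells, individual jitter) exist so that
redundant statistics of the same series (curvature and acceleration
quantiles, minima, vertical-velocity crossings, speed spread) are either
collapsed by the correlation de-duplication or carry visibly weaker signal.

### What the simulator does not capture

No 3D flight, host-odour plumes, net-contact micro-behaviour, visual cues, or
diel activity rhythms; arena reflection is a crude stand-in for leaving the
field of view; behavioural parameters are stationary within a track apart
from tremor/saccade/pause episodes. Passing benchmarks on this simulator
therefore demonstrates that the *pipeline* recovers planted structure of the
kind reported for real data — not that real mosquitoes behave like the
simulator.

## Segmentation and quality filtering

Windows are full-length only (7.5 s, 375 samples, stride 25); tracks shorter
than the window contribute no segments, which is the price of unifying
segment durations. Interpolation is linear against frame index (the camera
clock) and inserted samples are flagged so that no statistic ever uses them.
The quality score Σ rᵢ²/L penalises consecutive interpolation quadratically:
one 10-frame gap in a 100-frame window scores 1.0 while two 5-frame gaps
score 0.5. The removal threshold is chosen by computing, per feature, the
plug-in mutual information between the equal-frequency-binned (10 bins)
feature and the class label among segments at or below each candidate quality
level (deciles of observed non-zero quality plus 0); each feature votes for
its MI-maximising level (ties toward keeping more data) and the final
threshold is the MI-weighted mean of the votes. All thresholds in the package
are inclusive (≤ keeps).

## Features

First differences give velocity (mm/s), speed, acceleration magnitude
(mm/s²), absolute wrapped heading change (radians in [0, π]) and curvature
(angle change over step length, rad/mm). Validity masks require every
contributing position to be observed; zero-crossing adjacency never spans a
masked sample. Quantiles interpolate order statistics linearly; the sd uses
n − 1. Path length is the polyline length through consecutive *observed*
positions and net displacement the first-to-last observed distance, which
makes straightness = net/path ≤ 1 a theorem (triangle inequality) instead of
an approximation. Exact zeros (no epsilon band) define zero values, matching
the simulator's exact-zero pauses; real tracking data quantised to camera
pixels also produces exact zeros, but an epsilon variant would be a one-line
change.

## Selection

The Mann–Whitney U statistic uses midranks; p-values are exact (tie-aware
enumeration of rank splits) when both groups have ≤ 8 observations and the
split count is tractable, and otherwise use the normal approximation with
tie-corrected variance and continuity correction. Log-scale p-values are
carried alongside, because with thousands of segments the double-precision
p-value underflows to 0 for many features and could no longer order them for
the de-duplication tie-break. Bonferroni keeps features with p ≤ α/m
(α = 0.05). De-duplication visits pairs with Spearman |ρ| > 0.85 in
decreasing |ρ| order and drops from each still-intact pair the member with
the weaker marginal signal (larger p; exact ties break lexicographically);
constant features get ρ = 0 with a warning. Selection is fitted on tuning
trials only and frozen before any modelling fold is formed.

## Model

XGBoost binary classifier (positive class = treated net), default depth 4,
200 trees, learning rate 0.1, subsample 0.8, single-threaded `hist` for
determinism. `scale_pos_weight` is the UT/OL segment count ratio of the
training set. Features are Z-scored with training-set statistics; a constant
training feature is emitted as all-zero with a warning. The decision boundary
is swept over {0.01, …, 0.99} maximising training MCC (zero denominators
define MCC as 0; ties take the smallest boundary, i.e. the most sensitive
operating point among equals). Track calls are the mode of segment calls; an
exact tie goes to the treated class iff the mean segment probability reaches
the boundary — the tie uses the available evidence rather than a fixed class.
The balanced training strategy samples at *track* level (segments follow
their track) without replacement; the 30-minute boundary is inclusive.

## Evaluation

Folds split at trial level; the tuning/modelling and train/test partitions
are asserted disjoint on every run and a violation raises. Test-set
composition supports the full-study design (1 UT + 2 OL trials per strain,
surplus UT slots shed at random down to the requested test size) and a
class-level mode for small studies (n UT + n OL, split as evenly as possible
between resistance statuses so the balanced strategy always has susceptible
treated-net tracks to anchor on). Balanced test sets are enumerated when the
combinatorics allow (≤ 2·10⁵) and rejection-sampled otherwise; folds are
drawn without replacement and capped with a warning when fewer distinct sets
exist. The metric panel is computed on whole tracks, with
precision/recall/F1/PR-AUC reported for both choices of positive class; PR
AUC is average precision. Time-resolved accuracy uses half-open 5-minute bins
on track start times, the unweighted mean and sd across folds, and reports
empty bins as missing, never zero — with censored susceptible mosquitoes the
late treated-net bins are structurally empty, and conflating that with zero
accuracy would invert the interpretation. Feature attributions are computed
on every fold's test segments; the headline ranking aggregates all folds
(mean |SHAP| over all test rows), and the best fold's own ranking is kept
alongside, since single-fold rankings are noticeably noisier.

The windowing/model grid search runs entirely within the tuning trials,
maximising mean track-level balanced accuracy over an internal trial-level
cross-validation; ties prefer the smaller window and then the larger overlap
(more segments). Within a grid point, feature selection uses the whole tuning
set; the quantity being optimised is still estimated on trials unseen by that
point's model fits, and no modelling trial is touched.

## Explanation

Attributions are exact path-dependent TreeSHAP values produced by the
boosting library itself (`pred_contribs`), in margin (log-odds) space where
additivity is exact; the background distribution is the per-node training
cover recorded in the trees. Additivity (base + Σ attributions = margin) is
asserted on every scored row with an absolute tolerance of 10⁻⁵, reflecting
the library's single-precision output. The direction summary per feature is
the sign of the correlation between raw feature values and attributions —
+1 means high values push toward the treated-net class.

## Benchmark sizes and numerical conventions

The bundled benchmark uses 8 modelling trials per arm and a disjoint tuning
arm of 4 + 4 trials, 25 single-track mosquitoes per trial, 30 folds, and the
class-level fold composition (2 UT + 2 OL test trials, 12 training trials).
These sizes keep a complete pipeline run (≈ 16 000 segments, 30 model fits)
under a minute on one core while leaving every stage statistically
non-trivial. All randomness descends from a single master seed through
per-trial, per-track and per-fold child seeds; identical configuration and
seed reproduce byte-identical simulations and reports. Null calibrations
(permuted trial labels; identical behavioural regimes in both arms) run the
same pipeline unchanged and sit within 0.5 ± 0.05 balanced accuracy.

## Known limitations

* The quality-threshold procedure's plug-in MI estimator is upward-biased at
  small sample sizes, which biases per-feature votes toward stricter
  thresholds; the weighted averaging dampens but does not remove this.
* The exact Mann–Whitney path is capped at ~2·10⁶ enumerated splits; a 5 vs
  10 000 comparison silently uses the asymptotic path.
* Track-level aggregation by majority vote discards segment confidence except
  at exact ties; the mean segment probability is reported as the track score
  for ROC/PR curves.
* With fewer than two trials per (net, strain) cell the per-strain fold
  composition is unsatisfiable; the class-level composition is the supported
  fallback.
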