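# Methods

`npap` quantifies stereotyped ("preconfigured") activity patterns in
simultaneously recorded spike trains of the motor thalamus driven by
cortical stimulation and by forelimb movements.  This note documents the
models and procedures the package implements, the parameters that
matter, and the choices made where the procedure was genuinely open.

## Data model and conventions

A *session* holds spike trains (seconds on one clock), labeled events
(stimulus pulses grouped into 5-pulse trains at a 300 or 500 ms
inter-stimulus interval, rewards, movement onsets) and an optional lever
displacement trace at 250 Hz.  Throughout: 0-based bin indices,
half-open bins `[left, right)`, signed peri-event windows (e.g.
`(-1.0, 4.0)` s), and a default 1 s pre-event baseline.  Analyses
binarize spikes on a 1 ms grid; pattern-level analyses use 10 ms bins.

## Peri-event quantification

**Firing rate** is the reciprocal of the mean inter-spike interval over
the whole recording.  **Stability filtering** drops a unit when the
fraction of event-anchored windows (5 s for stimulation, 8 s for
behavior) with rate < 0.1 Hz strictly exceeds 40%; a unit silent in
exactly 40% of windows is kept.  The filter is monotone: adding spikes
can only lower the silent fraction.

**Z-scoring** standardizes the trial-averaged peri-event trace by the
mean and SD of its baseline bins; a zero baseline SD flags the unit and
excludes it downstream rather than propagating infinities.

**Latency detection** derives an upper and a lower limit from the 99th
and 1st nearest-rank percentiles of the 1000 trial-averaged 1 ms
baseline bins.  An *increase* begins at the first post-event bin
strictly above the upper limit (a `consecutive` parameter, default 1,
can require adjacent supra-limit bins; 2 is useful when scanning long
windows, since with ~300 search bins a single-bin rule crosses somewhere
in most units by chance alone).  Decreases cannot use the mirror rule:
1 ms counts are bounded below by zero and the 1st-percentile limit is
almost always exactly 0, so "strictly below" can never fire.  The
package instead detects a *calibrated silent run*: the shortest run
length m such that the expected number of runs of m consecutive
sub-limit bins in the search window, under the empirical baseline bin
distribution, is at most the percentile level alpha.  No smoothing is
applied on either side.  Consequences worth knowing: the run criterion
needs the suppression to outlast m bins (m grows as the baseline rate
falls; near 1 Hz a 100 ms suppression is undetectable and the detector
honestly reports absence), and with discrete counts the upper limit is
conservative - its attainable per-bin level (reported by
`latency_null_calibration` as `achieved_alpha`) sits below the nominal
1%, and the post-event false-crossing rate matches that attainable
level, as standard for discrete tests.

**Component amplitudes** summarize each of the five stimuli of a train:
short-latency amplitude = max z in (0, 30] ms after the pulse,
decremental = min z in (30, 100] ms, long-latency = mean z in
(100, 290] ms.  Only the 100-290 ms rebound window is fixed by the
recorded timing; the first two bracket the ~10 ms excitation and the
pre-rebound pause and are configurable.

## Surrogate null models

Circular surrogates re-order each spike independently: a magnitude
uniform on [low, high] (1-5 s for event windows; up to a quarter of the
recording for spontaneous activity) with random sign, wrapped at the
window edges.  Spike counts are preserved exactly; event locking is
destroyed.  Null distributions use one named random stream per
(repeat, unit) so results are reproducible under parallel or reordered
evaluation.  Percentiles are nearest-rank.  One discreteness subtlety:
the 99.5th nearest-rank percentile of n <= 199 repeats is the sample
maximum, and an exchangeable observed value exceeds the maximum of 199
with probability exactly 1/200 = 0.5%; with 200 repeats the rule picks
the 199th order statistic and the exceedance doubles.  Calibration runs
therefore use 199 repeats; ordinary analyses default to the protocol's
100 (where the rule flags ~1% of null pairs).

## Pattern classification

Evoked features are the z-scored train-aligned traces (1.5 s / 2.5 s
for the 300 / 500 ms ISI at 10 ms bins; a cross-ISI mode keeps only the
first 300 ms after each pulse so both conditions share one grid).  Each
unit's trace is row-standardized - classification is by response
*shape*, not amplitude - and projected onto the first three principal
components.  For every k in 2..10, k-means (k-means++ seeding) runs
`n_runs` times and each partition is scored by the mean silhouette in
the 3-PC space; the single best (k, partition) wins, ties toward
smaller k.  1000 restarts is the reference setting; 100 gives the same
selections on the synthetic cohorts and is used in the test suite.
Cluster naming is stable across runs: cluster 1 = smallest mean squared
template z (the non-responsive pattern), remaining clusters ordered by
template short-latency amplitude, descending.  On isotropic noise the
silhouette plateaus near 0.3 for every k (k-means always finds some
partition in 3 dimensions); structured cohorts score > 0.6 with a clear
peak, so the silhouette-by-k profile, not the absolute value alone,
carries the evidence.

The GLM validation regresses each unit's 10 ms-binned rate (trials
concatenated) on six standardized predictors - the five cluster
templates plus one random trajectory (white noise smoothed to template
bandwidth, sigma = 2 bins) - with a Gaussian identity link, and assigns
the unit to the predictor with the largest coefficient.  A Gaussian
family is used because coefficients are compared across predictors,
which requires one common scale.

Prevalence tables restrict percentage statistics to sessions with at
least 8 simultaneously recorded units; animal-presence counts use all
sessions.  Cross-cohort cluster correspondence is greedy
max-correlation matching of templates; the non-responsive template is
near-zero noise, so only responsive clusters have a correlation worth
interpreting.

## Population geometry

The population response is a neurons x 30 matrix: per unit, activity
after each pulse averaged over the five pulses and all trains, z-scored
against the pre-train baseline at the same bin width.  *Relative* mode
scales the bin width with the ISI (10 / 16.6 ms), *absolute* mode fixes
10 ms bins over the first 300 ms.  Conditions are compared through the
30 x 30 Euclidean distance matrix between population columns; rows are
summarized by the minimum-distance vector and the diagonal asymmetry
vector (offset of each row's minimum from the diagonal; ties resolve to
the smallest offset, then the lower column), transformed to degrees at
12 degrees per bin (30 bins = 360 degrees).  Both the mean over all 900
entries and the mean of the minimum-distance vector are reported - the
former is dominated by the overall response energy, the latter by
alignment, so the relative-vs-absolute contrast shows most clearly in
the asymmetry and the minimum-distance statistics.  Distances scale
with sqrt(n_units); a seeded subsampling utility equalizes counts
across cohorts.

## Behavior

Trials are segmented from the displacement trace at a 0.1 mm threshold:
the onset is the start of the contiguous supra-threshold run containing
the reward, the release is the first sustained (100 ms) return below
threshold after it.  Overshoot = release - reward; effort = cumulative
supra-threshold time from the trial's start (the previous release) to
the reward, so failed attempts add their duration; speed = mean
|displacement derivative| during the movement; intralimb correlation =
mean pairwise Pearson r between reward-aligned trajectories over
[-1.0, +0.5] s (window configurable; its variance indexes movement
stability).  Time normalization maps reward-aligned 1 ms activity onto
a 2300-bin grid: 1000 pre-movement bins, the 200 ms pre-reward segment
of short trials linearly interpolated to 500 bins (endpoints preserved,
constants mapped to constants; long trials pass through unresampled),
and 800 post-reward bins.

## Correlation analyses

Evoked pair correlations are Pearson r between z-scored train-aligned
traces at 10 ms; pairs are classified high/low against the 99.5th
percentile of their circular-surrogate null.  Spontaneous correlations
use 100 ms bins smoothed with a 200 ms-SD Gaussian kernel inside
caller-supplied task-free segments (smoothing SD 0 reduces to raw
binned correlation; under 60 s of segments raises a warning).  Signed
amplitudes take the z extremum (carrying its sign) in a +/-200 ms
window around the alignment event.

The movement-window cross-correlogram pools spike-time differences
t_b - t_a over +/-2 s around movement onsets at 10 ms bins.  A
shift-predictor correlogram (A around movement m against B around
movement m+1) is subtracted, removing chance coincidences and
movement-locked common modulation; the lag is the center of mass of the
bins that rise significantly above zero (robust-SD threshold,
Bonferroni across the 400 bins).  Without that mask, chance-level bins
at +/-2 s lags dominate the center of mass through leverage; without
the shift predictor, the estimate confounds common event locking with
genuine co-firing.  Conditionally independent Poisson units have *no*
excess synchrony for this estimator to find - by design it measures
coordination beyond individual event locking.

## Synthetic sessions

The generator reproduces the recorded protocol: 50 five-pulse trains
per ISI delivered every 5 s; baseline rates log-normal with median 3 Hz
and sigma = ln(5.5/1.3)/(2 x 0.6745) ~ 1.07 fitted to the reported
1.3-5.5 Hz interquartile range (a two-parameter fit cannot match both
quartiles of an asymmetric distribution; the median is matched by
construction).  Each unit is an exact inhomogeneous Poisson process -
homogeneous baseline plus thinning where the template gain < 1 and
Poisson superposition where > 1 - with one of five planted archetypes:

1. flat (non-responsive; half the population by default),
2. transient excitation (gain 6, 10-25 ms) then deep inhibition
   (gain 0.05, 25-150 ms),
3. sharp large activation only (gain 12, 10-40 ms),
4. inactivation (gain 0.05, 10-100 ms) then rebound (gain 3, 100-290 ms),
5. triphasic: excitation, inhibition, rebound (gain 2.5).

Modulation depths are free parameters; these defaults encode the
qualitative distinctions among the recorded archetypes so that the five
shapes are mutually distinguishable - a planted "five patterns" whose
shapes collapse onto one another would contradict the phenomenon being
emulated.  The `snr` scalar scales all depths (`gain_eff = max(0,
1 + snr (g - 1))`); snr = 0 collapses every unit to homogeneous
firing.  A per-pulse gain knob plants facilitation/adaptation.

Behavioral sessions build trapezoidal lever trials in alternating
20-trial blocks of 200/500 ms with a ~200 ms overshoot and assign units
movement archetypes (ramp-to-onset, suppression, reward transient).
The latency-linked generator plants spike-level common drive: one
shared response spike process per stimulus/movement received by each
unit at its own latency (2 ms jitter), creating the precise excess
synchrony the lag analysis targets.

What the generator does *not* emulate: bursting and refractoriness,
slow non-stationarities (drift, state changes), electrode artifacts and
sorting errors, correlated baseline activity outside the planted
windows, and the real anatomical mixture of projection classes.
Passing tests therefore demonstrate that the analysis chain recovers
what it is designed to measure under Poisson statistics at realistic
rates and trial counts - not that it is robust to every failure mode of
real recordings.

## Problem sizes in the test and acceptance runs

Recovery cohorts use 200 units x 50 trains with 100 k-means restarts
per k (the reference 1000-restart setting selects identically on these
cohorts); null calibrations use 1000 homogeneous 3 Hz units and ~2400
independent pairs with 199 surrogate repeats; geometry and correlation
cohorts use 100 units under both ISIs; linkage runs use 2 x 14 units
with 60 movements.  These sizes give the Monte-Carlo bounds quoted in
the acceptance suite comfortable margins on a single CPU.

## Known limitations

- Decrease latencies are biased a few ms early (the silent run can
  begin with chance-empty bins preceding the true suppression) and are
  undetectable for low-rate units; both follow from 1 ms counts.
- The lag estimator requires genuine excess synchrony; it returns a
  noisy near-zero lag, not an error, for merely co-modulated pairs.
- Cluster naming beyond Type 1 relies on template short-latency
  amplitudes; archetypes with equal excitation depth can swap names
  across runs (cross-run comparisons should go through
  `match_clusters`).
- `averaged_sequence` z-scores from a 1 s pre-train baseline at the
  sequence bin width (60-100 baseline bins); very low-rate units are
  excluded when that baseline has zero variance.
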