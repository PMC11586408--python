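# npap — peri-event analysis of preconfigured activity patterns

`npap` is a Python library for asking whether a recorded neural
population expresses *preconfigured* activity patterns: stereotyped,
experience-independent response motifs carried by fixed subgroups of
neurons.  It was built for cortico-thalamic data — motor-thalamic
(VL/VM) units driven by optogenetic stimulation of motor cortex (M1) in
5-pulse trains at 300 or 500 ms inter-stimulus intervals (ISI), and by
self-initiated lever movements — but every analysis operates on plain
spike times, event times and a displacement trace.

The package covers the full chain:

- **Peri-event quantification** — 1 ms binarization, PETHs, baseline
  z-scoring, ISI-based firing rates, a stability filter (drop a unit
  silent around >40% of events), percentile-limit response-latency
  detection, and per-stimulus component amplitudes (short-latency max z
  in 0–30 ms, decremental min z in 30–100 ms, long-latency mean z in
  100–290 ms).
- **Surrogate nulls** — per-spike circular re-ordering (±1–5 s around
  events; up to a quarter of the session for spontaneous activity),
  preserving spike counts while destroying event locking.
- **Pattern classification** — PCA of z-scored evoked traces, k-means
  over k = 2..10 with silhouette-based selection of the number of
  pattern clusters, per-session prevalence tables, greedy template
  matching across cohorts, and a GLM cross-check (best trajectory
  predictor among the five cluster templates plus a random trajectory).
- **Population geometry** — neurons × 30 averaged sequences per ISI in
  *relative* (bin = ISI/30) or *absolute* (10 ms) time, 30 × 30
  Euclidean distance matrices between population vectors, and the
  diagonal asymmetry index in degrees (30 bins = 360°).
- **Behavior** — lever-trial segmentation and the four movement
  parameters (intralimb correlation, overshoot, effort, speed), plus
  time normalization of reward-aligned activity to a 2300-bin grid.
- **Correlation analyses** — evoked and spontaneous pair correlations
  with 99.5th-percentile surrogate classification, signed amplitudes,
  and movement-window cross-correlogram lags against evoked-latency
  differences.
- **Synthetic sessions** — an inhomogeneous-Poisson generator that
  reproduces the recording protocol (50 trains every 5 s, log-normal
  baseline rates with median 3 Hz and IQR 1.3–5.5 Hz) and plants five
  archetypal evoked patterns, behavioral archetypes and common-drive
  pairs, with the ground truth stored in the session.

## Worked example

`examples/01_simulate_and_classify.py` generates a 200-unit session
under the 300 ms ISI protocol and recovers the planted patterns:

```
units classified : 200
chosen k         : 5
mean silhouette  : 0.704
silhouette by k  : {2: 0.483, 3: 0.549, 4: 0.675, 5: 0.704, 6: 0.668, ...}
non-responsive cluster share: 45.5% (planted 50%)
```

The silhouette curve peaks at the planted five archetypes, and the
cluster with the least response energy (cluster 1 by the package's
naming convention) captures the planted non-responsive units.
`examples/02_latency_and_amplitudes.py` quantifies one planted
triphasic unit:

```
unit u0057 (planted triphasic, 9.9 Hz baseline)
increase latency : 11.0 ms (planted onset 10 ms)
decrease latency : 55.0 ms (suppression from 25 ms)
stimulus 1: short +6.0  decremental -0.7  long +0.99  (z)
...
```

and `examples/03_population_geometry.py` shows the geometry contrast
that distinguishes absolute-time from ISI-scaled dynamics:

```
relative: bin 10.0/16.7 ms  mean asymmetry  67.2 deg  mean min-distance 9.15
absolute: bin 10.0/10.0 ms  mean asymmetry  43.6 deg  mean min-distance 7.07
self     : asymmetry 0.0 deg (30/30 offsets are zero)
```

Responses planted in absolute time misalign when bins stretch with the
ISI — higher asymmetry and minimum distance in relative mode — while a
condition compared with itself gives the degenerate thirty-zero
asymmetry vector.  `docs/methods.md` documents the models, parameter
choices and known limitations.

## Session file format

A session is a directory of columnar text files: `units.csv`
(`unit_id,t_start_s,t_stop_s`), `spikes.csv` (`unit_id,time_s`),
`events.csv` (`kind,time_s,label` with kinds `stim_pulse`,
`train_onset`, `reward`, `movement_onset`, `trial_start`), optional
`lever.csv` (`displacement_mm`, rate in the manifest), a
`manifest.yaml`, and `ground_truth.yaml` for synthetic sessions.  All
times are seconds on one session clock; the documented column order is
part of the public contract.  `npap validate <dir>` checks a directory
against the dialect and every structural invariant.
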