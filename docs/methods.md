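# Methods

This note documents the models and procedures `nfsim` implements, the
assumptions behind the synthetic data generator, and the numerical
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The experimental computation being modelled

A participant (or agent) completes three sessions. Each session starts
with a functional localizer — alternating 16 s blocks of mental drawing
(8), finger tapping (8) and rest (17), 528 volumes at TR = 1 s — and
continues with six neurofeedback runs of ten trials each (180 trials per
participant, 90 per target level). A trial is 16 s rest, 16 s motor
imagery, a prediction rating (0–12), a confidence rating (50–100% in
steps of 5), and 2 s of feedback; one trial in ten is a catch trial with
instructed ratings. The protocol's 1–3 s jitters around the rating
screens are fixed at their 2 s midpoint so volume counts are
deterministic (configurable in `TrialTiming`).

### Online scoring

* **Smoothing**: isotropic Gaussian, FWHM 4 mm converted to voxels via
  the voxel size (2 mm default).
* **Localizer GLM**: voxelwise OLS on HRF-convolved drawing and tapping
  boxcars plus a centred linear trend and intercept. The contrast is
  drawing − tapping with rest as the implicit baseline (a conjunction
  variant can be expressed through `contrast_tmap` weights). Voxels
  whose residual variance is at floating-point rounding level get a
  ±inf sentinel and are excluded from selection, which requires finite
  t inside the pre-mask.
* **Target region**: within an anatomical pre-mask (in the synthetic
  pipeline, a box with 2-voxel margin around the true blob, standing in
  for an expert's SMA pre-selection), grow a single 26-connected cluster
  greedily from the pre-mask t-maximum, always adding the neighbouring
  pre-mask voxel with highest t whose inclusion keeps the cluster within
  six contiguous slices (max z − min z + 1 ≤ 6), stopping at 30 voxels.
  The constraint set is fixed by the protocol; the *growth rule* is not,
  so the greedy best-neighbour rule is this package's definition —
  deterministic, constraint-respecting, and (verified by exhaustive
  enumeration on small grids in the test suite) near-optimal in summed
  t. Ties on t break toward the lowest (z, y, x) linearised index.
* **MaxPSC**: per drawing block, PSC of the region-mean signal using the
  same windows as trial scoring (baseline [−4, +2) s, active
  [+6, +16) s around block onset — the protocol does not pin down the
  localizer block windows, so mirroring the trial convention keeps the
  two stages on one scale); MaxPSC is the 75th percentile ("third upper
  quartile") of the block PSCs, with linear interpolation between order
  statistics.
* **Trial feedback**: PSC of the imagery window against the preceding
  baseline window, divided by MaxPSC, times 10, clipped to [0, 12].
  Catch trials are scored like any other (their feedback was displayed)
  and flagged for exclusion from behavioural analysis rows only. At
  non-integer TR the windows round inward (ceil start, exclusive end)
  and realized volume counts are logged.

## Synthetic data generator

The phantom plants what the analysis assumes and nothing more:

* signal = baseline (100 a.u.) + linear drift (0.002 a.u./volume) +
  i.i.d. Gaussian noise (sd 1 a.u. ≈ 1% of baseline) + HRF-convolved
  block activation. The canonical double-gamma HRF (peak 6 s,
  undershoot 16 s, ratio 1/6, unit dispersions) is sampled at TR;
  regressors are scaled so an isolated 16 s block plateaus at 1, which
  puts planted amplitudes, GLM betas and PSC on one scale.
* The drawing blob ("SMA") and tapping blob are disjoint ellipsoids
  (radii 2.5 × 2.5 × 2 voxels, ~50 voxels over 5 slices); the localizer
  activates them at `max_psc_true` (2% of baseline by default) — the
  ground truth that the measured MaxPSC estimates.
* A neurofeedback trial activates the drawing blob at
  (amp_TL + bias[session, TL]) × max_psc_true. Amplitudes are fractions
  of MaxPSC, so faithful regulation is 0.6 / 0.9. The default bias table
  encodes the pattern the analysis is designed to detect: overshoot at
  level 60 shrinking across sessions (+0.186, +0.120, +0.054) and a
  small shrinking undershoot at level 90 (−0.053, −0.032, −0.011),
  which puts session-1 group means near 7.9 and 8.5 and session-3 means
  near 6.5 and 8.9 on the feedback scale. The bias is per session *and*
  target level: a single shared bias cannot express simultaneous
  overshoot at one level and undershoot at the other.
* The agent's prediction is round(w·prior + (1−w)·feedback + noise) on
  the integer 0–12 grid, where the prior is the running mean of its last
  five same-target-level feedback values (the level's own scale
  position, 6 or 9, anchors the very first trial — a modelling
  convenience; participants' actual first-trial anchoring is unknown).
  The prior weight w declines across sessions (0.85, 0.75, 0.65 by
  default), producing both the "closer to the prior than to the real
  value" signature and the session-wise improvement in prediction
  error. Confidence is conf_base (70%) + slope·|prediction − feedback| +
  noise, rounded to the 50–100 step-5 grid; the default slope of 0 makes
  confidence non-diagnostic, the null pattern the confidence hypotheses
  probe. `null_agent()` removes every structured effect (equal
  amplitudes, zero bias, w = 0.5 — which makes the distances to prior
  and real value exchangeable — and zero confidence slope) for
  false-alarm calibration.
* Randomness: one `SeedSequence` per (participant, session), spawned
  from the master seed, with further per-run splits, so any subset of
  the study reproduces independently. Identical (config, seed) gives
  byte-identical outputs.
* `simulate_study` runs the **closed loop**: the localizer is analysed,
  the region selected and MaxPSC computed, and each run is scored
  online so the agent reacts to the same feedback values the offline
  analysis will later recompute from the archived files.
  `simulate_behaviour_study` skips volume rendering and draws trial
  feedback directly as 10 × planted amplitude + Gaussian noise
  (sd 1.5 scale points), for large simulation batteries.

What the phantom deliberately omits: head motion, physiological noise,
spatial autocorrelation beyond downstream smoothing, multi-band
artefacts, non-Gaussian rating behaviour, and any dependence of the
agent on feedback *content* beyond the running-average heuristic.
Passing tests therefore certify the computation — scoring, selection,
models, hypothesis logic — not the realism of any particular human
dataset.

## Hierarchical models and the hypothesis battery

All three models are Gaussian multi-level linear models with random
intercepts and slopes per participant; each fixed effect carries a
participant-level deviation, `y_i ~ N(x_i'(β + b_j), σ²)`,
`b_j ~ N(0, Σ_b)`.

* **Self-regulation**: target-centred feedback (feedback − 6 or − 9) on
  target-level × session cell means.
* **Prediction**: the long-format distance of the prediction to its
  reference (real achieved value vs running-average prior, two rows per
  trial; trials without a prior are dropped) on reference × session cell
  means. The running prior is the mean of up to five most recent
  same-level feedback values, crossing run and session boundaries
  (nothing in the protocol resets it; `reset_per_session` covers the
  alternative) and including catch-trial feedback (it was displayed).
* **Confidence**: confidence on per-session intercepts plus per-session
  slopes for prediction accuracy (|prediction − feedback|) and for the
  achieved feedback value, both grand-mean centred so the intercepts
  read as session means.

Cell-means coding keeps every directional hypothesis a transparent
linear combination: e.g. the session-1 target-level contrast on the raw
feedback scale is (μ_90,s1 − μ_60,s1) + 3, because the two centred cell
means sit 3 scale points apart.

**Sampling.** A blocked Gibbs sampler in the hierarchically centred
parameterisation η_j = β + b_j: per-group coefficients, the population
mean (flat prior), the residual variance (Inv-Gamma(1e−3, 1e−3)) and
the random-effect covariance (Inv-Wishart with ν₀ = q + 2 and scale
(0.5·sd(y))²·I) are updated in turn from their exact conditionals. The
centred parameterisation removes the β ↔ mean(b_j) random walk that
makes the uncentred sampler mix slowly when group effects are large.
Conjugate priors were chosen over half-t/LKJ alternatives because they
admit exact Gibbs updates; with 8 participants and ≥ 1000 trials the
likelihood dominates these weakly-informative choices. The default
schedule is 2 chains × 5000 iterations with 2000 warm-up;
`MCMCConfig.trimmed()` (2 × 1500, 500 warm-up) is used for simulation
batteries where many studies are fitted. Per-iteration cost is
independent of the number of rows (sufficient statistics are
pre-computed per participant), so a fit takes seconds.

**Diagnostics.** Split-R̂ and effective sample size (via arviz) on every
fixed effect and the residual scale; hypothesis evaluation refuses when
max R̂ ≥ 1.01 unless forced.

**Hypotheses A–Q.** The battery (17 statements over the three models —
regulation separation and level-wise learning A–E, prediction-error
decline and prior reliance F–J, confidence change and its accuracy /
self-regulation slopes K–Q) is a *reconstruction from the results
narrative* of the study it models; the original's exact formulae live in
supplementary material that is not part of this package's sources. Each
hypothesis is the posterior mass of a signed linear combination being
positive; the participant level adds that participant's random
deviations before thresholding. The accuracy-slope hypotheses L–N are
evaluated as −slope > 0 (better accuracy, i.e. smaller error, means
higher confidence); the self-regulation-slope hypotheses O–Q are
evaluated in the positive-slope direction, matching the sign of the
reported group estimates — the two-sided reading would halve their tail
mass.

## Problem sizes and numerical conventions

* Desk-scale defaults: 24 × 24 × 12 voxel grid (2 mm, TR 1 s),
  8 participants, full 3-session × 6-run × 10-trial schedule. Pipeline
  and end-to-end tests run smaller grids (12 × 12 × 6) and fewer
  runs/participants; the simulation-battery tests use the
  behaviour-only generator with 8 participants and the trimmed sampler.
* Percentiles use linear interpolation (h = q/100·(n−1)); rounding to
  rating grids is half-up; feedback clipping is to the closed interval
  [0, 12].
* Window extraction validates bounds and reports the offending trial;
  non-positive baseline or MaxPSC raise immediately (they indicate a
  corrupted baseline, not a scorable trial).
* Greedy region growth raises `ROISelectionError` naming the achieved
  size when no admissible neighbour remains.
* The pipeline records SHA-256 hashes of every stage output in
  `manifest.json`; all artefacts are NIfTI-1, CSV or JSON.

## Known limitations

* The greedy growth rule and the hypothesis formulae are this package's
  definitions of under-specified procedures (see above); both are
  flagged where they appear.
* Gaussian likelihoods are used for bounded, discretised outcomes
  (0–12 and 50–100 scales), as in the analysis being modelled; ordinal
  or beta likelihoods are out of scope.
* No AR(1) prewhitening or slice-timing correction in the GLM; the
  phantom's noise is white by construction.
* The closed-loop simulator scores with batch least squares once per
  session rather than emulating incremental real-time refitting.
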