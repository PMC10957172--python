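# Methods

`vta-memcode` re-implements, as a tested pipeline over synthetic data, a
single-neuron analysis of memory-specific coding in midbrain dopamine
(DA) and GABA neurons: mice run a figure-eight T-maze in which a visual
cue instructs a left or right reward arm, a delay separates the cue from
the choice point, and optogenetically identified VTA units are screened
for firing-rate differences between left-bound and right-bound runs.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmarks do and do not establish.

## Synthetic sessions

Every analysis stage is validated against a generator with planted
ground truth rather than recordings.  One synthetic session emulates:

- **Behavior.** 90 trials (configurable within the 80–100 range typical
  of a session), correct-response probability 0.87, left/right
  trajectories pseudo-random and balanced within 10%.  Each run covers a
  150 cm linearized track — start 0–50 cm, visual cue 50–80 cm, delay
  80–120 cm, side arms 120–150 cm — with a per-trial mean speed drawn
  lognormally around 20 cm/s (SD 6) and a smooth within-trial speed
  modulation floored at 20% of the trial mean, integrated into a
  strictly monotone position trace sampled at 50 Hz.  Reward-consumption
  dwell is uniform on 1–10 s; inter-trial gaps (the return run, which is
  not tracked) are uniform on 2–5 s.
- **Spiking.**  An inhomogeneous Poisson process, piecewise constant on
  the 20 ms tracking grid: rate = base rate × Gaussian position-field
  gain × trajectory gain × reward factor.  DA-like units default to a
  5 Hz base rate and GABA-like units to 20 Hz (the classes' relative
  rates are the constraint; the absolute values are configurable
  defaults, drawn lognormally per unit with σ=0.3).  Units carry 1–3
  Gaussian fields (widths 8–20 cm, gains 0.3–1.5).  A planted
  trajectory-modulated unit multiplies its rate by `traj_gain` (default
  2, randomly inverted to prefer either side) on left trials inside its
  modulated sections; this gain applies only on memory-task trials,
  because it emulates an internal choice signal that requires a
  memory-guided decision.  Reward responders apply a step gain (3×
  excited, 0.2× inhibited) for 1 s after the first lick, side-scaled by
  a lognormal left/right gain; the same side gain is applied in the side
  arms on all tasks, emulating the task-general sensory/motor asymmetry
  of physically distinct arms.  This coupling is what makes the
  side-arm and reward-epoch differences correlated across units while
  the delay difference stays independent of both.
- **Optotagging.**  Four light blocks (1–4 mW at 1, 2, 5, 10 Hz), 150
  twelve-millisecond pulses each.  A tagged unit fires one evoked spike
  per pulse with probability 0.8 at latency N(4 ms, 1 ms) resampled into
  the artifact-free (1, 11) ms window; spontaneous firing continues
  throughout.  Waveforms are a per-unit template plus independent noise
  at RMS signal-to-noise 10 for the spontaneous and light conditions.
- **Planting.**  Modulated/responder counts are `floor(n × fraction)`
  with membership chosen by a seed-fixed permutation, so recovery tests
  have exact expectations.  Default planted delay-modulated fractions:
  0.20 of 100 DA-like units and 0.47 of 74 GABA-like units.

What the generator does **not** emulate: bursting and refractoriness,
waveform drift, error-trial kinematics, overdispersion beyond Poisson,
spike sorting artifacts, and any dependence between behavior and firing
other than the planted gains.  Green benchmarks therefore establish
that the estimators and tests recover effects of the planted form at
realistic sizes — not that real recordings contain such effects.

## Linearization and the rate estimator

Each trial's analysis span runs from trial start to the first waterspout
lick; the return run is excluded.  The span is divided into 100 position
bins (bin x covers ((x−1)/100, x/100] × 150 cm).  Occupancy splits each
inter-sample interval across the bins its linearly interpolated path
traverses, proportionally to the path length in each; spikes are
assigned by linear interpolation of position at spike time.  Because
occupancy and spike assignment share the same interpolation support,
the rate estimator is exactly unbiased for a constant-rate unit —
midpoint assignment of whole intervals, the simpler alternative,
mismatches the supports and inflates the trial-averaged ratio by ~2% at
50 Hz tracking.  Per-bin speed is bin width
over occupancy.  The firing-rate estimate is the occupancy-normalized
trial average λ̂(x) = (1/K) Σ_k n_k(x)/t_k(x); trials with zero
occupancy at a bin are skipped there (n/t is undefined at t = 0, and
skipping is the unbiased choice for a Poisson rate), and bins no trial
visited are flagged missing.

Only correct memory-task trials enter trajectory analyses; error trials
are kept for the GLM's accuracy covariates.

## Smoothing

Rate maps are smoothed with a unit-sum Gaussian kernel of σ = 0.5
position bins on a 21-tap window (±10 bins); at the edges the kernel is
renormalized over its valid support, so constant maps are preserved
exactly.  Missing bins are linearly interpolated before convolution and
re-flagged after.  The narrow default deserves a comment: a 20-point
window invites a much wider kernel, but the permutation test's
multiplicity control (below) relies on neighboring bins staying nearly
independent.  With σ = 5 bins the pointwise p-values are so strongly
correlated that the run-length criterion passes null fluctuations at
14–23% per section; with σ = 0.5 the same criterion holds the
per-section false-flag rate below 1%.  σ is exposed in bin units
everywhere; users who broaden it should recalibrate `min_run`.  The
reward-epoch PSTH uses the same machinery with σ = 5 time bins (50 ms),
where nothing downstream depends on inter-bin independence (the
segment tests run on raw counts).

## Trajectory permutation test

The observed statistic is D0(x), the smoothed left-mean minus
right-mean rate.  Trajectory labels are reshuffled across correct
trials preserving the left/right counts; each permutation recomputes
the smoothed group means.  Pointwise two-sided p uses the add-one rule
p = (1 + #{|D_perm| ≥ |D0|}) / (n_perms + 1), which keeps p ≥
1/(n_perms+1) and the test exact-level.  When the number of distinct
label assignments is at most `n_perms` (e.g. 3+3 trials), the test
enumerates all of them instead of sampling — the standard small-sample
practice — and the add-one correction is dropped because the identity
assignment is included.  A bin is flagged only when p < α (0.05) and it
sits in a run of ≥ `min_run` = 3 consecutive sub-α bins; a neuron is
trajectory-specific in a section when at least one flagged bin falls
there.  The run criterion is the multiplicity control for ~100
simultaneous bins; measured on 200 null units it holds every section's
neuron-flag rate below 1% while detecting a planted 2× delay gain in
99% of units at 90 trials.  Permutations are vectorized as a
(n_perms × trials) membership matrix times the per-trial rate matrix,
followed by one smoothing-matrix multiply.

## Firing-rate GLM with shuffle calibration

Per unit, one observation per (trial, bin) with occupancy, response
FR = n/t unsmoothed, and 17 coefficients:

    FR = β0 + Σ_{k=1..6} β_TPk·T·P^k + Σ_{k=1..6} β_Sk·S^k
         + β_TN·TN + β_R·R + β_A0·A0 + β_A−1·A−1 + ε

with T ∈ {1 left, 2 right}, P normalized position in (0, 1], S speed,
TN trial number, R cumulative correct rate, A0/A−1 current/previous
accuracy (first trial's A−1 set to 1 — animals enter sessions trained).
The model is fit by ordinary least squares (Gaussian noise, identity
link); BIC = n·ln(RSS/n) + k·ln(n) drives polynomial-order selection.
For conditioning the position and speed power blocks are orthogonalized
by QR internally and the coefficients mapped back to the monomial
basis; predictions are identical in both bases (tested to 1e−8).

The formula is reproduced verbatim, including its quirk: T multiplies
the position polynomial and there is no position main effect.  Two
consequences are documented rather than "fixed".  First, a unit's
position tuning is absorbed by the T·P block, so the model-predicted
left−right difference D̂ = −Σ β_TPk·mean_region(P^k) (prediction at
T=1 minus T=2, averaged over the tested region's bins — delay by
default) is contaminated by tuning in both the observed fit and the
shuffled refits; the shuffle test below stays exact-level but loses
power on strongly field-tuned units, so permutation and GLM
concordance on spiking units is partial by construction.  Second, the
monomial basis is near-collinear (coefficient-SE multipliers up to
~10³), so coefficient-level recovery is demonstrated in a low-noise
regime chosen by rule — observation noise small enough that the
worst-conditioned coefficient's SE sits an order of magnitude below
the coefficient scale — while prediction-level correctness is tested at
realistic noise.

Significance of a predictor: shuffle its trial assignment (speed as
whole-trial profiles; trial-constant covariates as scalars), refit,
recompute D̂_j; 500 shuffles; reject when |D̂0| exceeds the
(1 − α/m)-quantile of |D̂_j| with α = 0.05 and Bonferroni m = 6 (the
number of predictors tested — the most natural reading; configurable).
A guard requires n_shuffles·α/m ≥ 2 so the corrected quantile is
resolvable.  Constant predictors are reported untestable.

## Optotagging

The pulse-aligned PSTH counts spikes in 1 ms bins of the 12 ms pulse
window across pulses; bins 0–1 and 11–12 ms are stimulation artifacts
and excluded from testing.  The baseline band draws 1000 surrogate
pulse-onset sets uniformly from the inter-pulse baseline (which must be
at least 10× the summed pulse-window duration), records each
surrogate's maximum non-artifact bin rate, and takes the
(1 − α)-quantile (α = 0.01) — a single global band that controls the
family-wise error across the ten tested bins.  A unit is
light-responsive when any non-artifact PSTH bin exceeds the band.
Identity of spontaneous and light-evoked waveforms is the Pearson
correlation of the flattened channel × sample matrices, with 0.9 as the
field's conventional threshold; template-plus-noise at SNR s gives
E[r] ≈ 1/(1 + 1/s²), tested against simulation.

## Reward-epoch analysis

The reward section is the first second after the first lick, binned at
10 ms.  Excitation/inhibition: ten 100 ms segments are each compared to
the 100 ms pre-lick rate by paired t-test across the preferred side's
trials (p < 0.05); the overall class uses the epoch mean.  Left/right
preference: trial counts differ between sides, so the default is
Welch's two-sample test on per-trial epoch means (a rank-pairing option
provides the literal paired reading).  Per unit, the mean left−right
smoothed difference is computed for each maze section (D_start, D_cue,
D_delay, D_arms) and the reward epoch (D_reward); per class, D_reward
is Pearson-correlated with each maze section's difference.  Finally
units are placed in the six delay × reward preference categories
(left/right/ns in each), with same-side / different / neither summary
counts.

## Behavioral statistics

Per session: overall/left/right correct rates; the choice × accuracy
independence test is a 2 × 2 χ² without continuity correction, compared
to the χ²(1) 0.05 critical value 3.84 (a uniformly correct session has
no accuracy variation, so its statistic is 0 by convention).  Across
sessions: paired t-tests of left vs right rates and of low- vs
high-memory-load rates, with zero-variance difference vectors reported
degenerate rather than producing spurious statistics.

## Reproducibility and problem sizes

All randomness flows through `numpy` Generators seeded explicitly;
pipeline stages draw their seeds from a master seed through a
SeedSequence counter scheme, and every artifact carries the
configuration hash.  The recovery benchmarks use 500 trials for the
rate-estimator check, 200 null and 100 planted units (90 trials, 1000
permutations) for the permutation calibration, 20 + 80 model-simulated
units (500 shuffles) for the GLM, 100 tagged + 100 untagged units (600
pulses, 1000 resamples) for optotagging, and the full 174-unit default
cohort end to end — sizes chosen to make binomial error small relative
to the margins being tested while a complete run stays in the minutes
range on one core.

## Known limitations

- The tagging band is one defensible construction of an "upper
  confidence limit" of baseline activity; latency-based criteria
  (SALT-style) are out of scope.
- The GLM's verbatim functional form limits coefficient
  interpretability and field-tuned power, as discussed above.
- Occupancy is exact only up to the linear-interpolation model of the
  path between tracking samples; the conservation tests bound the
  total, and the proportional splitting differs from midpoint
  accumulation by at most two boundary intervals per bin.
- The generator's behavior model has no error-trial kinematics and no
  within-session fatigue trend beyond the speed draw.
- The 100 ms pre-lick baseline sits at the end of the approach run, so
  a unit with a position field near the waterspout has an elevated
  baseline and can classify as mildly reward-inhibited without a
  planted response; cohort-level excitation/inhibition counts inherit
  this end-of-track tuning artifact.
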