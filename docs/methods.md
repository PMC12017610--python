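# Methods

`moodspeech` implements a speech-marker analysis for mood-disorder symptom
monitoring: acoustic voice-quality indices, conversational timing indices,
and semantic/NLP scores are extracted from a speech recording plus a
word-timestamped transcript, correlated against clinician-rated symptom
totals (MADRS for depressive, YMRS for manic symptoms, both 0–60), and used
as predictors in random-forest severity regressions under nested
cross-validation with Shapley attributions. Because no participant
recordings ship with the package, a synthetic-data layer generates inputs
with exactly known ground truth; every claim the test suite makes is a
claim about recovery of that ground truth.

## Synthetic speech: perturbed glottal pulse trains

Voiced speech is emulated as a train of exponentially damped sinusoid
pulses. With target fundamental frequency `f0`, period `i` is

    T_i = (1/f0) * (1 + j * z_i),    z_i ~ N(0, 1) iid,

with relative jitter `j`, and pulse `i` carries amplitude
`A_i = A0 * (1 + s * w_i)` with relative shimmer `s`. Draws producing a
non-positive period or amplitude are rejected and redrawn (counted in the
returned metadata); at the perturbation levels of interest (≤ 5 %) redraws
essentially never occur. Pulses are placed at continuous-time epochs and
evaluated analytically on the sample grid, so epoch timing is not
quantized. The kernel carrier sits at `min(6 f0, 0.35 sr)` and the decay
time constant at `1/(7 f0)`, leaving the previous pulse's tail at ≈ 0.1 %
amplitude by the next epoch — small enough that per-cycle peak times and
amplitudes are measurable to sub-sample accuracy. White Gaussian noise is
scaled from the rendered signal's empirical power to hit the requested SNR.

Two closed forms anchor the tests. For iid normal multiplicative
perturbations, the expected local jitter (mean absolute successive period
difference over mean period) is `2*sigma/sqrt(pi)`, and identically for
local shimmer. For a periodic signal plus independent white noise, the
normalized autocorrelation at the period lag satisfies `r/(1-r) =
P_signal/P_noise`, so the frame harmonicity `10*log10(r/(1-r))` equals the
additive SNR in dB — the HNR calibration checks exploit this directly.

Sessions compose speech segments (pulse trains) and silence segments
(noise floor 60 dB below the speech RMS — the generator enforces at least
40 dB) and carry a word plan that must lie inside speech segments; the
returned transcript and segment boundaries are the plan itself.

What the generator does **not** emulate: formants, articulation,
coarticulation, intonation contours, breath noise, room acoustics,
ASR transcription errors. Passing tests demonstrate that the measurement
chain is correct and well calibrated on signals whose ground truth is
known; they do not demonstrate clinical validity on real speech.

## Synthetic cohorts

Cohort tables use a one-factor Gaussian copula per feature: a latent
standard normal per target, and for a feature with configured Spearman
correlation `rho_s` the latent Pearson correlation is `r = 2 sin(pi
rho_s/6)` (the exact Gaussian-copula correspondence), so the population
Spearman against the continuous target latent equals the configured value
before noise and discretization. Symptom totals are negative-binomial
quantile transforms of the target latents, truncated to 0–60:
MADRS ~ NB(size 1.1, mean 19) (median 13, IQR 21) and YMRS ~ NB(size 0.45,
mean 13) (median 5, IQR 16), mimicking the strongly right-skewed severity
distributions of clinical bipolar-disorder samples. Score discreteness
introduces rank ties and therefore a small (< 0.01 at the levels used)
attenuation of sample Spearman relative to the configured target — well
inside the ±0.05 recovery tolerance tested at n = 2000. Sex-dependent
effect modification multiplies the copula correlation in one stratum
(females by convention); a modified |r| ≥ 1 is rejected as infeasible with
the offending features named.

## Silence segmentation

An intensity detector: frame RMS on 50 ms windows with 10 ms hop; the peak
reference is the 99.5th percentile of frame intensity (robust to clicks);
frames below `peak + threshold` (threshold negative dB, default −25) are
silent, so raising the threshold toward zero can only increase detected
silence. An absolute floor (−55 dBFS) additionally marks very quiet frames
silent, which keeps an all-quiet recording labeled as one silent interval.
Runs shorter than the minimum silent/sounding durations (0.10 s each) are
merged into their neighbors, silent-run merging first. Interval boundaries
are refined on a fine (1 ms) intensity track by locating the nearest
threshold crossing, which keeps boundary error well under the coarse
window half-width; intervals are half-open `[start, end)` seconds and tile
the recording exactly. All parameters are configurable; the defaults
follow common phonetics silence-annotation practice.

Conversational indices from the segmentation and a word count: speech
duration, phonation (sounding) time, silence time, phonation/duration,
silence/phonation (reported missing, not infinite, when phonation is
zero), and speech rate in words per second of speech duration (word rather
than syllable rate — the unit is in the column name).

## Voice quality

Pitch is tracked by short-time normalized cross-correlation (NCC): window
`3/floor` s, hop 10 ms, lag range `[sr/ceiling, sr/floor]` (defaults 75–500
Hz), parabolic interpolation of correlation peaks for fractional lags.
Candidate selection is a Viterbi path: a voiced candidate costs `1 - r`
plus a small octave cost (0.01/octave, favoring higher-frequency
candidates — subharmonic lags of a periodic signal tie the true lag in
correlation and must be disambiguated), the unvoiced state costs
`1 - voicing_threshold` (threshold 0.45), transitions pay 0.35 per octave
jumped and 0.14 for voicing switches. Frames of digital silence produce no
candidates and come out unvoiced; no absolute level gate is used, keeping
every voice-quality output invariant to amplitude scaling.

Cycle epochs are located by F0-guided peak picking within each voiced run:
from the strongest waveform peak, walk both directions in steps of the
local period, snapping to the consistent-polarity waveform peak within
±30 % of a period, with parabolic sub-sample refinement; cycles whose
period leaves the plausible band split the run and are counted as dropped.
Perturbation measures are computed within voiced runs only and pooled
across runs weighted by cycle count (pauses are never bridged):

* jitter: local `mean|dT|/mean T`, local absolute, RAP and PPQ5
  (3- and 5-point moving-average reference periods), DDP = 3·RAP;
* shimmer: local `mean|dA|/mean A`, local dB `mean|20 log10(A_i/A_{i-1})|`,
  APQ3/5/11, DDA = 3·APQ3 (the Praat-compatible de-facto standard
  definitions; the APQ5/APQ11 and absolute variants are included for
  panel completeness).

F0 statistics use voiced frames only, with the population (divide-by-n) SD
convention. HNR maps each voiced frame's NCC at the chosen lag through
`10 log10(r/(1-r))` (r clipped to `[1e-6, 1-1e-6]`, bounding frame HNR at
±60 dB) and averages over voiced frames.

## Language features

Token normalization is lowercase + punctuation stripping + whitespace
split; no lemmatization, stemming or stop-word removal (deterministic and
language-agnostic). Word count is the transcript length; story match
counts transcript tokens (with multiplicity) whose normalized form occurs
in the story's token set. Latency is first-word onset minus task start.
Mean intraword time uses onset-to-onset intervals between successive words
(per-word production time including articulation); an offset-to-onset
"gap" convention is available behind a config switch. Word mover's
distance solves the exact transportation LP (HiGHS) between the two
normalized bag-of-words distributions with Euclidean ground distance in a
user-supplied embedding space; out-of-vocabulary tokens are dropped and
counted, and an empty side yields a missing value. No embedding is
bundled — which embedding model is appropriate is a study-level choice.

## Associations

Correlations are pairwise-complete Spearman (average ranks for ties) or
Pearson, with two-sided p-values, per-cell effective n, and explicit
missing-value reasons (fewer than 4 complete pairs, zero variance).
Severity dichotomization uses the clinical cutoffs MADRS ≥ 19 and
YMRS ≥ 20, boundaries inclusive. Group differences use the Mann–Whitney U
test (exact null when both groups ≤ 20 and tie-free, otherwise the normal
approximation with tie correction); U is oriented as the number of
(severe, non-severe) pairs with the severe value larger. Subgroup analysis
repeats the correlation computation per sex stratum (strata under 4
participants are omitted with a warning). No multiple-testing correction
is applied by default — raw p-values are the primary output — with
Benjamini–Hochberg available as an option. Heat plots use a diverging
scale fixed at [−1, 1].

## Severity models

Random-forest regression of symptom totals on three canonical panels
(NLP + conversational, acoustic, combined), each optionally sex-adjusted
by appending a binary column (male = 0, female = 1). Features enter
unscaled — tree ensembles are invariant to monotone scaling. Evaluation is
nested cross-validation: 5 shuffled outer folds, stratified by target
quartile (small-sample folds otherwise end up with incomparable target
distributions; an unstratified switch exists), and a 3-fold inner grid
search per outer training set over

    n_estimators {200} x max_depth {None, 5} x min_samples_leaf {1, 3, 10}

scored by MSE. The grid is deliberately small and skewed toward
regularization options: at the sample sizes this package targets (tens to
a few thousand rows, 1–25 features), forest size beyond 200 trees changes
estimates negligibly while leaf-size regularization is what actually moves
held-out error, so the grid spends its budget there. Rows with missing
features are dropped listwise per evaluation (imputation would inject
structure). Held-out R² may legitimately be negative; per-fold metrics
always satisfy `MAE² ≤ MSE`, and averages recompute exactly from fold
values, with an average involving any missing fold value reported missing
rather than silently dropped.

Shapley attributions explain a tuned forest refit on all complete rows.
The coalition game is the interventional/baseline form `v(S) = E_b
f(x_S, b_–S)` over a small seeded background sample; panels up to 12
features are solved by exact subset enumeration (symmetry and additivity
exact), wider panels by permutation sampling with a fixed seed — whose
per-permutation marginal contributions telescope, so local additivity
(attributions sum to prediction − base value) holds to machine precision
in both modes.

## Pipeline

A manifest CSV links each participant's WAV, transcript JSON, sex and
scores. Validation is report-only per row (range checks, schema checks,
clipping detection); extraction failures are isolated to their row. All
randomness derives from the config seed; outputs carry a hash of the
resolved analysis parameters (file locations excluded) instead of
timestamps, so a rerun into a clean directory is byte-identical. Model
stages require at least 10 complete rows and are skipped (with a QC note)
below that.

## Problem sizes used in verification

The self-verification suite (tests and `scripts/acceptance.py`) uses: 50
two-second pulse trains for perturbation recovery (mean local jitter and
shimmer within 25 % of `2 sigma/sqrt(pi)` at sigma ∈ {0.005, 0.01, 0.02});
20 trains spanning 90–350 Hz for pitch (median within 1 %); SNR ∈ {5, 10,
20} dB for HNR (±2 dB); 20 sessions for silence recovery (±25 ms per
boundary); 100 random toy document pairs against an exhaustive
integral-transport-plan enumeration oracle (agreement to 1e-6); cohorts of
n = 2000 for Spearman recovery (±0.05) and n = 500 per stratum for
sex-modification ordering; and n = 200 cohorts for model sanity. The
planted-signal recovery bound (mean nested-CV R² ≥ 0.5) is evaluated on
the mean over 10 seeded replicates because the single-replicate sampling
SD (≈ 0.08 from fold-split and cohort randomness) is comparable to the
quantity's margin over the bound, so a mean over few replicates would
test the luck of the draw rather than the recovery property; the
pure-noise bound (R² ≤ 0.1) is checked per seed over 10 seeds, the
stricter reading for a null.

## Known limitations

* The pitch tracker and epoch picker are tuned for the package's own
  pulse-train signals and clean sustained phonation; real conversational
  speech (breathy voicing, creak, transients) would need the full battery
  of cross-checks against a reference analyzer.
* Story matching is type-level set membership after normalization;
  morphologically rich languages would benefit from lemmatization, left as
  an extension.
* The severity models are cross-sectional; no longitudinal or causal
  claims are supported.
* Cohort feature marginals are Gaussian; real acoustic feature
  distributions are often skewed, which matters for Pearson (not Spearman)
  analyses.
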