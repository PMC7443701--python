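# Methods

`lexdecode` re-implements, as a tested pipeline over synthetic data, the
analysis of a word-pair priming fMRI experiment on homonym comprehension:
univariate ROI contrasts, trial-wise GLM pattern estimation, ROI-based
linear decoding of (a) semantic relatedness and (b) homonym meaning, and
Monte-Carlo permutation group inference. This note records the model, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Experimental design

Ten target words — five balanced homonyms (*bark, calf, cell, pupil, seal*)
and five matched unambiguous controls (*coal, menu, monk, poet, wizard*) —
are each paired with 12 primes: for homonyms, 4 related to each meaning and
4 unrelated; for controls, 8 related and 4 unrelated. The 120 pairs are
divided into four 30-trial sets; per set each target appears twice with
related primes (opposing meanings, for homonyms) and once with an unrelated
prime, giving 20 related / 10 unrelated trials per run. Each set is shown
once under a semantic and once under a phonological judgement task (8 runs,
158 volumes of TR 1.8 s each). A trial is fixation (1.5 s), prime (0.5 s),
delay (1.5 s), target (0.5 s), so target onset trails prime onset by
exactly 2.0 s. Prime identities beyond the ten printed targets are
synthetic placeholder tokens; the real prime lists, and the collection of
relatedness ratings, are out of scope.

**ITI jitter.** Only the ITI mean (5 s) and range (3.5–7 s) are part of the
protocol; a uniform distribution on that range has mean 5.25 s, so the
distribution must be right-skewed. We sample from the half-second grid
{3.5, …, 7.0} with weights ∝ exp(−(x−3.5)/1.5) — the near-exponential shape
standard for event-related jitter — exponentially tilted (tilt solved
numerically once) so the expected ITI is exactly 5.0 s. This is one
admissible distribution, not a reconstruction of the original. An iid draw
of 29 ITIs occasionally exceeds the 284.4-s run (a ≈3.6σ event, but one
that surfaces across the tens of thousands of runs the calibration suites
simulate); since real schedules are constructed to fit, the scheduler
redraws the jitter in that case (seed-deterministic; the induced truncation
shifts the expected mean by <1e−3 s). Impossible configurations still raise
an overrun error.

**Counterbalancing.** Tasks are blocked four runs at a time, block order
alternating with participant parity; set order rotates Latin-square style
every two participants; trial order is randomised per (participant, run)
with a derived seed, so whole-cohort simulations replay bit-identically.

## Synthetic voxel data

The generator produces, per participant and region, trial×voxel patterns
(direct mode) or BOLD time series (time-series mode) carrying three
separable signals, in units of the voxel noise SD:

- `univariate_offsets`: a mean shift per condition (what univariate
  contrasts detect, and what per-trial mean-centring is designed to remove);
- `relatedness_amplitude`: a unit-norm multi-voxel pattern added on related
  and subtracted on unrelated trials (what the relatedness classifier reads);
- `meaning_amplitude`: one unit-norm pattern per (homonym, meaning), drawn
  independently per participant (what the meaning classifier reads; random
  unit vectors in ≥60 dimensions are near-orthogonal).

Defaults are a pure-noise region (`noise_sd` 1.0, amplitudes 0): analyses
plant effects explicitly, and the type-I calibration runs on the default.
Patterns are redrawn per participant because all decoding is
within-participant; group inference only averages accuracies. Noise is iid
Gaussian across voxels; time-series mode adds AR(1) noise over volumes
(ρ = 0.3) and optional slow cosine drift. Motion, physiological noise,
susceptibility dropout and spatial autocorrelation are not modelled, so
passing tests demonstrate the statistical machinery, not robustness to
scanner artefacts.

**Effect-size calibration.** No effect sizes for pattern signals are part
of the protocol; amplitudes are free parameters. For power analyses we
calibrate `meaning_amplitude` to a target *cross-validated* sensitivity d
of the held-out SVM decision variable, using the two-alternative convention
PC = Φ(d/√2) (each test run holds one trial of each meaning). With pattern
separation D = ‖µ₁−µ₂‖/σ and a weight vector estimated from n trials per
class in V voxels, the held-out sensitivity is ≈ D²/√(D² + 2V/n); weight
estimation noise is why the required amplitude grows with V/n. The
population-Mahalanobis reading of "d" would ignore that term and, at 6
training trials in 60 voxels, cap realised accuracy near 0.6 — no amplitude
satisfying it could support a recovery test. The closed-form inverse lives
in `meaning_amplitude_for_discriminability`; d = 1.5 at the default scale
gives amplitude ≈ 2.82 and realised accuracy ≈ 0.85.

## First-level GLM

The multivariate stream fits, per run, one 2-s boxcar regressor per target
(30 columns), a single impulse regressor for all primes (duration 0), a
discrete-cosine drift basis up to the 128-s high-pass cutoff
(K = ⌊2·T/128⌋ = 4 at 284.4 s), and an intercept; estimation is per-voxel
OLS (least-squares-all: all trials in one model), and the decoded features
are t-values (β/SE). The univariate stream replaces the 30 trial columns
with 4 condition columns. The canonical HRF is the standard double gamma
(peak 6, undershoot 16, dispersions 1, ratio 1/6), peak-normalised;
convolution runs on a 16× oversampled grid shared with the BOLD simulator,
so noiseless simulation is recovered exactly (to solver precision). No
prewhitening is applied: AR(1) noise slightly inflates the t scale
uniformly, which is harmless for decoding because patterns are used
comparatively. Note the DCT high-pass removes a subspace: drift inside the
basis span is absorbed exactly, but off-grid slow sinusoids near the
transition band are only attenuated (measured 3–30% leakage of the drift
amplitude into trial betas for 220–800-s periods) — intrinsic to subspace
projection and shared by the standard implementations of this filter.

## ROI masks

ROIs come from probabilistic atlas maps by strict thresholding (probability
> 0.30; a voxel at exactly 0.30 is excluded, the literal reading of
">30%"), optionally intersected with a millimetre-space cutoff — for pars
orbitalis, voxels more medial than x = −30 are removed (x ≤ −30 kept,
boundary retained). `max_probability_fraction` reports the share of mask
voxels whose target probability strictly exceeds every competitor's. Atlas
files are not bundled; tests use synthetic Gaussian-blob maps, and real
Harvard-Oxford/LPBA40 NIfTI maps load through the same path. Reproducing
the published max-probability statistic (94%) depends on atlas versions and
is a non-goal.

## Decoding

Both classifiers use a linear SVM (LIBLINEAR; primal squared-hinge,
`dual=False`, so fitting is deterministic) under leave-one-run-out
cross-validation, with C chosen per training fold by nested
leave-one-run-out cross-validation over the eight decade values 1e−4…1e3
(only the range is part of the protocol; the grid density and the
smallest-C tie-break are ours). Accuracy is the raw proportion correct —
classes are balanced by design in both analyses. The relatedness classifier
mean-centres each trial pattern (across voxels) first, so mean activation
differences cannot drive it; the meaning classifier does not centre by
default (centring is only specified for the relatedness analysis; a flag
exposes it). The searchlight repeats the decoder in a sphere of 12-mm
radius around each in-mask voxel and writes per-voxel accuracy maps;
cluster-level inference on those maps is a non-goal. Accuracy maps can be
smoothed with a 4-mm-FWHM Gaussian before any group step.

## Group inference

Decoder accuracy is compared to chance empirically. Per participant, the
relatedness null re-runs the identical pipeline on labels randomly permuted
within run (within-run permutation preserves the 20/10 run balance and the
leave-one-run-out exchangeability structure; the protocol specifies only
"randomly permuted"), 100 times by default. The meaning null is exhaustive:
with one trial per meaning per run, the design-preserving relabelings are
within-run swaps, i.e. sign patterns over the 4 runs, collapsed modulo the
global label exchange (which cannot change a binary decoder's accuracy) and
excluding identity — 2³−1 = 7 per homonym, 35 values per participant, with
no randomness. The group null draws one value per participant (for the
meaning classifier, one per homonym per participant, averaged within
participant first), averages, and repeats 100,000 times by default; the
empirical p is #{null ≥ observed}/n, floored at 1/n so p is never 0. The
classifier×region interaction statistic is the difference of the two
classifiers' accuracy differences between two regions; its null is built by
drawing each cell's group-null value per iteration, and the test is
two-sided (p = 2·min(upper, lower), capped at 1 — sidedness is not stated
in the protocol, and two-sided is the conservative choice). All ROI tests
within a task's analysis are corrected together with Benjamini-Hochberg
FDR.

## Univariate ROI analysis

Condition estimates are unweighted means over mask voxels (and, in the
pattern-level pipeline, over trials). Region×ambiguity×relatedness effects
use classical repeated-measures ANOVA (participants random; no sphericity
correction, as none is part of the protocol); for a 2-level factor F equals
the squared paired t to machine precision, and per-region contrasts are
paired t-tests. `anova2x2_from_summary` computes a between-subjects 2×2
ANOVA from cell means/SDs/ns with unweighted (Type-III-style) marginal
means and pooled within-cell error; on the published relatedness-rating
summaries (items as units, n = 40/20 per cell) it reproduces the printed
relatedness F (≈1919 vs 1938, within the tolerance implied by rounded
inputs; whether the original ANOVA unit was items or raters is not stated).

## Problem sizes and numerical choices

The test suites run at desk scale: 12-participant cohorts, 60 voxels per
region, direct pattern mode, 30 permutations per participant and 2,000
Monte-Carlo group draws for calibration (200 null cohorts), 20 cohorts for
power — the package's own choice of simulation scale; the full-size
defaults (100 permutations, 100,000 draws) remain the API defaults.
Calibration and power suites fix C = 1 instead of nested selection: the
nested search multiplies SVM fits ~25-fold and is validated separately,
and the null machinery is agnostic to how C is chosen. Ties in nested
selection take the smallest C; the SVM solver tolerance is 1e−6 and fits
are deterministic; all randomness flows through `numpy` `SeedSequence`
chains derived from one global seed, so every result replays bit-exactly.

## Known limitations

Simulated noise is far simpler than scanner noise (no motion, physiology,
or spatial correlation); the time-series mode shares its convolution with
the GLM, so model mismatch of the HRF is not exercised; the searchlight is
a straightforward loop, adequate for the small grids used in tests but not
optimised for whole-brain volumes; and published headline ROI accuracies
and p-values depend on the original dataset and are not reproduction
targets here.
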