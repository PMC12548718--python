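# Methods

This package re-implements, as a tested library, an fMRI analysis chain for
spontaneous self-focus: (1) derive a multivoxel "pre-self" pattern that
decodes, from pretrial rest activity, whether a person is about to choose to
think about themself; (2) quantify the moment-to-moment *instatement* of that
pattern during resting scans; (3) test whether pre-self instatement predicts
the instatement of an active self-reflection pattern seconds later; and
(4) relate the similarity of instatement time courses across a cohort to
trait internalizing with an Anna Karenina intersubject RSA.  A forward
simulator with known ground truth stands in for scanner data, so every stage
can be exercised — and its parameter recovery measured — at desk scale.

## The forward model

**Task geometry.** The choice task is 108 trials over two runs (TR 1 s):
jittered pretrial rest (2.5–6 s, mean 4.5 s), a 5 s three-alternative choice
(self / friend / known other) crossed over six content dimensions
(18 trials each), and a 2–4.5 s (mean 3 s) shape-matching interlude.  The
printed timing gives only the jitter range and mean; a uniform distribution
on 2.5–6 s would have mean 4.25 s, so the sampler is a discretized
truncated-exponential on {2.5, 3.0, …, 6.0} whose rate is solved (Brent) so
the mean is exactly 4.5 s — standard fMRI jitter practice consistent with
both printed numbers.  The same sampler covers the interlude (mean below the
uniform mean, positive rate) and the reflection-task jitter (1–3 s, mean 2 s,
rate 0).

**Neural signal.** Volumes live on a 36×26×12 grid of 2.5 mm voxels with two
disjoint ellipsoid ROIs (~2100 voxels each) standing in for the core-network
and reflection-network nodes.  Ground-truth patterns are unit-RMS Gaussian
maps with a +0.5 spatial mean component (so univariate ROI analyses see net
activation; correlation-based instatement is insensitive to the mean).  Task
signal is the sum of HRF-convolved event responses; each pretrial-rest epoch
additionally adds `pattern_snr × noise_sd × a_i` times the pre-self pattern,
where the trial amplitude `a_i ~ N(0,1)` also drives behavior:
`P(self) = logistic(choice_gain · a_i + offset)`, the offset matching the
observed baseline choice proportions 1696 : 1127 : 624.  RTs are lognormal
(log-SD 0.3) with medians 1.8 / 1.95 / 2.0 s for self / friend / known
other; on self trials the log-RT decreases by `rt_gain = 0.15` per unit
amplitude, producing the faster-self-when-pattern-is-stronger coupling that
the parametric-modulation analysis recovers.  The RT and rating
distributions are simulator free parameters (the printed results give only
directions, not distributions).  Noise is white Gaussian per voxel plus a
per-voxel linear drift and a random-walk motion table; optional injected
spikes raise both the global signal and the frame difference.  Physiological
noise and spatial noise correlation are *not* modeled: passing recovery
tests show the chain is correct under its stated assumptions, not that real
data would yield these effect sizes.  With white noise, per-voxel SNR 0.5 is
generous, and cross-validated decoding saturates near 1.0; the chance-level
and permutation calibrations are therefore the sharper checks.

**Rest dynamics.** The latent pre-self amplitude a(t) is a unit-variance
AR(1) process with lag-1 autocorrelation 0.6; the reflection amplitude is
`b(t) = c · a(t − L) + noise`, scaled to unit variance (defaults L = 8 TRs,
c = 0.5).  The autocorrelation value matters: reverse-direction leakage in
the lag sweep is proportional to ρ^(8+L), so ρ = 0.8 would make the reverse
sweep ~13% as strong as the forward effect and Bonferroni-significant
whenever the forward effect is localizable, while ρ = 0.6 keeps it near
1%.  0.6 preserves the "smooth state occupancy" character at 1 s sampling
while making an 8-TR lag resolvable.  Default rest noise is
`noise_sd = sqrt(n_mask_voxels)`, which for a unit-RMS pattern gives a
per-TR instatement-to-state correlation of ~0.7 — strong enough that the
per-TR time course is meaningful, weak enough that single TRs are noisy, in
the spirit of template-matching analyses whose per-TR correlations are
small.

**Ratings and cohorts.** Block ratings are affine in the block-mean
instatement plus Gaussian noise (SD 0.5), clipped to the 1–5 probe scale;
other/future/past ratings are independent noise.  Cohort internalizing
totals are right-skewed (gamma(2, 6), rounded — ties arise as with real
symptom scores); subjects above the median share a latent time course with
loading `ak_share` (`tc = ak·shared + (1−ak)·idiosyncratic`), others are
fully idiosyncratic; subscales are the total plus rounded noise (SD 4).  Two
high scorers then correlate at `ak² / (ak² + (1−ak)²)` in expectation, which
the tests check against simulation.

## The analysis chain

**Residualization.** The canonical HRF is the double-gamma (response peak
6 s, undershoot 16 s, ratio 6, 32 s support), unit-peak normalized, built on
a 16× oversampled grid.  The task GLM contains one convolved boxcar column
per condition plus nuisance: 6 motion parameters, their derivatives and
squared derivatives, one-hot spike regressors (global signal beyond 3 SD
two-sided, RMS frame difference beyond 3 SD above its mean, and the first
n non-steady volumes), a linear drift and a constant per run.  Fitting is
per-voxel OLS; residuals are orthogonal to every design column (checked at
relative 1e-6; in practice ~1e-16).  Rank deficiency is an error naming the
collinear columns, never silently dropped.  Gaussian smoothing (default
6 mm FWHM for univariate stages, none for MVPA inputs) uses reflected
boundaries so the volume mean is conserved.

**Pre-self pattern.** A second GLM on the residuals codes the pretrial-rest
epochs preceding self, friend, and known-other choices; friend and
known-other betas are averaged into the "other" class (the combination rule
is not printed; averaging keeps per-class epoch counts comparable).  Each
subject contributes one beta map per class; a linear SVM (C = 1, per-feature
mean-centering fit on the training fold only — the centering choice is ours,
scaling is not applied) separates self (+1) from other (−1).  Validity:
subject-level sixfold cross-validation (random near-equal folds,
seed-controlled).  Inference: each permutation independently flips each
subject's label pair with probability ½, re-partitions, reruns the full CV;
p = (#{null ≥ observed}+1)/(n+1), ties counting against significance.  The
battery threshold is alpha/n_masks (0.003 for 15 masks).  The pre-self
pattern is the weight map of the SVM fit on all subjects' maps.

**Instatement and lag sweep.** Instatement is the per-TR Pearson correlation
of the masked volume with the masked pattern, Fisher z-transformed with |r|
clipped at 1−1e-6 (degenerate TRs are missing, with a warning).  Block
summaries average z within each 2-min rest block and z-score across a
subject's blocks (a zero-variance set of blocks is defined as all-zero);
this fixes an order-of-operations ambiguity by transforming each TR first,
averaging second, norming third.  The ratings model and the lag sweep are
random-intercept linear mixed models (statsmodels MixedLM, REML; Wald
z-based p).  Residual degrees of freedom are reported since a Satterthwaite
approximation is not available there; when the intercept variance estimate
hits the boundary at zero — common with within-subject z-scored outcomes —
the GLS estimator reduces exactly to OLS, and OLS standard errors are used.
The lag family is 41 tests (lags 0–20 in both directions, lag 0 entering
once, as the two directions coincide there), Bonferroni threshold
0.05/41 = 0.00122.  VIF and tolerance (=100/VIF %) are computed on the
fixed-effects design.

**IS-RSA.** The Anna Karenina model matrix holds pairwise mean trait ranks
(ascending from 0, average ranks for ties — the tie rule is ours; symptom
scores are discrete so ties occur).  The neural matrix holds pairwise
Pearson correlations of instatement time courses.  The statistic is the
Spearman correlation of the strictly-lower triangles.  The Mantel test
shuffles subject identities: because every matrix entry depends only on its
pair, relabeling time courses and recomputing all pairwise correlations is
mathematically identical to permuting the precomputed similarity matrix
jointly over rows and columns, which is O(N²) per permutation instead of
O(N²T).  The tests verify this equivalence against the literal recompute.
Each pair's rank is also permutation-invariant, so ranks are computed once
and gathered per permutation.  The test is one-sided (null ≥ observed),
add-one p, with z = (observed − null mean)/null SD.

**Behavioral statistics.** The printed choice statistics are reproduced
exactly by goodness-of-fit chi-squares (Σ(O−E)²/E against a uniform split),
although the source labels them tests of independence; the per-target counts
(1696, 1127, 624) are recovered by solving the linear system of the printed
pairwise Ns (2823, 2320, 1751; grand N 3447 — 9 trials short of 32×108,
presumably omitted responses, which the simulator can emulate).  RT effects
use a random-intercept mixed model with treatment coding (self as
reference).

## Problem sizes and numerical choices

The test suite runs everything at desk scale, chosen as the smallest sizes
at which the recovery properties are comfortably powered: decoding recovery
at 32 subjects × two 54-trial runs on the default grid with 1000
permutations; chance-level calibration over 100 seeds (beta-domain
generator, which produces the same Gaussian features the full chain yields
when no signal is embedded); permutation-p uniformity over 200 null
datasets at 79 permutations; lag recovery over 20 seeds at 32 subjects ×
480 TRs; null family-wise calibration over 200 seeds at 8 subjects ×
150 TRs; Mantel power over 50 cohorts (N = 60, 300 TRs, 5000 permutations)
and null calibration over 200 cohorts.  The full-scale sizes of the source
design (N = 1086, 100,000 permutations) are supported but not exercised by
default.

Degenerate-input conventions: correlations of zero-variance vectors are
errors (or missing values, for single TRs); base choice probabilities of 0
or 1 short-circuit the logistic; an empty event table builds a
nuisance-only design with a warning.  All generators are bit-reproducible
given a seed, and every stochastic routine takes an explicit seed — there is
no hidden global RNG state.

## Known limitations

- White, spatially uncorrelated noise makes multivoxel decoding far easier
  than on real data; accuracies here calibrate the machinery, not empirical
  effect sizes.
- The mixed models ignore residual temporal autocorrelation, as does the
  original analysis; under the simulator's measurement noise this is mild.
- No slice timing, motion correction, registration, or physiological noise:
  the artifact consumes preprocessed-like series by design.
- The parametric-modulation design (mean-centered RT modulators per class)
  is a documented stand-in where the source describes details only in
  supplementary material.
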