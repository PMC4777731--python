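# Methods

This note documents the models, defaults and numerical choices behind the
package, in the order the pipeline runs them.

## Experimental design generator

The factorial condition space is 3 motion patterns × 4 sizes × 2 stereo
levels = 24 conditions, indexed with motion fastest-varying, then size,
then stereo. A run presents each condition twice (48 trials of 3 s) on a
fixed 170-volume grid at TR = 2 s, with 10-s lead-in and lead-out blanks.

**ISI law.** Inter-stimulus intervals follow a discrete Poisson law in
whole seconds, truncated to [2, 8] s. The rate is calibrated once by root
finding (brentq) so the truncated mean equals 3.7 s; the solution is
λ ≈ 3.254. Sampling draws directly from the renormalized truncated pmf,
which is equivalent to rejection sampling and deterministic given a seed.

**Counterbalancing.** The true counterbalancing scheme of such
experiments is rarely published; we approximate it with a seeded uniform
permutation of the 48-trial multiset, re-drawn until no condition repeats
back-to-back. ISIs are re-drawn until the run, including its final 10-s
blank, fits the 340-s grid; this acceptance step conditions the
per-schedule ISI sum to ≤ 176 s and therefore biases realized
within-schedule ISI means downward by a few hundredths of a second. The
ISI *law* itself (what `scripts/acceptance.py` samples) is unaffected.
Realized run lengths are recorded in the design manifest.

**Dot fields.** Dot count is proportional to stimulus area with 800 dots
at the full 100° × 67.7° field (the 16:9 aspect is fixed, so area scales
with the squared width). Dot speed is linear in eccentricity from 0.12 to
3.9 °/s with the field-corner eccentricity (≈ 60.4°) as the reference for
all sizes, so the speed at a given retinal location is identical across
sizes. Stereo stimuli carry a ±3.77° disparity gradient and a 1.0°
fixation disparity. The generator parameterizes these stimuli; it does
not render them.

## Forward BOLD model

Per subject and ROI, a voxel tuning model defines the noise-free neural
amplitude of voxel v under condition c:

    A[v, c] = M[m, s] · (1 + V[v, s] · gate[m]) + P[v, m]
              + W[v] · z(st) + coupling[c]

* `M` (3 × 4) — mean amplitude per motion × size, in percent signal
  change around a ~100-unit baseline. For retinotopic archetypes the
  size dependence comes from the mean sigmoid coverage of the voxels'
  eccentricity preferences; CSv instead carries a small scalar size ramp
  on its coherent gain only.
* `V` — zero-mean voxelwise size pattern derived from each voxel's
  eccentricity coverage (a soft sigmoid of stimulus radius minus
  preferred eccentricity), gated per motion level. PcM's gate is
  coherent-only: its size information rides exclusively on the
  coherent-driven component.
* `P` — zero-mean per-voxel motion pattern codes. Their per-level SDs are
  the main decodability dial: all three levels for V1/hMT+/V6, coherent
  only for PcM/CSv, near zero for PIVC.
* `W` — zero-mean stereo pattern code (stereo coded ±0.5).
* `coupling` — optional condition profile shared by all voxels, used by
  the rating-coupled scenario.

A run's clean signal is the trial-wise design matrix (HRF-convolved
unit-scaled regressors, below) times per-trial amplitudes, so with all
noise off the trial-wise GLM recovers `A` exactly — the forward model and
the estimator share the same basis by construction.

**Noise.** AR(1) Gaussian time-series noise (coefficient 0.3, SD 2.0
signal units = 2% of baseline), multiplicative subject gain (SD 0.15),
run gain (SD 0.05) and per-trial amplitude jitter shared across voxels
(SD 0.1), plus a weak leakage of the six simulated head-motion series
into the data (the GLM includes the same series as nuisance regressors).
The multiplicative terms are what make spatially uniform mean differences
hard to decode while leaving voxel-heterogeneous patterns decodable — the
regime the real phenomenon occupies.

**Archetype defaults.** The per-ROI gains, pattern SDs and map parameters
in `synth.ARCHETYPES` are free parameters of the generator. They were
chosen so the full pipeline lands in the qualitative regime the method is
meant to resolve at n = 9 subjects: decoding accuracies roughly 0.3–0.9,
univariate motion contrasts of 0.03–1 percent signal change, and in
particular the joint CSv behavior — a ~0.04% uniform static-minus-random
difference that is Holm-significant univariately yet linearly
undecodable. Absolute pattern signal-to-noise is not identifiable from
published group statistics, so these numbers should be read as "a world
in which the method's distinctions are real", not as estimates of cortex.

**ROI sizes.** Each subject contributes 48 voxels per ROI by default
(432 pooled across nine subjects), and the decoder then selects 112
pooled voxels — the equalized count convention. The per-subject count is
deliberately larger than 112/9: with only ~12 voxels per subject the
ROI-averaged univariate contrasts (especially CSv's small inhibition)
are underpowered at this noise level, and the joint univariate + MVPA
signature cannot be expressed at desk scale.

**Ratings.** Vection ratings live on [0, 10], anchored at the standard
stimulus (coherent, 100°, stereo ≈ 9.6 expected). The coherent curve
(3.5, 6.0, 9.3, 9.6) saturates between 67° and 100°; random motion sits
at 1.5, static at 0.5; stereo has no effect by default (configurable);
between-subject SD 0.8, clipped to the scale. The clipped-normal mean
(closed form) gives the expected *observed* profile, which the coupled
scenario uses when constructing ROI profiles with exact target
correlations to the rating profile (residual direction orthogonalized
per ROI).

## GLM

The canonical HRF is the double-gamma difference (peak delay 6 s,
undershoot 16 s, ratio 1/6, 32-s support), peak-normalized, sampled at
0.1 s. Task regressors are 3-s boxcars convolved with this kernel and
sampled at volume times; **all task columns are scaled by the peak of one
isolated trial's response**, so a beta of 1 means a 1-unit peak excursion
for a single event irrespective of overlap between trials of the same
condition. This convention makes percent-signal-change scaling exact
(percent = 100·beta/baseline) and makes the average of a condition's two
trial-wise betas equal its condition-wise beta on noise-free data.

Estimation is ordinary least squares with six mean-centered head-motion
regressors and an intercept (31 columns condition-wise, 55 trial-wise per
run). OLS rather than prewhitened GLS: under the simulated AR(1) noise
OLS betas remain unbiased, and the permutation and resampling inference
downstream does not rely on parametric residual models. High-pass/drift
regressors are omitted because the generator produces no drift; the
design-matrix builder accepts extra nuisance columns if needed.
Rank-deficient designs are rejected with the offending column named.

## Univariate statistics

The three-way fully-within ANOVA is computed by projecting each subject's
24 condition means onto orthonormal Kronecker contrast bases (Helmert per
factor). For each of the seven effects this yields SS_effect = n‖t̄‖²,
SS_error = (n−1)·tr S, the Greenhouse–Geisser ε = (tr S)²/(q tr S²)
(clipped to [1/q, 1]), and Mauchly's W with its χ² approximation. The
correction is applied when Mauchly rejects at α = 0.05 — the conventional
"correct only if sphericity deviates significantly" gate; the α is an
assumption, as is the choice to collapse over the other two factors
before motion post-hocs. Degenerate inputs (zero error variance) return
F = 0 (no effect) or F = ∞ (exact effect) explicitly. No installed
package provides a 3-factor within-subject ANOVA with per-effect ε, so
the decomposition is implemented here and cross-checked in the tests
against statsmodels' AnovaRM (F values) and an independent brute-force
marginal-means implementation, with pingouin validating ε.

## Decoding

Samples are trial-wise betas in percent signal change, aligned across
subjects on the shared (run, condition, occurrence) grid and
concatenated voxelwise; misaligned grids are an error naming the
offending subjects. Voxel selection ranks by mean activation over all
samples (label-agnostic, hence computed once rather than nested in the
cross-validation) with ties broken by stable index.

The classifier is a linear soft-margin SVM, C = 1, one-vs-one.
**Engine.** Permutation inference reruns the full leave-one-run-out
cross-validation thousands of times on a fixed linear Gram matrix, which
the generic libsvm solver cannot do in reasonable time on permuted
(non-separable) labels. The default engine is therefore a dual
coordinate descent solver (the liblinear algorithm: randomly permuted
sweeps, active-set shrinking, projected-gradient stop at 0.1) on the
precomputed Gram with the intercept as an augmented kernel constant
scaled to the mean kernel diagonal — at that scale the intercept is
effectively unregularized and predictions match the free-intercept
libsvm solution. Sweeps are capped at 150 per subproblem; fold
accuracies are prediction-stable well before the cap (observed and null
distributions change by < 0.01 versus full convergence). sklearn's SVC
remains available (`SVMConfig(engine="libsvm")`) and the test suite
asserts agreement between the two engines. Optional per-voxel
standardization is computed on training folds only and is off by
default.

**Inference.** Each permutation replicate shuffles labels independently
within every run (preserving per-run label multisets) and reruns the
full cross-validation. p = (1 + #{null ≥ observed})/(1 + n_perm); the
95th null percentile implements the "above the 95% percentile" decision
rule. Accuracy-difference tests between two problems or ROIs share one
label draw per replicate where the label maps coincide, making the null
a paired difference; Holm adjustment is available across test families.
Binary results can be read off a multi-class confusion matrix by
excluding third-class predictions and renormalizing each of the pair's
rows (the derivation rule is stated explicitly because more than one is
defensible); directly retrained binary classifiers are the default for
archetype-recovery checks.

## Neuro-perceptual correlation

BOLD condition responses are z-scored within subject (population SD);
ratings are left raw by default (a toggle exists). Two inference modes
are provided because "converting r to a t-score" admits both readings:
pooled (one r over all subject × condition points,
t = r√(n−2)/√(1−r²)) and per-subject (Fisher-z of each subject's r,
one-sample t with df = n_subjects − 1), the latter being the default for
subject-level claims. ROI pairs are compared with the
Meng–Rosenthal–Rubin (1992) Z for dependent correlations sharing one
variable, Bonferroni corrected over the tested family (15 pairs for six
ROIs); a percentile bootstrap over the Fisher-z difference serves as the
independent cross-check in the tests. Size-stratified correlations
restrict the points to one size's six cells while keeping the full
24-condition z-scoring.

## Chance-compatibility conventions

Several scientific claims are of the form "this problem is *not*
decodable" or "this region shows *no* correlation". A p ≥ 0.05 cut on an
exactly calibrated test fails such claims 5% of the time by
construction, so null claims are instead checked as magnitude bands:
decoding accuracies must lie within 3 null SDs of the permutation null
mean, and a null correlation within ~3 SDs of zero (|r| ≤ 0.15 at this
design's n). Positive claims always use the permutation/parametric p at
α = 0.05.

## Problem sizes

Default analyses use 9 subjects × 8 runs × 170 volumes, 48 voxels per
ROI per subject, 112 selected voxels, and 999–1,000 permutation
replicates (10,000 available via `--paper-scale`); calibration studies
use 300 null datasets at 199 replicates and reduced feature counts.
These sizes were chosen so a single CPU reproduces every analysis in
minutes while keeping all inferential margins away from their
thresholds.

## Known limitations

* The BOLD model is linear-time-invariant with stationary AR(1) noise:
  no hemodynamic nonlinearity, drift, physiological noise, or spatial
  noise correlations, so absolute accuracies and F values should not be
  read as forecasts for real data — only the ordinal signature structure
  is calibrated.
* Counterbalancing and the exact dependent-correlation reference are
  reconstructions of under-specified conventions; both are flagged where
  implemented.
* Voxel selection is not nested inside cross-validation (defensible
  because the ranking is label-agnostic, but still a choice).
* The uniform-inhibition variant of the CSv archetype is the default;
  the sparse-activation alternative exists
  (`csv_sparse_fraction`/`csv_sparse_gain`) but is not exercised by the
  default pipeline.
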