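# Methods

This note documents the models, the numerical choices and the synthetic
data behind `strokepatterns`, and what the test suite does and does not
establish.

## Lesion representation

Lesion masks are binary images on a grid shared with a three-layer label
atlas (94 cortical regions, 15 subcortical regions, 20 white-matter
tracts; 129 regions in total).  The layers are counted independently: a
voxel labelled in both the cortical and the tract layer contributes to
both counts, since the three measure sets come from separate atlases.
Grids must match exactly (affines compared elementwise at 1e-4); no
resampling is ever performed, because the inputs are assumed spatially
normalized and silent resampling would corrupt counts.  Probabilistic
atlas distributions are discretized to maximum-probability labels with a
25% floor (`discretize_probabilistic_atlas`), the common practice for
these atlases.  Total lesion volume is voxels × voxel volume / 1000 (ml);
fixtures use 1 mm³ voxels so tests carry no affine ambiguity.

Sex comparisons of lesion anatomy use Welch t-tests on per-region counts
and two-sided Fisher tests on affected/not-affected status,
Bonferroni-corrected within each 129-region family, plus a whole-brain
volume t-test.

## Pattern discovery

The patients × 129 matrix is factorized as `X ≈ W H`, W, H ≥ 0, k = 10,
by multiplicative updates under the Frobenius loss with NNDSVDa
initialization.  The solver normalizes its input by the matrix maximum
(making the fit exactly scale-invariant), asserts a non-increasing
objective at every iteration, and stops when the relative improvement
over a 10-iteration window drops below 1e-6 (or at 2000 iterations).
Basis rows are rescaled to max-loading 1 with the inverse scale absorbed
into W; a region is *affiliated* with a pattern when its normalized
loading exceeds 0.05, i.e. 5% of the pattern's peak loading.
Max-normalization is a documented default — L1 normalization can be
substituted by rescaling `PatternBasis.H` before thresholding.  Scoring
new patients against a fixed basis is row-wise non-negative least
squares.  Raw voxel counts enter unscaled: per-region standardization
would destroy the non-negativity and volume semantics the factorization
relies on.

## Outcome model

Unfavourable outcome is mRS > 2 at 3 months.  For patient i with sex
s(i):

    y_i ~ Bernoulli(logit⁻¹(α + Σ_j β_{j,s(i)} W_ij + γ·C_i))

* `W` — the 10 pattern expressions, z-scored on the fitting cohort.
* `C` — age (z-scored), age² (squared after centring, then z-scored),
  female indicator, six risk-factor indicators (hypertension, atrial
  fibrillation, diabetes, ischaemic heart disease, prior stroke,
  smoking), lesion volume (z-scored).
* Priors: µ_j ~ N(0,1), τ_j ~ HalfNormal(1), β_{j,s} = µ_j + τ_j z_{j,s}
  with z ~ N(0,1), α ~ N(0,2.5), γ ~ N(0,1).  These are
  weakly-informative defaults on standardized inputs; all scales are
  exposed in `PriorConfig`.  Sex deliberately enters twice: as a fixed
  covariate (main effect) and as the grouping level of the
  pattern-coefficient hierarchy.

Complete cases only; rows with missing fields are dropped with a logged
count.  Standardization parameters are stored and reusable; downsampled
refits restandardize on their own subsample (switchable).

### Sampling

The posterior is sampled with the No-U-Turn Sampler: slice-sampling tree
variant, dual-averaging step-size adaptation targeting 0.9 acceptance,
Stan-style windowed diagonal mass-matrix adaptation, Δ_max = 1000
divergence threshold, non-centered parameterization, analytic gradients.
Two implementations share the algorithm: a generic numpy reference
(`_nuts.py`) and a numba-compiled chain specialized to this model
(`_nuts_fast.py`, the default engine) — a test verifies they sample the
same posterior.  Defaults are 5000 draws and 4 chains with 1000 warm-up
iterations per chain (excluded); diagnostics (split-R̂, ESS via arviz,
divergence counts) are recorded, the fit fails loudly when split-R̂
exceeds 1.05, and a divergence rate above 5% is logged and flagged.  At
strongly reduced draw counts (≈500/chain) the rank-normalized split-R̂
estimator itself is noisy at the ±0.05 level; reduced-draw studies in the
test suite therefore pass an explicit threshold of 1.1.

### Inference

The 90% HPDI is the shortest window of ⌈0.9·n⌉ consecutive sorted draws,
ties resolved toward the lower window.  An effect is *substantial* when
its HPDI excludes zero.  Sex differences are per-draw β_male − β_female
(men − women), summarized by mean, 90% HPDI and the same rule.
Posterior-predictive AUC scores each patient by the posterior mean of
logit⁻¹(linear predictor) and computes the Mann–Whitney AUC with ties at
½; it is in-sample on the fitting cohort (no held-out split is modelled),
and a per-draw-AUC-averaging variant is available
(`method="mean_auc"`).  Baseline characteristics are compared by Welch
t-tests (continuous) and two-sided Fisher exact tests (binary).

### Downsampling sensitivity analysis

Per repetition, the majority sex's favourable-outcome patients are
sampled without replacement down to the minority sex's favourable count;
unfavourable patients and the whole minority sex are always kept; the
design is rebuilt and the model refit.  The NMF basis is *not* refit —
expressions are fixed from the full-cohort factorization and subset.
Each repetition derives an independent subsample and sampler seed from
(master seed, repetition); a fixed-fit-seed policy exists for determinism
checks.  The summary counts, per pattern, the repetitions whose
sex-difference HPDI excludes zero.

## Lesion network mapping

For each pattern, 100 variants draw a size m uniform on
{1..|affiliated|} and then m affiliated regions without replacement.  A
variant's seed mask is the union of its regions' atlas support.  Per
healthy subject: voxel series are demeaned, the global signal (mean over
nonzero-variance voxels) is regressed out (simple least squares), the
seed series is the mask mean, every voxel is Pearson-correlated with the
seed, r is clipped to ±0.999999 and Fisher z-transformed (constant voxels
get r = 0), and the group map is the one-sample t across subjects (voxels
with zero across-subject variance get t = 0, keeping maps finite).  A
batched implementation (one GEMM per subject over all 1000 variant seeds,
float32) is numerically verified against the per-variant routine.

Intensity is the signed *sum* of t within each of the 14
hemisphere-specific networks, per sign — the stricter reading of
summarizing t-values within networks; a per-voxel mean variant would be a
one-line change on the aggregation.  Contrasts are two-sided Welch
t-tests across the 100 variants (male-based vs female-based values),
BH-FDR corrected within each sign's 140-cell family (14 networks × 10
patterns; the two signs are corrected separately — a documented
interpretation), flags at adjusted p < 0.05.

## Synthetic data

The generator is the pipeline's testbed; its defaults encode the study
conditions the analysis is meant to face.

**Cohort.**  Pattern expressions are sparse gammas (shape 0.25, scale 100
voxels) so most patients load on one or two territories, mimicking
single-territory strokes; region counts are Poisson around `W_true @
H_true` with a territory basis of contiguous disjoint region blocks;
volume is the count sum (1 mm³ voxels).  The `paper_shape` preset fixes
n = 822, 39.2% women, per-sex age moments and risk-factor prevalences
from the published cohort table, and an intercept giving ≈ 28%
unfavourable outcomes.  Outcomes are Bernoulli draws from the same
linear predictor the model fits, with the sex-appropriate coefficients
applied to sample-standardized expressions — so `true_coefficients` are
on the per-SD scale the fitted model reports.  mRS is drawn consistently
with the binary outcome (uniform on 3–6 or 0–2).

**Masks and atlases.**  Fixture atlases are layer-disjoint, so
`generate_lesion_images` (first `count` voxels of each region's sorted
support) inverts parcellation exactly — the round trip is integer-exact.
Region blocks are assigned to labels in a strided ("scattered") order, so
one generator territory (consecutive labels) has support spread across
the grid; real vascular territories also cut across functional-network
boundaries.  An unscattered contiguous layout is available
(`scatter=False`).

**Connectomes.**  Each subject's voxel series stacks a global
physiological signal (amplitude 1), a within-network latent (amplitude
0.5), and unit i.i.d. noise.  The 14 network latents are orthogonalized
(QR) within each subject, so inter-network sample correlations vanish
identically instead of fluctuating at the 1/√T scale — with only 20
subjects per sex, those fluctuations would otherwise produce occasional
genuine sample-level network differences that the variant-level contrast
correctly, but unhelpfully, detects.  The female sex effect divides the
voxel noise of the target network's voxels by the effect size:
within-network coherence rises exactly as if the latent were amplified,
but the latent and global-signal loadings keep their male-law values, so
the global mean — and hence global signal regression — is sex-invariant
by construction.

This construction is the outcome of an explicit calibration analysis.
The variant-level sex-contrast t-test treats variants as independent
replicates, but all variants share the same 2 × 20 subjects, so any
systematic difference between the two normative samples is detected with
enough sensitivity; naive fixtures (shared full-amplitude latents, small
contiguous masks, short series) make the null test wildly
anti-conservative, and a planted effect leaks through the global-signal
estimate into every network.  Four properties of the final design matter
and are documented so users changing the fixture know what they are
trading away: (i) across-variant composition diversity (scattered
regions) supplies the honest variance term of the test; (ii) the
sex-invariant global mean prevents GSR from propagating a planted
coherence change into other networks; (iii) orthogonalized latents
remove chance inter-network sample differences between the two finite
normative samples; (iv) mask sizes of ~50 voxels and series of several
hundred timepoints keep the residual seed-norm artifact and finite-sample
t-map offsets below the detection threshold.  The
calibration studies in the test suite run at a 24×24×12 grid with 450
timepoints and 20 subjects per sex; the desk-scale default
(20×20×10, 150 timepoints) is for smoke use, and the study-scale
normative cohort size (346 per sex) is a named constant, not a default.

What the fixtures do *not* emulate: haemodynamics, spatial smoothness,
motion artefacts, inter-subject anatomical variability, and genuinely
overlapping vascular territories.  Passing tests therefore demonstrate
the pipeline's statistical machinery (calibration, recovery,
specificity), not performance on real resting-state data.

## Problem sizes in the test suite

The suite favours many moderate studies over few large ones: recovery
studies use n = 2000 patients with 2 chains × (500 warm-up + 1000 draws);
calibration uses 25 replicate fits at n = 1000 with 500 draws;
the LNM calibration runs 5 seeds per condition at 100 variants.
Simulation-based calibration draws the pattern coefficients from the
model's own prior, which makes 90% nominal coverage exact in expectation;
fixing all true coefficients at zero instead would measure ≈ 100%
coverage (hierarchical shrinkage pulls every interval onto zero), which
is a property of shrinkage, not a calibration failure.

## Known limitations

* The prior family is a documented default; the analysis it mirrors does
  not publish its full specification, so only the structure (sex-level
  hierarchy over pattern coefficients) is load-bearing.
* The AUC is in-sample; no cross-validated out-of-sample protocol is
  provided.
* The LNM contrast inherits the method's own limitation: variants are
  correlated replicates, so the test compares the two *realized*
  normative samples, and its calibration depends on the fixture
  properties listed above (and, with real data, on the normative sample
  size).
* Model-order selection for the factorization (k = 10) is fixed, not
  estimated.
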