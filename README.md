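# strokepatterns

Sex-specific lesion-pattern analysis of long-term stroke outcome.

After acute ischaemic stroke, women experience unfavourable 3-month
outcomes (modified Rankin Scale > 2) more often than men, and part of that
divergence may live in *where* the lesion sits rather than in demographics
or risk factors.  This package implements, as a tested and reusable
pipeline, an analysis framework for that question:

1. **Parcellation** — binary lesion masks on a common grid are reduced to
   lesioned-voxel counts in 129 atlas regions (94 cortical + 15
   subcortical + 20 white-matter tracts; the three label layers are
   independent, so a voxel may count toward a cortical region and a
   tract).
2. **Lesion patterns** — non-negative matrix factorization (multiplicative
   updates, NNDSVDa initialization) compresses the patients × 129 count
   matrix into k = 10 archetypal lesion patterns
   `X ≈ W H`, with basis rows max-normalized so that the 0.05
   region-affiliation threshold reads as "≥ 5% of the pattern's peak
   loading".
3. **Outcome model** — Bayesian hierarchical logistic regression

       y_i ~ Bernoulli(logit⁻¹(α + Σ_j β_{j,sex(i)} W_ij + γ·C_i))
       β_{j,s} = µ_j + τ_j z_{j,s},   µ_j ~ N(0,1),  τ_j ~ HalfNormal(1),
       z_{j,s} ~ N(0,1),  α ~ N(0,2.5),  γ ~ N(0,1)

   with covariates age, age², sex, six cardiovascular risk factors and
   lesion volume.  Sampling is NUTS (written here with analytic
   gradients; a numba-compiled chain makes repeated fits fast).  Effects
   are "substantial" when the 90% highest posterior density interval
   (HPDI) excludes zero; sex differences are the men − women posterior
   difference per pattern.  Model performance is the posterior-predictive
   AUC.
4. **Sensitivity** — the majority sex's favourable-outcome group is
   repeatedly downsampled to the minority's size and the model refit,
   tallying how often each sex difference survives.
5. **Lesion network mapping (LNM)** — each pattern is perturbed into 100
   variants (random subsets of its affiliated regions); every variant
   seeds a whole-brain connectivity t-map in male-only and female-only
   normative resting-state cohorts (global signal regression, Fisher z,
   one-sample t).  Signed t-sums ("intensity") within 14
   hemisphere-specific cortical networks are compared between the
   male- and female-based maps (Welch t-tests, Benjamini–Hochberg FDR over
   the 140-cell family per sign).

No patient data ship with the package.  The `synthetic` module generates
every input with known ground truth — territory-structured lesion
matrices, cohort tables whose outcomes come from a known sex-specific
logistic model, layer-disjoint label atlases whose masks round-trip
exactly, and sex-specific connectome fixtures with controllable
per-network coherence differences — so the entire pipeline is testable
offline.

## Worked example

```python
import numpy as np
from strokepatterns import (paper_shape_config, generate_cohort,
                            fit_nmf, build_design,
                            fit_hierarchical_logistic, sex_difference,
                            posterior_predictive_auc)
from strokepatterns.parcellation import region_columns

# synthetic cohort in the published cohort's shape, with one planted
# female-specific pattern effect (0.8 log-odds per SD of expression)
truth = np.zeros((2, 10)); truth[1, 2] = 0.8
cfg = paper_shape_config(seed=1, n_patients=2000, true_coefficients=truth)
lesion, expressions, cohort = generate_cohort(cfg)

design = build_design(cohort, expressions)
post = fit_hierarchical_logistic(design, draws=1000, warmup=600,
                                 chains=2, seed=7)
d = sex_difference(post, 3)
print(f"pattern #3 men-women difference: {d.mean:+.3f} "
      f"90% HPDI [{d.interval.lower:+.3f}, {d.interval.upper:+.3f}] "
      f"substantial={d.substantial}")
print(f"posterior-predictive AUC: "
      f"{posterior_predictive_auc(post, design):.3f}")
```

prints

```
pattern #3 men-women difference: -0.861 90% HPDI [-1.080, -0.609] substantial=True
posterior-predictive AUC: 0.720
```

The difference is negative (men − women) because the planted effect makes
lesions expressing pattern #3 more consequential in women; the HPDI
excludes zero, so the decision rule flags the sex difference, and the
model separates unfavourable from favourable outcomes with AUC ≈ 0.72 on
this synthetic cohort.

A command-line interface mirrors the library
(`strokepatterns simulate cohort`, `parcellate`, `patterns fit`, `fit`,
`sensitivity downsample`, `lnm run`, `pipeline run --config config.yaml`).

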