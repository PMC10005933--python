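# neurosubtypes

Semi-supervised subtype discovery for multimodal regional neuroimaging
cohorts, built for studies that ask: *within a clinical group (here,
pre-adolescents with mood and anxiety disorders), are there neurobiologically
distinct subtypes, defined by how each participant's brain deviates from a
typically developing reference group?*

Standard clustering groups patients by mutual similarity, which is dominated
by non-specific factors such as age, sex, and scanner. This package instead
implements heterogeneity-through-discriminative-analysis (HYDRA-style)
clustering: the clinical group is separated from the reference group by a
convex polytope of K max-margin hyperplanes,

```
min_{w,b,S}  Σ_j ½‖w_j‖² + C [ Σ_{i∈ref} Σ_j (1/K)·max(0, 1 + w_j·x_i + b_j)
                             + Σ_{i∈clin} Σ_j s_ij·max(0, 1 − w_j·x_i − b_j) ]
```

where every face must repel all reference participants but each clinical
participant only needs to be covered by the face it is assigned to
(`s_ij ∈ {0,1}`, one face per participant). The face assignment *is* the
subtype. K is chosen by clustering stability: 5-fold cross-validated
Adjusted Rand Index (ARI) over K = 2–7, with permutation tests (random
group shuffling, and pseudo-groups drawn from the reference pool alone)
supplying the significance of the selected solution.

Around this core the package provides:

- **`synthetic_cohort`** (`schema.py`, `cohort.py`) — a generator for
  multi-site, five-modality regional feature tables (cortical thickness,
  surface area, subcortical volume, neurite density, gray/white contrast on
  Desikan-Killiany / subcortical atlas regions) with age/sex/TIV covariate
  effects, site batch effects, and three planted deviation subtypes.
- **`harmonization.py`** — parametric empirical-Bayes location/scale
  (ComBat) removal of site effects, covariate-preserving, with a
  serializable fit/apply split.
- **`polytope.py`** — the alternating max-margin solver, covariate
  residualization against the reference group, and consensus clustering
  over restarts.
- **`stability.py`** — CV-ARI model selection and both permutation schemes.
- **`profiling.py`** — post-hoc mixed-model contrasts of every subtype
  against the reference for imaging and non-imaging measures, with
  Benjamini-Hochberg FDR at q = 0.005 and chi-squared diagnostic-composition
  tests.
- **`cli.py` / `pipeline.py`** — a `neurosubtypes` command with
  `simulate / harmonize / subtype / select-k / permtest / profile / run /
  validate` subcommands and a fully seeded, manifest-stamped pipeline.

## Worked example

```python
import numpy as np
import neurosubtypes as ns

schema = ns.default_schema(toy=True)            # 40 features for speed
spec = ns.CohortSpec(
    n_reference=300, n_clinical=300, n_sites=1,
    site_additive_sd=0.0, site_multiplicative_sd=0.0,
    effect_template=ns.subtype_effect_template(2.0), seed=42)
participants, features = ns.generate_cohort(spec, schema)

ref = (participants["group"] == "reference").to_numpy()
cov = ns.build_covariates(participants, reference_mask=ref)
resid, _ = ns.residualize(features, cov, ref)
X = resid.drop(columns="participant_id").to_numpy()
y = np.where(ref, -1, 1)

result = ns.select_k(X, y, k_min=2, k_max=7, n_folds=5,
                     fit_params={"n_init": 10}, seed=7)
print({k: round(v, 3) for k, v in result.mean_curve().items()})
print("selected K =", result.selected_k)
```

prints

```
{2: 0.888, 3: 0.988, 4: 0.77, 5: 0.798, 6: 0.639, 7: 0.638}
selected K = 3
```

The stability curve peaks sharply at the three planted subtypes: fold-models
at K = 3 re-assign the full clinical sample almost identically
(mean pairwise ARI 0.99), while K = 2 merges two subtypes inconsistently and
K ≥ 4 splits noise. A permutation test then quantifies the evidence:

```python
perm = ns.permutation_null_random_grouping(X, y, K=3, n_perm=49, seed=7)
print(round(perm.observed_ari, 2), round(max(perm.null_aris), 2),
      round(perm.p_value, 3))
```

```
0.6 0.15 0.02
```

The observed stability (0.60 under the cheaper permutation fit settings)
exceeds every one of the 49 label-shuffled null draws (max 0.15), giving the
smallest attainable add-one p-value, (1+0)/(49+1) = 0.02.

The same analysis end to end, from the shell:

```bash
neurosubtypes run --out results/demo --seed 42
```

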