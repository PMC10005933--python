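# Methods

## The clustering model

The package targets case-control cohorts in which the clinical group is
suspected to be heterogeneous. Each participant is represented by a vector
of regional neuroimaging features; clinical participants are clustered not
by mutual similarity but by *how they deviate* from a typically developing
reference group. K linear max-margin hyperplanes are fitted so that their
half-space intersection (a convex polytope) encloses the reference cloud;
each clinical participant must lie outside the face it is assigned to.
Faces therefore specialize toward different directions of deviation, and
the face assignment defines the subtypes. The objective is

    min_{w,b,S}  Σ_j ½‖w_j‖²
               + C [ Σ_{i∈ref} Σ_j (1/K) hinge(1 + w_j·x_i + b_j)
                   + Σ_{i∈clin} Σ_j s_ij  hinge(1 − w_j·x_i − b_j) ]

with hard one-hot assignments S. Reference participants pay the hinge on
every face (weight 1/K each); clinical participants pay it only on their
assigned face.

**Optimization.** Block coordinate descent: for fixed S, each face is an
independent weighted soft-margin linear SVM (solved with libsvm via
scikit-learn, tolerance 1e-6); for fixed hyperplanes, the optimal
assignment is the face of largest signed margin (ties break to the lowest
face index). Both steps are exact minimizations of the joint objective,
so the objective is non-increasing along the alternation; the trajectory
is recorded in the model metadata and asserted in the tests. Iteration
stops when the fraction of changed assignments drops to `tol` (default 0,
i.e. a fixed point) or after `max_iter` (default 50) rounds.

**Initialization and restarts.** Clinical displacement directions from the
reference centroid are unit-normalized and seeded k-means++-style; `n_init`
restarts (default 10) are run and the lowest final objective wins. The final
pipeline stage additionally builds a consensus partition: the co-assignment
frequency matrix across restart solutions is spectrally partitioned into
K groups, which removes the residual restart-to-restart label noise.

**Empty faces.** A face that loses all its clinical members is re-seeded
once from the worst-fitting clinical points (smallest maximum margin); if it
empties again it is dropped with a warning and the model continues with
K−1 active faces.

**Covariates and scaling.** Age, sex, and race/ethnicity (one-hot, largest
category as baseline) are removed by per-feature OLS fitted on the reference
group only and subtracted from everyone, so clinical deviations are
expressed relative to the covariate-expected reference value. Features are
then standardized to reference-group z-scores inside the solver. An
alternative design — augmenting the margin problem with covariate terms
instead of residualizing — would also be defensible; residualization was
chosen because it keeps the solver a pure geometry problem and makes the
adjustment reusable by the profiling stage.

## Model selection and significance

For each candidate K (2–7 by default), the clinical group is split into
5 folds; each fold-model is trained on all reference participants plus the
out-of-fold clinical participants and then labels the *entire* clinical
sample. Stability is the mean ARI over all C(5,2) fold-model pairs, and the
K with the highest mean wins (ties go to the smaller K). This
fit-on-complement / assign-everyone definition of cross-validated ARI is the
package's documented choice; the alternative (scoring only held-out members)
measures the same construct less directly because partitions over different
subsets are not comparable.

Two permutation nulls calibrate the selected solution, both using the
add-one estimator p = (1 + #{null ≥ observed}) / (n_perm + 1), which cannot
return 0:

- **random grouping** — reference/clinical labels are shuffled with group
  sizes preserved and the full CV-ARI pipeline is re-run; this destroys the
  case-control contrast that the polytope exploits.
- **reference only** — pseudo-clinical/pseudo-reference groups are drawn
  from the reference pool alone (pipeline default: pseudo-group sizes
  proportional to the real cohort), measuring the stability obtainable with
  no clinical group at all. Because this scheme never touches the clinical
  data, the observed statistic is supplied explicitly.

Inside permutation draws the solver runs with a reduced budget
(`n_init=3, max_iter=20, tol=0.02` versus 10/50/0 for model selection):
null fits never reach a stable fixed point and would otherwise burn the
whole iteration cap for no change in the conclusion. The observed statistic
is computed with the *same* reduced settings, so observed and null remain
exchangeable. On the default planted cohort the observed mean CV-ARI is
≈0.6 under these settings versus a null maximum of ≈0.15 — the distinction
does not depend on the optimization budget. Permutations default to 100;
the acceptance script uses 49 (p resolution 0.02), which keeps the full
sweep around ten minutes on one core.

## Site harmonization

Multi-site tables are harmonized before clustering with the parametric
empirical-Bayes location/scale model: per feature g and site i,
y = α_g + xβ_g + γ_ig + δ_ig ε. Site effects are estimated on data
standardized by the pooled residual SD, shrunk with a normal prior on γ and
an inverse-gamma prior on δ² (hyperpriors by method of moments across
features), and solved by iterated conditional modes (tolerance 1e-4,
≤100 iterations, variance floor 1e-12). Harmonized values are
(y − α − xβ − γ*)/δ* rescaled to the pooled SD and re-centered at α + xβ.
The implementation agrees with the Bioconductor `sva::ComBat` reference to
~1e-7 on a two-site fixture (checked in the test suite).

Design choices worth knowing:

- The harmonization design matrix includes age, sex, race/ethnicity **and
  the clinical/reference indicator** (toggle `harmonize_include_group`), so
  diagnosis-related variance is not mistaken for a site effect when group
  composition differs across sites.
- A single-site table is passed through unchanged (γ* = 0, δ* = 1): with
  one batch there is no between-site variation to model.
- Constant features are passed through with a logged warning; sites with
  fewer than two participants are refused (scale not estimable).
- Empirical-Bayes shrinkage has a known consequence: re-harmonizing
  already-harmonized data still nudges values by roughly half the sampling
  noise of the per-site means (~0.5/√n_site SD), because the moment
  estimator of the prior variance includes sampling noise. Harmonization is
  therefore *approximately* idempotent at the noise scale, not to machine
  precision, and the tests assert exactly that. Likewise, in-sample F-tests
  of site after harmonization are conservative by construction (the tested
  quantity is what was removed); the meaningful calibration check — applying
  a fitted model to held-out data from the same sites — rejects at the
  nominal rate, and is what the test suite verifies.

## Post-hoc profiling

Every (measure, subtype) pair is contrasted against the reference group
with a linear model adjusting for age, sex, and race/ethnicity; total
intracranial volume is added for surface-area, subcortical-volume, and
neurite-density features (volume/area scaling), not for thickness or
gray/white contrast. When a grouping factor with ≥2 levels is supplied
(site by default; family is an option), a random intercept is fitted by
REML and the Wald z of the group coefficient is reported with a
normal-approximation p — adequate at these group sizes. If the REML
variance estimate collapses to the boundary (<1e-8 of the residual
variance), the model is exactly ordinary least squares, and the OLS
t and p (residual df) are returned instead.

Benjamini-Hochberg FDR is applied across the full (measure × subtype)
family at q = 0.005; the family is pooled per analysis run (a per-modality
option exists). Flags use the strict convention adjusted-p < q. Binary
non-imaging measures are contrasted as linear probability models so every
row carries a comparable mean-difference estimate; diagnostic composition
between two subtypes is tested with Pearson chi-squared (no continuity
correction) on the 4×2 category table, with empty categories dropped and
the df reduced accordingly.

## The synthetic cohort generator

The generator emulates the structure of a multi-site developmental imaging
study so every stage is testable without restricted data:

- **Schema.** 68 Desikan-Killiany cortical parcels (thickness, surface
  area, gray/white contrast), 14 subcortical regions (volume), and neurite
  density on all 82 — 300 features; a 40-feature toy schema (8 cortical +
  4 subcortical regions) for tests and examples.
- **Participants.** Age uniform over 108–131 months; sex Bernoulli(1/2);
  race/ethnicity over five levels (52/14/22/3/9%); TIV normal
  (1.4e6 ± 1.2e5, +1e5 for males); sites uniform; one participant per
  family by default with an optional sibling-pair fraction. Clinical
  diagnoses (depressive / bipolar / anxiety / comorbid) are drawn
  per subtype from a mixture whose marginal follows the 178:307:1197:249
  composition, with subtype 3 tilted toward bipolar and away from anxiety.
- **Features.** Gaussian baseline per feature (modality-typical means/SDs)
  plus, in reference-SD units: age slope 0.008/month, male offset 0.15,
  TIV slope 0.2/SD on volume/area-like modalities, the planted subtype
  effect, an additive site effect N(0, 0.2²), and residual noise scaled by
  a log-normal site factor (exp N(0, 0.1²)) — exactly the location/scale
  structure the harmonization model assumes.
- **Subtype template.** Three deviation profiles at base magnitude
  d = 0.5·strength: (1) larger amygdala/striatal/thalamic volumes, globally
  larger surface area, thinner/more myelinated dorsal-prefrontal cortex,
  neurite density untouched; (2) globally thicker cortex, globally smaller
  surface area and lower myelin, lower neurite density in ventromedial
  prefrontal/parietal/occipital cortex; (3) thinner posterior cortex,
  globally smaller surface area and subcortical volumes, globally higher
  myelin and neurite density. Only signs and region groupings are
  specified; per-region magnitudes are uniform within a region set because
  no finer ground truth is available, and the default d = 0.5 gives
  recoverable but non-trivial separation. The named region sets
  (dorsal-prefrontal, ventromedial-prefrontal/parietal/occipital,
  posterior, amygdala/striatum/thalamus) are fixed, hemisphere-symmetric
  groupings of standard atlas names.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: spatially correlated residuals between
neighboring regions and across modalities, non-Gaussian tails, missing
data, scanner software upgrades within site, family clustering beyond a
shared random intercept, and diagnosis-feature dependence beyond the
subtype labels. Recovery results on synthetic cohorts are a correctness
check of the machinery, not an effect-size claim about any real cohort.

## Default problem sizes

Tests and the acceptance script run the toy schema at 300 reference + 300
clinical participants with strength-2 effects — large enough that planted
structure is recovered with high probability (ARI ≥ 0.8 in ≥90% of seeds;
the full suite verifies this over 20 seeds) yet small enough that the full
K-sweep plus a 49-draw permutation test completes in about ten minutes on
one core. The pipeline itself has no such limits; the full 300-feature
schema and larger cohorts only scale the SVM subproblems.

## Known limitations

- Linear faces only: a subtype defined by a nonlinear deviation surface
  will be approximated by several linear faces or missed.
- Hard assignments; no membership probabilities.
- The mixed-model p-values use the normal approximation for the Wald
  statistic (no Satterthwaite df correction).
- The alternating solver finds local optima; restarts and consensus
  mitigate but do not guarantee global optimality.
- Model selection by maximum mean CV-ARI ignores the SD across fold pairs;
  a one-SE-style rule could prefer smaller K in noisy regimes.
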