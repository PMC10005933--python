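"""Synthetic multi-site, multimodal cohort generator.

Emulates a developmental neuroimaging sample: a typically developing
reference group and a clinical group carrying planted subtypes, observed
through regional features with covariate (age, sex, TIV) effects, additive
and multiplicative site batch effects, and Gaussian residual noise.

The generative model for participant ``i``, feature ``g`` (site ``s(i)``,
subtype ``k(i)``, reference baseline mean ``mu_g`` and SD ``sigma_g``) is::

    y_ig = mu_g + sigma_g * ( beta_age * (age_i - 119.5)
                            + beta_sex * male_i
                            + beta_tiv * tivz_i          (TIV-scaled modalities)
                            + d_{k(i), g}                 (planted subtype shift)
                            + a_{s(i), g}                 (additive site effect)
                            + m_{s(i), g} * eps_ig ),     eps ~ N(0, 1)

with ``a ~ N(0, site_additive_sd^2)`` and ``m = exp(N(0, site_mult_sd^2))``
per (site, feature) — the location/scale structure the ComBat model assumes.
Effect sizes ``d`` are standardized (reference-SD units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema

AGE_RANGE_MONTHS = (108, 131)  # ages 9-10 years
AGE_CENTER = 119.5

DIAGNOSES = ("depressive", "bipolar", "anxiety", "comorbid")

#: Printed clinical group sizes (depressive, bipolar, anxiety-only, comorbid).
CLINICAL_GROUP_COUNTS = {
    "depressive": 178,
    "bipolar": 307,
    "anxiety": 1197,
    "comorbid": 249,
}

RACE_LEVELS = ("white", "black", "hispanic", "asian", "other")
RACE_PROPORTIONS = (0.52, 0.14, 0.22, 0.03, 0.09)

TIV_MEAN = 1.4e6     # mm^3-like units
TIV_SD = 1.2e5
TIV_SEX_SHIFT = 1.0e5  # added for males

#: Modalities whose features scale with intracranial volume.
TIV_SCALED_MODALITIES = ("CSA", "SV", "ND")


@dataclass(frozen=True)
class CovariateEffects:
    """Per-feature covariate slopes, in reference-SD units."""

    age_per_month: float = 0.008   # SD per month of age
    sex_offset: float = 0.15       # SD shift for males
    tiv_per_sd: float = 0.20       # SD per TIV-SD, TIV-scaled modalities only

    @classmethod
    def none(cls) -> "CovariateEffects":
        return cls(0.0, 0.0, 0.0)


class SubtypeEffectMap:
    """Map (subtype, modality, region-set) -> standardized effect size d.

    ``d`` is the shift of the subtype mean from the reference mean in
    reference-SD units; sign carries direction.  Region sets are named
    (``"global"`` or a schema region-set name) and resolved against a
    :class:`~neurosubtypes.schema.FeatureSchema` at generation time.
    """

    def __init__(self, effects: dict[tuple[int, str, str], float]):
        for (_, _, _), d in effects.items():
            if not math.isfinite(d):
                raise ValueError("effect sizes must be finite")
        self._effects = dict(effects)

    @property
    def n_subtypes(self) -> int:
        return max((k for k, _, _ in self._effects), default=0)

    def lookup(self, subtype: int, modality: str, set_name: str) -> float:
        """Effect size for an entry, 0.0 if absent."""
        return self._effects.get((subtype, modality, set_name), 0.0)

    def items(self):
        return self._effects.items()

    def per_feature(self, schema: FeatureSchema, n_subtypes: int) -> pd.DataFrame:
        """Resolve to an (n_subtypes x n_features) effect-size matrix."""
        feats = schema.feature_names()
        out = pd.DataFrame(0.0, index=range(1, n_subtypes + 1), columns=feats)
        for (k, mod, set_name), d in self._effects.items():
            if k > n_subtypes or mod not in schema.regions:
                continue
            for reg in schema.resolve_region_set(mod, set_name):
                out.loc[k, f"{mod}__{reg}"] += d
        return out

    def scaled(self, factor: float) -> "SubtypeEffectMap":
        return SubtypeEffectMap({k: d * factor for k, d in self._effects.items()})

    def to_dict(self) -> dict:
        return {f"{k}|{m}|{s}": d for (k, m, s), d in self._effects.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeEffectMap":
        eff = {}
        for key, v in d.items():
            k, m, s = key.split("|")
            eff[(int(k), m, s)] = float(v)
        return cls(eff)


def subtype_effect_template(strength: float = 1.0) -> SubtypeEffectMap:
    """Three-subtype deviation template at base magnitude ``d = 0.5 * strength``.

    Encodes the qualitative deviation profiles of three developmental
    subtypes relative to the typically developing reference:

    * subtype 1 — imbalanced cortical/subcortical maturation: larger
      amygdala/striatal/thalamic volumes, globally greater surface area,
      with thinner and more myelinated dorsal-prefrontal cortex; neurite
      density unaffected.
    * subtype 2 — delayed cortical maturation: globally thicker cortex,
      globally smaller surface area and lower myelin, lower neurite density
      in ventromedial-prefrontal/parietal/occipital cortex.
    * subtype 3 — atypical maturation: thinner posterior cortex, globally
      smaller surface area and subcortical volumes, globally higher myelin
      and neurite density.
    """
    if not strength > 0:
        raise ValueError("strength must be positive")
    d = 0.5 * strength
    return SubtypeEffectMap({
        (1, "SV", "amygdala_striatum_thalamus"): +d,
        (1, "CSA", "global"): +d,
        (1, "CT", "dorsal_prefrontal"): -d,
        (1, "GWC", "dorsal_prefrontal"): +d,
        (2, "CT", "global"): +d,
        (2, "CSA", "global"): -d,
        (2, "GWC", "global"): -d,
        (2, "ND", "vmpfc_parietal_occipital"): -d,
        (3, "CT", "posterior"): -d,
        (3, "CSA", "global"): -d,
        (3, "SV", "global"): -d,
        (3, "GWC", "global"): +d,
        (3, "ND", "global"): +d,
    })


def default_diagnosis_mixture() -> np.ndarray:
    """Per-subtype probabilities over the four diagnostic categories.

    Marginals follow the 178:307:1197:249 clinical composition; subtype 3
    is tilted toward bipolar and away from anxiety disorders.
    """
    return np.array([
        [0.095, 0.130, 0.655, 0.120],
        [0.095, 0.130, 0.655, 0.120],
        [0.085, 0.220, 0.550, 0.145],
    ])


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_reference: int = 300
    n_clinical: int = 300
    n_subtypes: int = 3
    subtype_proportions: tuple[float, ...] | None = None
    n_sites: int = 4
    site_additive_sd: float = 0.2
    site_multiplicative_sd: float = 0.1
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    effect_template: SubtypeEffectMap | None = None
    diagnosis_mixture: np.ndarray | None = None
    sibling_pair_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference < 0 or self.n_clinical < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.site_additive_sd < 0 or self.site_multiplicative_sd < 0:
            raise ValueError("site effect SDs must be nonnegative")
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple(
                1.0 / self.n_subtypes for _ in range(self.n_subtypes)
            )
        props = np.asarray(self.subtype_proportions, float)
        if len(props) != self.n_subtypes or np.any(props < 0) or \
                not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("subtype_proportions must be a simplex of length n_subtypes")
        if self.effect_template is None:
            self.effect_template = subtype_effect_template(1.0)
        if self.diagnosis_mixture is None:
            mix = default_diagnosis_mixture()
            if self.n_subtypes != mix.shape[0]:
                mix = np.tile(
                    np.array([c / 1931 for c in CLINICAL_GROUP_COUNTS.values()]),
                    (self.n_subtypes, 1),
                )
            self.diagnosis_mixture = mix
        mix = np.asarray(self.diagnosis_mixture, float)
        if mix.shape != (self.n_subtypes, len(DIAGNOSES)):
            raise ValueError("diagnosis_mixture must be (n_subtypes x 4)")
        if not np.allclose(mix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("diagnosis_mixture rows must sum to 1")
        if not 0 <= self.sibling_pair_fraction <= 1:
            raise ValueError("sibling_pair_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_effects"] = asdict(self.covariate_effects)
        d["effect_template"] = self.effect_template.to_dict()
        d["diagnosis_mixture"] = np.asarray(self.diagnosis_mixture).tolist()
        d["subtype_proportions"] = list(self.subtype_proportions)
        return d


def _draw_participants(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_reference + spec.n_clinical
    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    group = ["reference"] * spec.n_reference + ["clinical"] * spec.n_clinical

    subtype = np.full(n, np.nan)
    diagnosis = np.array(["none"] * n, dtype=object)
    if spec.n_clinical:
        ks = rng.choice(
            np.arange(1, spec.n_subtypes + 1), size=spec.n_clinical,
            p=np.asarray(spec.subtype_proportions, float),
        )
        subtype[spec.n_reference:] = ks
        mix = np.asarray(spec.diagnosis_mixture, float)
        for i, k in enumerate(ks):
            diagnosis[spec.n_reference + i] = rng.choice(DIAGNOSES, p=mix[k - 1])

    age = rng.integers(AGE_RANGE_MONTHS[0], AGE_RANGE_MONTHS[1] + 1, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROPORTIONS)
    site = rng.integers(0, spec.n_sites, size=n)
    tiv = rng.normal(TIV_MEAN, TIV_SD, size=n) + np.where(sex == "M", TIV_SEX_SHIFT, 0.0)

    family = [f"F{i:05d}" for i in range(1, n + 1)]
    if spec.sibling_pair_fraction > 0:
        n_pairs = int(spec.sibling_pair_fraction * n / 2)
        order = rng.permutation(n)
        for p in range(n_pairs):
            a, b = order[2 * p], order[2 * p + 1]
            family[b] = family[a]
            site[b] = site[a]

    return pd.DataFrame({
        "participant_id": ids,
        "group": group,
        "true_subtype": subtype,
        "diagnosis": diagnosis,
        "age_months": age,
        "sex": sex,
        "race_ethnicity": race,
        "site": [f"site{s + 1:02d}" for s in site],
        "family_id": family,
        "tiv": tiv,
    })


def generate_cohort(
    spec: CohortSpec, schema: FeatureSchema | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a (ParticipantTable, FeatureTable) pair.

    Deterministic given ``(spec, schema)``: the same spec (including its
    ``seed``) reproduces both tables bit-identically.
    """
    if schema is None:
        schema = default_schema()
    rng = np.random.default_rng(spec.seed)
    part = _draw_participants(spec, rng)
    n = len(part)
    feats = schema.feature_names()
    p = len(feats)

    mu = np.array([schema.baseline_mean[f] for f in feats])
    sigma = np.array([schema.baseline_sd[f] for f in feats])
    mods = np.array([schema.modality_of(f) for f in feats])

    ce = spec.covariate_effects
    std = np.zeros((n, p))
    std += ce.age_per_month * (part["age_months"].to_numpy() - AGE_CENTER)[:, None]
    std += ce.sex_offset * (part["sex"].to_numpy() == "M")[:, None].astype(float)
    tivz = ((part["tiv"].to_numpy() - TIV_MEAN) / TIV_SD)[:, None]
    std += ce.tiv_per_sd * tivz * np.isin(mods, TIV_SCALED_MODALITIES)[None, :]

    if spec.n_clinical:
        eff = spec.effect_template.per_feature(schema, spec.n_subtypes).to_numpy()
        ks = part["true_subtype"].to_numpy()
        clin = ~np.isnan(ks)
        std[clin] += eff[ks[clin].astype(int) - 1]

    sites = part["site"].to_numpy()
    site_levels = [f"site{s + 1:02d}" for s in range(spec.n_sites)]
    add = rng.normal(0.0, 1.0, size=(spec.n_sites, p)) * spec.site_additive_sd
    mult = np.exp(rng.normal(0.0, 1.0, size=(spec.n_sites, p)) * spec.site_multiplicative_sd)
    site_idx = np.array([site_levels.index(s) for s in sites])
    eps = rng.standard_normal((n, p))
    std += add[site_idx] + mult[site_idx] * eps

    values = mu[None, :] + sigma[None, :] * std
    features = pd.DataFrame(values, columns=feats)
    features.insert(0, "participant_id", part["participant_id"].to_numpy())
    return part, features
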