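"""Feature schemas: modalities, atlas regions, baselines and named region sets.

Five modalities of regional measures are modelled:

* ``CT``  -- cortical thickness (FreeSurfer, Desikan-Killiany parcels)
* ``CSA`` -- cortical surface area (same parcels)
* ``SV``  -- subcortical volume (Fischl probabilistic atlas regions)
* ``ND``  -- neurite density from restriction spectrum imaging, defined on
  both the cortical parcels and the subcortical regions
* ``GWC`` -- gray/white-matter contrast, an intracortical myelin proxy,
  on the cortical parcels

Feature columns are named ``<MODALITY>__<region>``.  The default schema uses
the 68 Desikan-Killiany cortical parcels (34 per hemisphere, ``lh_``/``rh_``
prefixes) and 14 bilateral subcortical regions; a reduced "toy" schema
(8 cortical + 4 subcortical regions, 40 features) keeps simulations and
tests fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MODALITIES = ("CT", "CSA", "SV", "ND", "GWC")

CORTICAL_MODALITIES = ("CT", "CSA", "GWC")  # strictly cortical
SUBCORTICAL_MODALITIES = ("SV",)            # strictly subcortical
# ND spans cortex and subcortex.

#: 34 Desikan-Killiany cortical parcel names (one hemisphere).
DESIKAN_KILLIANY_34 = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

#: Seven bilateral subcortical structures (Fischl probabilistic atlas).
SUBCORTICAL_7 = (
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus",
    "amygdala", "accumbens",
)

# Base-name membership of the named region sets used by effect templates.
# Hemisphere prefixes are ignored when resolving membership.
_DORSAL_PREFRONTAL = (
    "superiorfrontal", "rostralmiddlefrontal", "caudalmiddlefrontal",
    "frontalpole",
)
_VMPFC_PARIETAL_OCCIPITAL = (
    "medialorbitofrontal", "rostralanteriorcingulate",
    "superiorparietal", "inferiorparietal", "supramarginal", "precuneus",
    "cuneus", "lateraloccipital", "lingual", "pericalcarine",
)
_POSTERIOR = (
    "superiorparietal", "inferiorparietal", "supramarginal", "precuneus",
    "postcentral", "paracentral", "posteriorcingulate", "isthmuscingulate",
    "cuneus", "lateraloccipital", "lingual", "pericalcarine",
)
_AMYGDALA_STRIATUM_THALAMUS = (
    "amygdala", "caudate", "putamen", "accumbens", "thalamus",
)

REGION_SET_BASENAMES: dict[str, tuple[str, ...]] = {
    "dorsal_prefrontal": _DORSAL_PREFRONTAL,
    "vmpfc_parietal_occipital": _VMPFC_PARIETAL_OCCIPITAL,
    "posterior": _POSTERIOR,
    "amygdala_striatum_thalamus": _AMYGDALA_STRIATUM_THALAMUS,
}

# Modality-typical baselines (arbitrary units resembling mm, mm^2, mm^3,
# restricted fraction, and intensity ratio respectively).
_BASELINES = {
    "CT": (2.7, 0.15),
    "CSA": (2500.0, 400.0),
    "SV": (4000.0, 600.0),
    "ND": (0.60, 0.05),
    "GWC": (0.20, 0.03),
}


def region_basename(region: str) -> str:
    """Strip a leading hemisphere prefix (``lh_`` / ``rh_``) if present."""
    if region.startswith(("lh_", "rh_")):
        return region[3:]
    return region


@dataclass(frozen=True)
class FeatureSchema:
    """Modalities, their ordered region lists, and per-feature baselines."""

    name: str
    regions: dict[str, tuple[str, ...]]  # modality -> region names
    baseline_mean: dict[str, float] = field(default_factory=dict)  # feature -> mean
    baseline_sd: dict[str, float] = field(default_factory=dict)    # feature -> sd

    def __post_init__(self) -> None:
        for mod in self.regions:
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality code {mod!r}")
        for mod, regs in self.regions.items():
            if len(set(regs)) != len(regs):
                raise ValueError(f"duplicate region names in modality {mod}")
        ct = self.regions.get("CT", ())
        for mod in ("CSA", "GWC"):
            if mod in self.regions and tuple(self.regions[mod]) != tuple(ct):
                raise ValueError(f"{mod} must share the CT cortical region list")
        sv = set(self.regions.get("SV", ()))
        if sv & set(ct):
            raise ValueError("SV regions must be disjoint from cortical regions")
        if not self.baseline_mean:
            mean, sd = {}, {}
            for feat in self.feature_names():
                mod = feat.split("__", 1)[0]
                mean[feat], sd[feat] = _BASELINES[mod]
            object.__setattr__(self, "baseline_mean", mean)
            object.__setattr__(self, "baseline_sd", sd)
        for feat in self.feature_names():
            if not self.baseline_sd.get(feat, 0.0) > 0:
                raise ValueError(f"feature {feat} needs a positive baseline_sd")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def feature_names(self) -> list[str]:
        """Ordered ``MOD__region`` column names across all modalities."""
        return [f"{mod}__{reg}" for mod in self.regions for reg in self.regions[mod]]

    @property
    def n_features(self) -> int:
        return sum(len(r) for r in self.regions.values())

    def modality_of(self, feature: str) -> str:
        return feature.split("__", 1)[0]

    def resolve_region_set(self, modality: str, set_name: str) -> list[str]:
        """Regions of ``modality`` belonging to a named set (``"global"`` = all)."""
        regs = self.regions[modality]
        if set_name == "global":
            return list(regs)
        try:
            basenames = set(REGION_SET_BASENAMES[set_name])
        except KeyError:
            raise KeyError(f"unknown region set {set_name!r}") from None
        return [r for r in regs if region_basename(r) in basenames]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "regions": {m: list(r) for m, r in self.regions.items()},
            "baseline_mean": dict(self.baseline_mean),
            "baseline_sd": dict(self.baseline_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            name=d["name"],
            regions={m: tuple(r) for m, r in d["regions"].items()},
            baseline_mean=dict(d.get("baseline_mean", {})),
            baseline_sd=dict(d.get("baseline_sd", {})),
        )


def _bilateral(names: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(f"{h}_{n}" for h in ("lh", "rh") for n in names)


def default_schema(toy: bool = False) -> FeatureSchema:
    """The packaged atlas schema.

    The full schema has 68 Desikan-Killiany cortical parcels for CT/CSA/GWC,
    14 subcortical regions for SV, and ND on all 82 (300 features total).
    ``toy=True`` returns the reduced test schema: 8 cortical + 4 subcortical
    regions, 40 features.
    """
    if toy:
        cortical = (
            "superiorfrontal", "rostralmiddlefrontal", "medialorbitofrontal",
            "precentral", "superiorparietal", "inferiorparietal",
            "lateraloccipital", "superiortemporal",
        )
        subcortical = ("thalamus", "caudate", "putamen", "amygdala")
        name = "toy"
    else:
        cortical = _bilateral(DESIKAN_KILLIANY_34)
        subcortical = _bilateral(SUBCORTICAL_7)
        name = "default"
    return FeatureSchema(
        name=name,
        regions={
            "CT": cortical,
            "CSA": cortical,
            "SV": subcortical,
            "ND": cortical + subcortical,
            "GWC": cortical,
        },
    )
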