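"""End-to-end orchestration: simulate/load -> harmonize -> residualize ->
model selection -> final polytope fit with consensus -> permutation tests ->
post-hoc profiling, with a reproducibility manifest.

Every random stage derives its seed from the single config seed through
``numpy.random.SeedSequence``, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, generate_cohort, subtype_effect_template
from .design import build_covariates
from .harmonization import apply_combat, fit_combat
from .io import (read_tables, validate_tables, write_comparison_table,
                 write_labels, write_tables)
from .polytope import consensus_assign, fit_polytope, residualize
from .profiling import profile_neuroimaging
from .schema import default_schema
from .stability import (permutation_null_random_grouping,
                        permutation_null_reference_only, select_k)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    participants_path: str | None = None
    features_path: str | None = None
    simulate: bool = False
    toy_schema: bool = False
    n_reference: int = 300
    n_clinical: int = 300
    effect_strength: float = 1.0
    n_sites: int = 4
    site_additive_sd: float = 0.2
    site_multiplicative_sd: float = 0.1
    harmonize: bool = True
    harmonize_include_group: bool = True
    k_min: int = 2
    k_max: int = 7
    n_folds: int = 5
    C: float = 1.0
    n_init: int = 10
    n_perm: int = 100
    run_reference_only_null: bool = True
    q: float = 0.005
    seed: int = 0
    out_dir: str = "run_output"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns in-memory results and writes artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(c.generate_state(1)[0] % 2**31)
             for name, c in zip(
                 ["cohort", "select_k", "final_fit", "perm_rg", "perm_ref",
                  "consensus"], ss.spawn(6))}
    timings = {}

    t0 = _stage("load/simulate")
    schema = default_schema(toy=config.toy_schema)
    if config.simulate:
        spec = CohortSpec(
            n_reference=config.n_reference,
            n_clinical=config.n_clinical,
            n_sites=config.n_sites,
            site_additive_sd=config.site_additive_sd,
            site_multiplicative_sd=config.site_multiplicative_sd,
            effect_template=subtype_effect_template(config.effect_strength),
            seed=seeds["cohort"],
        )
        participants, features = generate_cohort(spec, schema)
        write_tables(participants, features, out, schema=schema, spec=spec)
    else:
        if not (config.participants_path and config.features_path):
            raise ValueError("either simulate=True or both input paths are required")
        participants, features = read_tables(config.participants_path,
                                             config.features_path)
    validate_tables(participants, features)
    if (participants["group"] == "clinical").sum() == 0:
        raise ValueError("no clinical participants: nothing to subtype")
    if (participants["group"] == "reference").sum() == 0:
        raise ValueError("no reference participants: no deviation baseline")
    timings["load"] = time.time() - t0

    t0 = _stage("harmonize")
    if config.harmonize and participants["site"].nunique() > 1:
        design = build_covariates(participants,
                                  include_group=config.harmonize_include_group)
        combat = fit_combat(features, participants["site"], design)
        features_h = apply_combat(combat, features, participants["site"], design)
        combat.to_json(out / "combat_model.json")
    else:
        features_h = features
    features_h.to_csv(out / "features_harmonized.csv", index=False,
                      float_format="%.17g")
    timings["harmonize"] = time.time() - t0

    t0 = _stage("residualize")
    ref_mask = (participants["group"] == "reference").to_numpy()
    covariates = build_covariates(participants, reference_mask=ref_mask)
    features_r, _ = residualize(features_h, covariates, ref_mask)
    y = np.where(ref_mask, -1, 1)
    feat_cols = [c for c in features_r.columns if c != "participant_id"]
    X = features_r[feat_cols].to_numpy(float)
    timings["residualize"] = time.time() - t0

    t0 = _stage("select_k")
    fit_params = {"C": config.C, "n_init": config.n_init}
    stability = select_k(X, y, k_min=config.k_min, k_max=config.k_max,
                         n_folds=config.n_folds, fit_params=fit_params,
                         seed=seeds["select_k"])
    stability.to_json(out / "stability.json")
    k_star = stability.selected_k
    timings["select_k"] = time.time() - t0

    t0 = _stage("final_fit")
    model, _ = fit_polytope(X, y, k_star, C=config.C, n_init=config.n_init,
                            seed=seeds["final_fit"])
    restart_labels = model.metadata.get("restart_labels", [])
    labels_arr = consensus_assign([np.asarray(v) for v in restart_labels],
                                  n_clusters=model.n_active,
                                  seed=seeds["consensus"]) + 1
    clin_ids = participants.loc[~ref_mask, "participant_id"]
    labels = pd.Series(labels_arr, index=clin_ids, name="subtype")
    model.metadata.pop("restart_labels", None)
    model.to_json(out / "polytope_model.json")
    write_labels(labels, out / "subtype_labels.tsv")
    timings["final_fit"] = time.time() - t0

    t0 = _stage("permutation_tests")
    perm_rg = permutation_null_random_grouping(
        X, y, k_star, n_perm=config.n_perm, n_folds=config.n_folds,
        fit_params=fit_params, seed=seeds["perm_rg"])
    perm_rg.to_json(out / "permutation_random_grouping.json")
    perm_ref = None
    if config.run_reference_only_null:
        n_ref = int(ref_mask.sum())
        n_clin = int((~ref_mask).sum())
        n_pc = max(config.n_folds, round(n_ref * n_clin / (n_ref + n_clin)))
        perm_ref = permutation_null_reference_only(
            X[ref_mask], k_star, (n_pc, n_ref - n_pc),
            observed_ari=perm_rg.observed_ari, n_perm=config.n_perm,
            n_folds=config.n_folds, fit_params=fit_params,
            seed=seeds["perm_ref"])
        perm_ref.to_json(out / "permutation_reference_only.json")
    timings["permutations"] = time.time() - t0

    t0 = _stage("profiling")
    comparisons = profile_neuroimaging(features_h, participants, labels,
                                       q=config.q)
    write_comparison_table(comparisons, out / "comparisons_neuroimaging.tsv")
    n_sig = comparisons.groupby(["domain", "subtype"])["significant"].sum()
    summary = {
        "selected_k": k_star,
        "mean_ari_curve": stability.mean_curve(),
        "p_random_grouping": perm_rg.p_value,
        "p_reference_only": perm_ref.p_value if perm_ref else None,
        "subtype_sizes": labels.value_counts().sort_index().to_dict(),
        "n_significant": {f"{d}|{s}": int(v) for (d, s), v in n_sig.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    timings["profiling"] = time.time() - t0

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "derived_seeds": seeds,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "participants": participants,
        "features_harmonized": features_h,
        "stability": stability,
        "model": model,
        "labels": labels,
        "permutation_random_grouping": perm_rg,
        "permutation_reference_only": perm_ref,
        "comparisons": comparisons,
        "summary": summary,
    }
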