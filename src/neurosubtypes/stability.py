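"""Stability-based model selection and permutation significance testing.

The number of subtypes K is chosen by cross-validated clustering
stability: for each candidate K, the polytope is refitted on the
reference group plus four fifths of the clinical group, each fold-model
re-assigns the *entire* clinical sample, and the adjusted Rand index
(ARI) between every pair of fold assignments measures how reproducible
the partition is.  The K with the highest mean pairwise ARI wins (ties go
to the smaller, more parsimonious K).

Two permutation schemes give the stability score a null distribution:

* ``random_grouping`` — reference/clinical labels are shuffled with group
  sizes preserved, destroying the clinical/reference contrast.
* ``reference_only`` — pseudo-clinical groups are carved out of the
  reference pool alone, measuring the stability achievable with no
  clinical group at all.

Permutation p-values use the add-one estimator
``p = (1 + #{null >= observed}) / (n_perm + 1)``, which can never be 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import KFold

from .polytope import assign as polytope_assign
from .polytope import fit_polytope

logger = logging.getLogger(__name__)

#: Default fit parameters used inside cross-validation folds.
DEFAULT_FIT_PARAMS = {"C": 1.0, "n_init": 10, "max_iter": 50, "tol": 0.0}

#: Cheaper restart budget used inside permutation draws (documented choice;
#: identical parameters are applied to the observed statistic and every
#: null draw, so exchangeability is preserved).
PERM_FIT_PARAMS = {"C": 1.0, "n_init": 3, "max_iter": 20, "tol": 0.02}


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions (permutation model)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal lengths")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


@dataclass
class CvAriResult:
    """Pairwise fold-model agreement for one candidate K."""

    K: int
    pairwise_aris: list[float]
    mean_ari: float
    sd_ari: float
    fold_labels: list[list[int]] = field(default_factory=list, repr=False)


@dataclass
class StabilityResult:
    """CV-ARI curve over the K sweep and the selected K*."""

    k_values: list[int]
    per_k: dict[int, CvAriResult]
    selected_k: int

    def mean_curve(self) -> dict[int, float]:
        return {k: self.per_k[k].mean_ari for k in self.k_values}

    def to_json(self, path) -> None:
        payload = {
            "k_values": self.k_values,
            "selected_k": self.selected_k,
            "per_k": {
                str(k): {
                    "pairwise_aris": r.pairwise_aris,
                    "mean_ari": r.mean_ari,
                    "sd_ari": r.sd_ari,
                }
                for k, r in self.per_k.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class PermutationResult:
    """Observed statistic vs its permutation null."""

    observed_ari: float
    null_aris: list[float]
    p_value: float
    scheme: str
    seed: int | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _perm_p(observed: float, null: np.ndarray) -> float:
    return float((1 + int((null >= observed).sum())) / (len(null) + 1))


def cv_ari(
    X,
    y,
    K: int,
    n_folds: int = 5,
    fit_params: dict | None = None,
    seed: int | None = None,
) -> CvAriResult:
    """Mean pairwise ARI across fold-models at one K.

    Folds split the *clinical* rows only; every fold-model trains on all
    reference rows plus the out-of-fold clinical rows and then labels the
    full clinical sample.
    """
    X = np.asarray(X, float) if not hasattr(X, "to_numpy") else X.to_numpy(float)
    y = np.asarray(y)
    clin_idx = np.where(y == +1)[0]
    ref_idx = np.where(y == -1)[0]
    if len(clin_idx) < n_folds:
        raise ValueError("fewer clinical participants than folds")
    if len(ref_idx) == 0:
        raise ValueError("no reference participants")
    params = {**DEFAULT_FIT_PARAMS, **(fit_params or {})}

    ss = np.random.SeedSequence(seed)
    kf = KFold(n_splits=n_folds, shuffle=True,
               random_state=int(ss.generate_state(1)[0] % 2**31))
    fold_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_folds)]

    labels = []
    for f, (train_clin, _) in enumerate(kf.split(clin_idx)):
        train = np.concatenate([ref_idx, clin_idx[train_clin]])
        model, _ = fit_polytope(X[train], y[train], K, seed=fold_seeds[f], **params)
        labels.append(polytope_assign(model, X[clin_idx]))

    pairs = [
        adjusted_rand_index(labels[i], labels[j])
        for i in range(n_folds) for j in range(i + 1, n_folds)
    ]
    return CvAriResult(
        K=K,
        pairwise_aris=pairs,
        mean_ari=float(np.mean(pairs)),
        sd_ari=float(np.std(pairs, ddof=1)) if len(pairs) > 1 else 0.0,
        fold_labels=[lab.tolist() for lab in labels],
    )


def select_k(
    X,
    y,
    k_min: int = 2,
    k_max: int = 7,
    n_folds: int = 5,
    fit_params: dict | None = None,
    seed: int | None = None,
) -> StabilityResult:
    """Sweep K over [k_min, k_max] and pick the most stable solution."""
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    ss = np.random.SeedSequence(seed)
    per_k: dict[int, CvAriResult] = {}
    for K, child in zip(range(k_min, k_max + 1), ss.spawn(k_max - k_min + 1)):
        per_k[K] = cv_ari(X, y, K, n_folds=n_folds, fit_params=fit_params,
                          seed=int(child.generate_state(1)[0] % 2**31))
    best = max(per_k.values(), key=lambda r: (r.mean_ari, -r.K))
    ties = [k for k, r in per_k.items()
            if r.mean_ari == best.mean_ari and k != best.K]
    if ties:
        logger.info("mean-ARI tie between K=%s; choosing smaller K=%d",
                    sorted([best.K] + ties), best.K)
    return StabilityResult(list(per_k), per_k, best.K)


def permutation_null_random_grouping(
    X,
    y,
    K: int,
    n_perm: int = 100,
    n_folds: int = 5,
    fit_params: dict | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Stability null from shuffled reference/clinical labels.

    The observed statistic is the mean CV-ARI at K under the true labels;
    each permutation shuffles the group labels uniformly (sizes preserved)
    and recomputes it with identical settings.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y)
    params = {**PERM_FIT_PARAMS, **(fit_params or {})}
    ss = np.random.SeedSequence(seed)
    obs_seed, *perm_children = ss.spawn(n_perm + 1)
    observed = cv_ari(X, y, K, n_folds=n_folds, fit_params=params,
                      seed=int(obs_seed.generate_state(1)[0] % 2**31)).mean_ari
    null = np.empty(n_perm)
    for i, child in enumerate(perm_children):
        rng = np.random.default_rng(child)
        y_perm = rng.permutation(y)
        null[i] = cv_ari(X, y_perm, K, n_folds=n_folds, fit_params=params,
                         seed=int(rng.integers(2**31))).mean_ari
    return PermutationResult(
        observed_ari=observed,
        null_aris=null.tolist(),
        p_value=_perm_p(observed, null),
        scheme="random_grouping",
        seed=seed,
    )


def permutation_null_reference_only(
    X_reference,
    K: int,
    pseudo_sizes: tuple[int, int],
    observed_ari: float,
    n_perm: int = 100,
    n_folds: int = 5,
    fit_params: dict | None = None,
    seed: int | None = None,
) -> PermutationResult:
    """Stability null from pseudo-groups carved out of the reference pool.

    Each permutation partitions reference participants into a
    pseudo-clinical group of ``pseudo_sizes[0]`` and a pseudo-reference
    group of ``pseudo_sizes[1]`` members, then scores CV-ARI at K.  The
    real clinical solution's mean CV-ARI (``observed_ari``) is compared
    against this null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xr = (X_reference.to_numpy(float) if hasattr(X_reference, "to_numpy")
          else np.asarray(X_reference, float))
    n_pc, n_pr = pseudo_sizes
    if n_pc < 1 or n_pr < 1:
        raise ValueError("pseudo group sizes must be positive")
    if n_pc + n_pr > len(Xr):
        raise ValueError("pseudo group sizes exceed available reference participants")
    params = {**PERM_FIT_PARAMS, **(fit_params or {})}
    ss = np.random.SeedSequence(seed)
    null = np.empty(n_perm)
    for i, child in enumerate(ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(Xr))
        take = order[: n_pc + n_pr]
        y_pseudo = np.concatenate([np.ones(n_pc), -np.ones(n_pr)]).astype(int)
        null[i] = cv_ari(Xr[take], y_pseudo, K, n_folds=n_folds,
                         fit_params=params,
                         seed=int(rng.integers(2**31))).mean_ari
    return PermutationResult(
        observed_ari=float(observed_ari),
        null_aris=null.tolist(),
        p_value=_perm_p(observed_ari, null),
        scheme="reference_only",
        seed=seed,
    )
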