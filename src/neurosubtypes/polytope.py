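"""Semi-supervised convex-polytope (max-margin) subtype clustering.

The clinical group is separated from a reference group by K linear
max-margin hyperplanes whose half-space intersection forms a convex
polytope enclosing the reference cloud.  Every hyperplane must push all
reference participants to its negative side, while each clinical
participant needs only to be separated by the single face it is assigned
to — the faces therefore specialize, and the face assignment defines the
subtypes.  The joint problem ::

    min_{w, b, S}  sum_j 1/2 ||w_j||^2
                 + C [ sum_{i in ref}  sum_j (1/K) hinge(1 + w_j.x_i + b_j)
                     + sum_{i in clin} sum_j s_ij  hinge(1 - w_j.x_i - b_j) ]

(``S`` a one-hot assignment of clinical rows to faces) is solved by
alternating weighted soft-margin SVM fits for each face given ``S`` with
the assignment update ``s_ij = 1`` for the face of largest signed margin.
Both steps decrease the objective, so the alternation converges to a
local optimum; restarts plus consensus make the result stable.

Features are standardized to reference-group z-scores before fitting, and
covariate effects (age, sex, race/ethnicity) are removed beforehand with
:func:`residualize`, so the hyperplanes express deviation from the
covariate-expected reference pattern rather than demographic structure.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-12
SVM_TOL = 1e-6


def _hinge(z: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, z)


# ---------------------------------------------------------------------------
# covariate residualization


@dataclass
class CovariateAdjuster:
    """Reference-group OLS fit of features on covariates (with intercept)."""

    covariate_columns: list[str]
    feature_names: list[str]
    coef: np.ndarray  # (1 + n_covariates) x n_features, row 0 = intercept

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([
            np.ones(len(covariates)),
            covariates[self.covariate_columns].to_numpy(float),
        ])
        return Z @ self.coef


def _collinear_columns(Z: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(Z)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [names[i] for i in np.where(bad)[0]]


def residualize(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    reference_mask: np.ndarray,
) -> tuple[pd.DataFrame, CovariateAdjuster]:
    """Remove covariate effects learned from the reference group only.

    Per feature, an ordinary least-squares model (intercept + covariates)
    is fitted on reference participants and its prediction subtracted from
    *all* participants, so clinical deviations are expressed relative to
    the covariate-expected reference value.
    """
    reference_mask = np.asarray(reference_mask, bool)
    if not reference_mask.any():
        raise ValueError("reference_mask selects no participants")
    feat_cols = [c for c in features.columns if c != "participant_id"]
    Y = features[feat_cols].to_numpy(float)
    cov_cols = list(covariates.columns)
    Z = np.column_stack([np.ones(len(covariates)),
                         covariates.to_numpy(float)])
    Zr = Z[reference_mask]
    if np.linalg.matrix_rank(Zr) < Zr.shape[1]:
        bad = _collinear_columns(Zr, ["intercept"] + cov_cols)
        raise ValueError(f"collinear covariate columns on the reference subset: {bad}")
    coef, *_ = np.linalg.lstsq(Zr, Y[reference_mask], rcond=None)
    resid = Y - Z @ coef
    out = features.copy()
    out.loc[:, feat_cols] = resid
    return out, CovariateAdjuster(cov_cols, feat_cols, coef)


# ---------------------------------------------------------------------------
# polytope model


@dataclass
class PolytopeModel:
    """K max-margin faces in standardized feature space."""

    K: int
    weights: np.ndarray        # (K_active x p)
    offsets: np.ndarray        # (K_active,)
    C: float
    feature_names: list[str] | None
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_active(self) -> int:
        return self.weights.shape[0]

    def decision_values(self, X) -> np.ndarray:
        Xs = self._standardize(X)
        return Xs @ self.weights.T + self.offsets

    def _standardize(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = [c for c in X.columns if c != "participant_id"]
            if self.feature_names is not None and cols != self.feature_names:
                raise ValueError("feature columns do not match the fitted model")
            X = X[cols].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.standardize_mean.shape[0]:
            raise ValueError(
                f"expected {self.standardize_mean.shape[0]} feature columns, "
                f"got {X.shape[1]}"
            )
        return (X - self.standardize_mean) / self.standardize_sd

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "weights": self.weights.tolist(),
            "offsets": self.offsets.tolist(),
            "C": self.C,
            "feature_names": self.feature_names,
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "metadata": {
                k: v for k, v in self.metadata.items()
                if isinstance(v, (int, float, str, bool, list, type(None)))
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PolytopeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            K=d["K"],
            weights=np.array(d["weights"]),
            offsets=np.array(d["offsets"]),
            C=d["C"],
            feature_names=d["feature_names"],
            standardize_mean=np.array(d["standardize_mean"]),
            standardize_sd=np.array(d["standardize_sd"]),
            metadata=d.get("metadata", {}),
        )


def polytope_objective(model: PolytopeModel, X, y, S: np.ndarray) -> float:
    """Exact objective value for a model, data, and clinical assignment."""
    Xs = model._standardize(X)
    y = np.asarray(y)
    S = np.asarray(S, float)
    return _objective(model.weights, model.offsets,
                      Xs[y == -1], Xs[y == +1], S, model.C)


def _objective(W, b, Xr, Xc, S, C) -> float:
    K = W.shape[0]
    reg = 0.5 * float((W ** 2).sum())
    margins_r = Xr @ W.T + b          # want <= -1
    ref_loss = _hinge(1.0 + margins_r).sum() / K
    margins_c = Xc @ W.T + b          # want >= +1 on the assigned face
    clin_loss = float((S * _hinge(1.0 - margins_c)).sum())
    return reg + C * (ref_loss + clin_loss)


def _fit_face(Xr, Xc_j, C, K) -> tuple[np.ndarray, float]:
    """Weighted linear soft-margin fit for one face.

    Reference rows carry weight 1/K (shared across faces), the face's
    clinical rows weight 1.
    """
    X = np.vstack([Xr, Xc_j])
    y = np.concatenate([-np.ones(len(Xr)), np.ones(len(Xc_j))])
    w = np.concatenate([np.full(len(Xr), 1.0 / K), np.ones(len(Xc_j))])
    clf = SVC(kernel="linear", C=C, tol=SVM_TOL, shrinking=True)
    clf.fit(X, y, sample_weight=w)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _init_assignments(Xc: np.ndarray, ref_centroid: np.ndarray, K: int,
                      rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding on clinical displacement directions."""
    D = Xc - ref_centroid
    norms = np.linalg.norm(D, axis=1)
    norms[norms < SD_FLOOR] = 1.0
    U = D / norms[:, None]
    n = len(U)
    seeds = [int(rng.integers(n))]
    d2 = ((U - U[seeds[0]]) ** 2).sum(axis=1)
    for _ in range(1, min(K, n)):
        total = d2.sum()
        if total <= 0:
            seeds.append(int(rng.integers(n)))
        else:
            seeds.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, ((U - U[seeds[-1]]) ** 2).sum(axis=1))
    centers = U[seeds]
    assign = np.argmin(
        ((U[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    if len(seeds) < K:  # fewer points than faces
        assign = rng.integers(0, K, size=n)
    return assign


def _alternate(Xr, Xc, K, C, max_iter, tol, assign0):
    """One restart of the alternating minimization.

    Returns (W, b, assign, trajectory, n_iter, converged, dead_clusters).
    ``assign`` indexes the surviving faces 0..K_active-1.
    """
    n_clin = len(Xc)
    active = list(range(K))
    assign = assign0.copy()
    reseeded: set[int] = set()
    traj: list[float] = []
    converged = False
    n_iter = 0
    W = np.zeros((K, Xr.shape[1]))
    b = np.zeros(K)
    for n_iter in range(1, max_iter + 1):
        # empty-cluster policy: one re-seed from worst-fit points, then death
        while True:
            counts = np.bincount(assign, minlength=len(active))
            empties = [j for j in range(len(active)) if counts[j] == 0]
            if not empties:
                break
            j = empties[0]
            face_id = active[j]
            if face_id not in reseeded and len(active) > 1 and n_clin >= len(active):
                reseeded.add(face_id)
                if W.any():
                    margins = (Xc @ W.T + b).max(axis=1)
                else:
                    margins = -np.linalg.norm(Xc - Xr.mean(axis=0), axis=1)
                m = max(1, n_clin // (2 * len(active)))
                worst = np.argsort(margins)[:m]
                assign[worst] = j
            else:
                logger.warning("face %d died (empty cluster); continuing with %d faces",
                               face_id, len(active) - 1)
                del active[j]
                assign[assign > j] -= 1  # faces above j shift down
                W = np.delete(W, j, axis=0)
                b = np.delete(b, j)
                if len(active) == 1:
                    assign[:] = 0
        Ka = len(active)
        W = np.zeros((Ka, Xr.shape[1]))
        b = np.zeros(Ka)
        for j in range(Ka):
            W[j], b[j] = _fit_face(Xr, Xc[assign == j], C, Ka)
        S = np.eye(Ka)[assign]
        traj.append(_objective(W, b, Xr, Xc, S, C))
        margins = Xc @ W.T + b
        new_assign = np.argmax(margins, axis=1)  # ties -> lowest face index
        S_new = np.eye(Ka)[new_assign]
        traj.append(_objective(W, b, Xr, Xc, S_new, C))
        changed = (new_assign != assign).mean()
        assign = new_assign
        if changed <= tol:
            converged = True
            break
    return W, b, assign, traj, n_iter, converged, K - len(active)


def fit_polytope(
    X,
    y,
    K: int,
    C: float = 1.0,
    n_init: int = 10,
    max_iter: int = 50,
    tol: float = 0.0,
    seed: int | None = None,
) -> tuple[PolytopeModel, np.ndarray]:
    """Fit the K-face polytope separating clinical from reference rows.

    Parameters
    ----------
    X : (n x p) array or FeatureTable DataFrame.
    y : labels, -1 for reference and +1 for clinical rows.
    K : number of faces (candidate subtype count).
    C : soft-margin penalty.
    n_init : restarts; the restart with the lowest final objective wins.
    max_iter : cap on alternating iterations per restart.
    tol : stop when the changed-assignment fraction is <= tol.
    seed : RNG seed controlling initialization.

    Returns the fitted model and the (n_clinical x K_active) one-hot
    assignment matrix, rows ordered as the clinical rows of ``X``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not C > 0:
        raise ValueError("C must be positive")
    feature_names = None
    if isinstance(X, pd.DataFrame):
        feature_names = [c for c in X.columns if c != "participant_id"]
        X = X[feature_names].to_numpy(float)
    X = np.asarray(X, float)
    y = np.asarray(y)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("y must contain only -1 (reference) and +1 (clinical)")
    if (y == -1).sum() == 0 or (y == +1).sum() == 0:
        raise ValueError("both reference and clinical rows are required")

    mean = X[y == -1].mean(axis=0)
    sd = X[y == -1].std(axis=0)
    sd = np.where(sd < SD_FLOOR, 1.0, sd)
    Xs = (X - mean) / sd
    Xr, Xc = Xs[y == -1], Xs[y == +1]

    if np.allclose(Xs, Xs[0], atol=1e-12):
        warnings.warn("all participants identical; returning a single-face solution",
                      stacklevel=2)
        model = PolytopeModel(K, np.zeros((1, X.shape[1])), np.zeros(1), C,
                              feature_names, mean, sd,
                              {"degenerate": True, "n_active": 1})
        return model, np.ones((len(Xc), 1))

    ss = np.random.SeedSequence(seed)
    best = None
    restart_labels = []
    for child in ss.spawn(max(1, n_init)):
        rng = np.random.default_rng(child)
        assign0 = _init_assignments(Xc, np.zeros(X.shape[1]), K, rng)
        result = _alternate(Xr, Xc, K, C, max_iter, tol, assign0)
        restart_labels.append(result[2].copy())
        if best is None or result[3][-1] < best[3][-1]:
            best = result
    W, b, assign, traj, n_iter, converged, n_dead = best
    if n_dead:
        logger.warning("%d of %d faces died during fitting", n_dead, K)
    Ka = W.shape[0]
    model = PolytopeModel(
        K=K, weights=W, offsets=b, C=C, feature_names=feature_names,
        standardize_mean=mean, standardize_sd=sd,
        metadata={
            "objective_trajectory": traj,
            "n_iter": n_iter,
            "converged": bool(converged),
            "n_init": n_init,
            "seed": seed,
            "n_active": Ka,
            "dead_faces": n_dead,
            "restart_labels": [lab.tolist() for lab in restart_labels],
        },
    )
    S = np.eye(Ka)[assign]
    return model, S


def assign(model: PolytopeModel, X) -> np.ndarray:
    """Face labels (1-based) by largest signed margin; ties -> lowest face."""
    dv = model.decision_values(X)
    return np.argmax(dv, axis=1) + 1


def consensus_assign(label_vectors, n_clusters: int | None = None,
                     seed: int = 0) -> np.ndarray:
    """Consensus partition across restarts/folds via the co-assignment matrix.

    Builds the frequency matrix M_ij = fraction of input partitions placing
    items i and j in the same cluster and spectrally partitions it.  A
    single input vector is returned unchanged.
    """
    vectors = [np.asarray(v) for v in label_vectors]
    if not vectors:
        raise ValueError("need at least one label vector")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("label vectors must have equal lengths")
    if len(vectors) == 1:
        return vectors[0].copy()
    if n_clusters is None:
        n_clusters = max(len(np.unique(v)) for v in vectors)
    if n_clusters <= 1:
        return np.zeros(n, dtype=int)
    M = np.zeros((n, n))
    for v in vectors:
        M += (v[:, None] == v[None, :]).astype(float)
    M /= len(vectors)
    sc = SpectralClustering(
        n_clusters=n_clusters, affinity="precomputed",
        assign_labels="kmeans", random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sc.fit_predict(M)
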