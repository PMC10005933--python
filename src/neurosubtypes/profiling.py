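"""Post-hoc subtype profiling: group contrasts, FDR control, composition tests.

Each subtype is contrasted against the reference group measure by measure
with a linear model (optionally a random-intercept mixed model for site),
adjusting for age, sex and race/ethnicity — plus total intracranial volume
for volume- and area-like modalities (CSA, SV, ND).  Benjamini-Hochberg
FDR is applied across the full (measure x subtype) family at q = 0.005 by
default.  Diagnostic-composition differences between subtype pairs are
tested with Pearson chi-squared on the 4 x 2 category table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import DIAGNOSES, TIV_SCALED_MODALITIES
from .design import build_covariates

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.005

#: REML variance ratio below which the mixed model is collapsed to OLS.
RE_VARIANCE_COLLAPSE = 1e-8


def bh_fdr(pvalues, q: float = DEFAULT_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def chi2_sf(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if statistic < 0:
        raise ValueError("statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


@dataclass
class CompositionTest:
    """Chi-squared comparison of diagnostic composition between two subtypes."""

    table: pd.DataFrame  # categories x 2 subtype counts
    statistic: float
    df: int
    p_value: float


def composition_test(diagnosis_labels, subtype_labels, subtype_pair) -> CompositionTest:
    """Pearson chi-squared (no continuity correction) on the 4x2 diagnosis table.

    Categories empty in both subtypes are dropped with a logged df reduction.
    """
    diag = np.asarray(diagnosis_labels)
    sub = np.asarray(subtype_labels)
    if diag.shape != sub.shape:
        raise ValueError("label vectors must align")
    a, b = subtype_pair
    counts = pd.DataFrame(0, index=list(DIAGNOSES), columns=[a, b])
    for s in (a, b):
        vals, n = np.unique(diag[sub == s], return_counts=True)
        for v, c in zip(vals, n):
            if v not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis category {v!r}")
            counts.loc[v, s] = c
    nonempty = counts.sum(axis=1) > 0
    if (~nonempty).any():
        dropped = counts.index[~nonempty].tolist()
        logger.warning("empty diagnosis categories dropped (df reduced): %s", dropped)
    table = counts.loc[nonempty]
    stat, _, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return CompositionTest(table=table, statistic=float(stat), df=int(df),
                           p_value=chi2_sf(float(stat), int(df)))


def fit_group_contrast(outcome, group_indicator, covariates=None,
                       random_factor=None) -> tuple[float, float, float]:
    """Group coefficient, t statistic and two-sided p for one measure.

    Fits ``outcome ~ group + covariates`` with a single random intercept
    for ``random_factor`` (REML).  With no random factor, a single level,
    or a boundary (zero) variance estimate, the fit collapses exactly to
    ordinary least squares.
    """
    yv = np.asarray(outcome, float)
    g = np.asarray(group_indicator, float)
    if len(np.unique(g)) != 2:
        raise ValueError("group_indicator must have exactly two levels")
    for level in np.unique(g):
        if (g == level).sum() < 3:
            raise ValueError("fewer than 3 observations in a group")
    cols = {"group": g - g.min()}
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(float)
    Xd = pd.DataFrame(cols)
    X = sm.add_constant(Xd, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear covariates in the contrast design")

    groups = None
    if random_factor is not None:
        groups = np.asarray(random_factor)
        if len(pd.unique(groups)) < 2:
            groups = None

    if groups is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(yv, X, groups=groups).fit(reml=True)
        re_var = float(np.squeeze(fit.cov_re))
        if re_var > RE_VARIANCE_COLLAPSE * max(fit.scale, 1e-300):
            beta = float(fit.params["group"])
            t = float(fit.tvalues["group"])
            p = float(fit.pvalues["group"])  # Wald normal approximation
            return beta, t, p
        # boundary estimate: the GLS fit is OLS, report it exactly
    fit = sm.OLS(yv, X).fit()
    return (float(fit.params["group"]), float(fit.tvalues["group"]),
            float(fit.pvalues["group"]))


def _contrast_rows(measures: pd.DataFrame, participants: pd.DataFrame,
                   subtype_labels: pd.Series, tiv_rule, domain_of,
                   random_factor_col: str | None) -> list[dict]:
    ref_mask = (participants["group"] == "reference").to_numpy()
    labels = subtype_labels.reindex(participants["participant_id"])
    subtypes = sorted(int(s) for s in labels.dropna().unique())
    rows = []
    for measure in measures.columns:
        vals = measures[measure].to_numpy(float)
        if np.nanstd(vals) == 0:
            logger.warning("measure %s has zero variance; skipped", measure)
            continue
        needs_tiv = tiv_rule(measure)
        for s in subtypes:
            sub_mask = (labels == s).to_numpy()
            sel = ref_mask | sub_mask
            part = participants.loc[sel]
            cov = build_covariates(part, include_tiv=needs_tiv)
            rf = part[random_factor_col] if random_factor_col else None
            beta, t, p = fit_group_contrast(
                vals[sel], sub_mask[sel].astype(int),
                covariates=cov.reset_index(drop=True), random_factor=rf,
            )
            rows.append({
                "measure": measure,
                "domain": domain_of(measure),
                "subtype": s,
                "estimate": beta,
                "t_value": t,
                "p_raw": p,
                "n_reference": int(ref_mask.sum()),
                "n_subtype": int(sub_mask.sum()),
                "covariates": "+".join(cov.columns),
            })
    return rows


def _finish_table(rows: list[dict], q: float) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    if len(table):
        p_adj, flags = bh_fdr(table["p_raw"].to_numpy(), q)
        table["p_fdr"] = np.maximum(p_adj, table["p_raw"])
        table["significant"] = flags
    else:
        table = pd.DataFrame(columns=[
            "measure", "domain", "subtype", "estimate", "t_value", "p_raw",
            "n_reference", "n_subtype", "covariates", "p_fdr", "significant",
        ])
    return table


def profile_neuroimaging(features: pd.DataFrame, participants: pd.DataFrame,
                         subtype_labels: pd.Series, q: float = DEFAULT_Q,
                         random_factor: str | None = "site") -> pd.DataFrame:
    """ComparisonTable of every (feature, subtype) contrast vs reference.

    ``subtype_labels`` is a Series of subtype numbers indexed by
    participant_id, covering the clinical group.  TIV is added as a
    covariate for CSA, SV and ND features (volume/area scaling), not for
    CT or GWC.  BH-FDR is applied across the whole (feature x subtype)
    family.
    """
    feat_cols = [c for c in features.columns if c != "participant_id"]
    meas = features[feat_cols]
    if any(c.split("__")[0] in TIV_SCALED_MODALITIES for c in feat_cols) \
            and "tiv" not in participants.columns:
        raise ValueError("participants table lacks the TIV column required "
                         "for CSA/SV/ND contrasts")
    rf = random_factor if (random_factor and
                           participants[random_factor].nunique() > 1) else None
    rows = _contrast_rows(
        meas, participants, subtype_labels,
        tiv_rule=lambda m: m.split("__")[0] in TIV_SCALED_MODALITIES,
        domain_of=lambda m: m.split("__")[0],
        random_factor_col=rf,
    )
    return _finish_table(rows, q)


def profile_nonimaging(measures: pd.DataFrame, participants: pd.DataFrame,
                       subtype_labels: pd.Series, q: float = DEFAULT_Q,
                       random_factor: str | None = "site") -> pd.DataFrame:
    """ComparisonTable for non-imaging measures (no TIV adjustment).

    Binary measures are contrasted as linear probability models so every
    row carries a comparable mean-difference estimate.
    """
    meas = measures[[c for c in measures.columns if c != "participant_id"]]
    rf = random_factor if (random_factor and
                           participants[random_factor].nunique() > 1) else None
    rows = _contrast_rows(
        meas, participants, subtype_labels,
        tiv_rule=lambda m: False,
        domain_of=lambda m: "nonimaging",
        random_factor_col=rf,
    )
    return _finish_table(rows, q)
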