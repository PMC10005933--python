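"""Covariate design matrices built from a participant table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import AGE_CENTER


def build_covariates(
    participants: pd.DataFrame,
    include_tiv: bool = False,
    include_group: bool = False,
    reference_mask=None,
) -> pd.DataFrame:
    """Numeric covariate matrix: age (centered), sex, race one-hots, optional TIV.

    Race/ethnicity is one-hot encoded with the largest observed category as
    the baseline (dropped) level.  No intercept column is added.
    """
    out = pd.DataFrame(index=participants.index)
    out["age_c"] = participants["age_months"].astype(float) - AGE_CENTER
    out["sex_male"] = (participants["sex"] == "M").astype(float)
    race = participants["race_ethnicity"].astype(str)
    baseline = race.value_counts().idxmax()
    for level in sorted(race.unique()):
        if level != baseline:
            out[f"race_{level}"] = (race == level).astype(float)
    if include_tiv:
        tiv = participants["tiv"].astype(float)
        sd = tiv.std(ddof=1)
        out["tiv_z"] = (tiv - tiv.mean()) / (sd if sd > 0 else 1.0)
    if include_group:
        out["group_clinical"] = (participants["group"] == "clinical").astype(float)
    # drop zero-variance columns (e.g. single-sex samples); when a
    # reference mask is given, a column must also vary within the
    # reference subset, since residualization fits there only
    keep = [c for c in out.columns if np.nanstd(out[c].to_numpy()) > 0]
    if reference_mask is not None:
        mask = np.asarray(reference_mask, bool)
        keep = [c for c in keep if np.nanstd(out.loc[mask, c].to_numpy()) > 0]
    return out[keep]
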