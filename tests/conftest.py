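import numpy as np
import pytest

import neurosubtypes as ns


@pytest.fixture(scope="session")
def toy_schema():
    return ns.default_schema(toy=True)


def make_planted_cohort(seed=42, n=300, strength=2.0, toy=True):
    """Strength-scaled three-subtype cohort, single site (no batch effects)."""
    spec = ns.CohortSpec(
        n_reference=n, n_clinical=n, n_sites=1,
        site_additive_sd=0.0, site_multiplicative_sd=0.0,
        effect_template=ns.subtype_effect_template(strength), seed=seed,
    )
    return spec, ns.generate_cohort(spec, ns.default_schema(toy=toy))


def prepare_xy(participants, features):
    """Residualize covariates and return (X, y, true_subtype)."""
    cov = ns.build_covariates(participants)
    ref = (participants["group"] == "reference").to_numpy()
    resid, _ = ns.residualize(features, cov, ref)
    cols = [c for c in resid.columns if c != "participant_id"]
    X = resid[cols].to_numpy(float)
    y = np.where(ref, -1, 1)
    true = participants.loc[~ref, "true_subtype"].astype(int).to_numpy()
    return X, y, true


@pytest.fixture(scope="session")
def planted_cohort():
    """The session-wide strength-2 toy cohort (300 + 300, seed 42)."""
    spec, (part, feat) = make_planted_cohort()
    return spec, part, feat


@pytest.fixture(scope="session")
def planted_xy(planted_cohort):
    _, part, feat = planted_cohort
    return prepare_xy(part, feat)


@pytest.fixture(scope="session")
def two_blob_data():
    """Reference cloud at the origin, two clinical blobs on opposite sides."""
    rng = np.random.default_rng(7)
    Xr = rng.standard_normal((120, 5)) * 0.5
    Xa = rng.standard_normal((60, 5)) * 0.5 + np.array([6, 0, 0, 0, 0])
    Xb = rng.standard_normal((60, 5)) * 0.5 + np.array([-6, 0, 0, 0, 0])
    X = np.vstack([Xr, Xa, Xb])
    y = np.concatenate([-np.ones(120), np.ones(120)]).astype(int)
    blob = np.concatenate([np.zeros(60), np.ones(60)]).astype(int)
    return X, y, blob
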