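"""Group contrasts, FDR control, chi-squared composition tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

import neurosubtypes as ns
from conftest import make_planted_cohort


def bh_bruteforce(p, q):
    """Step-up rule: reject the k smallest p-values where k is the largest
    rank with p_(k) < k*q/m (strict threshold, matching the flag contract
    `adjusted p < q`)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] * m / rank < q:
            k_max = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


class TestBhFdr:
    def test_hand_worked_stepup(self):
        p = [0.001, 0.002, 0.003, 0.9]
        _, flags = ns.bh_fdr(p, q=0.005)
        assert flags.tolist() == [True, True, True, False]

    def test_all_equal_at_max_rank(self):
        _, flags = ns.bh_fdr([0.004] * 10, q=0.005)
        assert flags.all()

    def test_empty_input(self):
        adj, flags = ns.bh_fdr([], q=0.005)
        assert adj.size == 0 and flags.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ns.bh_fdr([0.5, 1.5], q=0.05)

    def test_adjusted_ge_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj, _ = ns.bh_fdr(p, q=0.05)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.floats(0.001, 0.2))
    def test_flags_match_bruteforce(self, p, q):
        _, flags = ns.bh_fdr(p, q=q)
        assert flags.tolist() == bh_bruteforce(p, q).tolist()

    def test_bruteforce_agreement_many_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            q = rng.uniform(0.001, 0.1)
            _, flags = ns.bh_fdr(p, q)
            assert np.array_equal(flags, bh_bruteforce(p, q))


class TestChi2Sf:
    @pytest.mark.parametrize("stat,df,printed,decimals", [
        (15.80, 3, 0.001, 3),
        (10.12, 3, 0.02, 2),
        (2.45, 3, 0.48, 2),
    ])
    def test_printed_composition_pvalues(self, stat, df, printed, decimals):
        assert round(ns.chi2_sf(stat, df), decimals) == printed

    @pytest.mark.parametrize("df", [1, 2, 3, 5, 10])
    def test_zero_statistic(self, df):
        assert ns.chi2_sf(0.0, df) == 1.0

    @pytest.mark.parametrize("df", range(1, 11))
    def test_agrees_with_numerical_integration(self, df):
        from math import gamma
        dens = lambda t: t ** (df / 2 - 1) * np.exp(-t / 2) / (
            2 ** (df / 2) * gamma(df / 2))
        for x in (0.5, 2.0, 10.0, 25.0, 50.0):
            numeric, _ = quad(dens, 0, x, limit=200)
            assert ns.chi2_sf(x, df) == pytest.approx(1 - numeric, abs=1e-6)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            ns.chi2_sf(-1.0, 3)
        with pytest.raises(ValueError):
            ns.chi2_sf(1.0, 0)


class TestCompositionTest:
    def _labels(self, counts_a, counts_b):
        diag, sub = [], []
        cats = ("depressive", "bipolar", "anxiety", "comorbid")
        for c, n in zip(cats, counts_a):
            diag += [c] * n
            sub += [1] * n
        for c, n in zip(cats, counts_b):
            diag += [c] * n
            sub += [2] * n
        return np.array(diag), np.array(sub)

    def test_identical_proportions_give_zero(self):
        diag, sub = self._labels([10, 20, 30, 5], [10, 20, 30, 5])
        res = ns.composition_test(diag, sub, (1, 2))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_expected_count_expansion(self):
        counts = np.array([[10, 20], [20, 10], [30, 30], [5, 5]], float)
        diag, sub = self._labels(counts[:, 0].astype(int),
                                 counts[:, 1].astype(int))
        res = ns.composition_test(diag, sub, (1, 2))
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        stat = ((counts - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(stat)
        assert res.df == 3

    def test_invariant_to_column_swap(self):
        diag, sub = self._labels([10, 20, 30, 5], [5, 25, 28, 9])
        r12 = ns.composition_test(diag, sub, (1, 2))
        r21 = ns.composition_test(diag, sub, (2, 1))
        assert r12.statistic == pytest.approx(r21.statistic)
        assert r12.p_value == pytest.approx(r21.p_value)

    def test_empty_category_dropped_with_df_reduction(self):
        diag, sub = self._labels([10, 20, 30, 0], [5, 25, 28, 0])
        res = ns.composition_test(diag, sub, (1, 2))
        assert res.df == 2
        assert len(res.table) == 3


class TestFitGroupContrast:
    def test_zero_variance_random_intercept_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 120
        site = np.repeat([f"s{i}" for i in range(4)], n // 4)
        g = rng.integers(0, 2, n)
        cov = pd.DataFrame({"age": rng.normal(0, 1, n)})
        yv = 0.5 * g + 0.3 * cov["age"].to_numpy() + rng.standard_normal(n)
        b, t, p = ns.fit_group_contrast(yv, g, cov, random_factor=site)
        X = sm.add_constant(pd.DataFrame({"group": g.astype(float),
                                          "age": cov["age"]}))
        f = sm.OLS(yv, X).fit()
        assert b == pytest.approx(f.params["group"], abs=1e-4)
        assert t == pytest.approx(f.tvalues["group"], abs=1e-4)

    def test_ols_t_matches_two_sample_t(self):
        """Without covariates, the regression t equals the pooled t-test."""
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 40)
        b_ = rng.normal(0.4, 1, 35)
        yv = np.concatenate([a, b_])
        g = np.concatenate([np.zeros(40), np.ones(35)])
        _, t, p = ns.fit_group_contrast(yv, g)
        t_ref, p_ref = stats.ttest_ind(b_, a, equal_var=True)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_type_i_error_near_nominal(self):
        """Null contrasts reject at ~alpha over 1000 simulated measures."""
        rng = np.random.default_rng(7)
        n = 100
        g = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            yv = rng.standard_normal(n)
            _, _, p = ns.fit_group_contrast(yv, g)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rejections / n_sim - 0.05) < 3 * se

    def test_planted_effect_recovered(self):
        """beta estimates for a unit effect land in (0.8, 1.2) almost always."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            yv = np.concatenate([rng.normal(0, 1, 500), rng.normal(1, 1, 500)])
            g = np.concatenate([np.zeros(500), np.ones(500)])
            b, _, _ = ns.fit_group_contrast(yv, g)
            hits += 0.8 < b < 1.2
        assert hits >= 95

    def test_mixed_model_recovers_effect_with_site_variance(self):
        rng = np.random.default_rng(8)
        n_sites, per_site = 8, 40
        site = np.repeat([f"s{i}" for i in range(n_sites)], per_site)
        site_eff = np.repeat(rng.normal(0, 0.8, n_sites), per_site)
        g = rng.integers(0, 2, n_sites * per_site)
        yv = 1.0 * g + site_eff + rng.standard_normal(n_sites * per_site)
        b, t, p = ns.fit_group_contrast(yv, g, random_factor=site)
        assert b == pytest.approx(1.0, abs=0.3)
        assert p < 1e-6

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="two levels"):
            ns.fit_group_contrast(np.ones(6), np.zeros(6))
        with pytest.raises(ValueError, match="fewer than 3"):
            ns.fit_group_contrast(np.arange(5.0),
                                  np.array([0, 0, 0, 0, 1]))


@pytest.fixture(scope="module")
def planted():
    _, (part, feat) = make_planted_cohort(seed=4, n=250, strength=2.0)
    labels = pd.Series(
        part.loc[part["group"] == "clinical", "true_subtype"].astype(int).to_numpy(),
        index=part.loc[part["group"] == "clinical", "participant_id"])
    return part, feat, labels


class TestProfiles:
    def test_subtype2_global_ct_flagged_positive(self, planted):
        part, feat, labels = planted
        table = ns.profile_neuroimaging(feat, part, labels, q=0.005)
        ct2 = table[(table["domain"] == "CT") & (table["subtype"] == 2)]
        assert len(ct2) == 8
        assert ct2["significant"].all()
        assert (ct2["t_value"] > 0).all()

    def test_tiv_covariate_rule(self, planted):
        part, feat, labels = planted
        table = ns.profile_neuroimaging(feat, part, labels, q=0.005)
        sv = table[table["domain"] == "SV"]
        ct = table[table["domain"] == "CT"]
        assert sv["covariates"].str.contains("tiv_z").all()
        assert not ct["covariates"].str.contains("tiv_z").any()

    def test_missing_tiv_rejected(self, planted):
        part, feat, labels = planted
        with pytest.raises(ValueError, match="TIV"):
            ns.profile_neuroimaging(feat, part.drop(columns="tiv"), labels)

    def test_null_cohort_rarely_flags(self):
        """With no planted effects, false flags at q=.005 stay at most 1."""
        good = 0
        for seed in range(10):
            spec = ns.CohortSpec(
                n_reference=150, n_clinical=150, n_sites=1,
                site_additive_sd=0, site_multiplicative_sd=0,
                effect_template=ns.SubtypeEffectMap({}), seed=seed)
            part, feat = ns.generate_cohort(spec, ns.default_schema(toy=True))
            labels = pd.Series(
                part.loc[part["group"] == "clinical", "true_subtype"]
                .astype(int).to_numpy(),
                index=part.loc[part["group"] == "clinical", "participant_id"])
            table = ns.profile_neuroimaging(feat, part, labels, q=0.005)
            good += table["significant"].sum() <= 1
        assert good >= 9

    def test_nonimaging_planted_elevation_flagged(self, planted):
        part, _, labels = planted
        rng = np.random.default_rng(0)
        clin = (part["group"] == "clinical").to_numpy()
        internalizing = rng.normal(43, 8, len(part)) + clin * 6
        measures = pd.DataFrame({
            "cbcl_internalizing": internalizing,
            "noise_measure": rng.standard_normal(len(part)),
        })
        table = ns.profile_nonimaging(measures, part, labels, q=0.005)
        flagged = table[table["measure"] == "cbcl_internalizing"]
        assert len(flagged) == 3  # one row per subtype
        assert flagged["significant"].all()
        assert (flagged["estimate"] > 0).all()

    def test_zero_variance_measure_skipped(self, planted):
        part, _, labels = planted
        measures = pd.DataFrame({"flat": np.ones(len(part))})
        table = ns.profile_nonimaging(measures, part, labels)
        assert len(table) == 0
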