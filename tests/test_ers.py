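import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from ersmix.ers import (
    compute_ers,
    continuous_association,
    covariate_design,
    hierarchical_refit,
    quintile_association,
    quintile_groups,
    sensitivity_refits,
    stratified_association,
)
from ersmix.expansion import expand, standardize
from ersmix.preprocess import log10_metals
from ersmix.simulate import METAL_PANEL

#: Refit-model coefficients of the emulated analysis (standardized log10 scale).
REFIT_COEFS = {"Ag": 0.174, "Sb": 0.128, "Sn": -0.149, "La": -0.026,
               "Ce": -0.058, "Sn^2": -0.173, "Ce^2": -0.065, "La:Ce": -0.437}

COVARIATES = ["age", "sex", "bmi", "income", "smoking", "alcohol",
              "physical_activity"]


def _model_with_coefs(termset, coefs: dict):
    """An ERSModel carrying prescribed term coefficients (no fitting)."""
    from ersmix.ers import ERSModel
    s = pd.Series(coefs, dtype=float)
    return ERSModel(
        refit_terms=list(s.index), term_coefficients=s,
        covariate_coefficients=pd.Series(dtype=float), intercept=0.0,
        standard_errors=pd.Series(dtype=float), covariance=pd.DataFrame(),
        ers_values=np.zeros(len(termset.values)),
        metal_names=termset.metal_names, scaling=termset.scaling)


class TestHierarchicalRefit:
    def test_selected_terms_imply_their_main_effects(self, cohort, termset):
        model = hierarchical_refit(["Ag", "Sb", "Sn^2", "Ce^2", "La:Ce"],
                                   termset, cohort["depressed"],
                                   cohort[COVARIATES])
        assert model.refit_terms == ["Ag", "Sn", "Sb", "La", "Ce",
                                     "Sn^2", "Ce^2", "La:Ce"]
        kinds = [5, 2, 1]  # 5 mains, 2 squares, 1 interaction
        assert [sum(":" not in t and "^" not in t for t in model.refit_terms),
                sum(t.endswith("^2") for t in model.refit_terms),
                sum(":" in t for t in model.refit_terms)] == kinds

    def test_empty_selection_gives_zero_ers(self, cohort, termset):
        model = hierarchical_refit([], termset, cohort["depressed"],
                                   cohort[COVARIATES])
        assert model.refit_terms == []
        np.testing.assert_array_equal(model.ers_values, 0.0)

    def test_single_main_effect_recovery(self):
        # y generated from exactly one standardized metal at n=50,000
        rng = np.random.default_rng(77)
        z = rng.standard_normal(50_000)
        y = (rng.random(len(z)) < expit(-3.0 + 0.4 * z)).astype(int)
        Z = pd.DataFrame({"Ag": z, "Sb": rng.standard_normal(len(z))})
        ts = expand(Z, ["Ag", "Sb"])
        model = hierarchical_refit(["Ag"], ts, y, covariates=None)
        est = model.term_coefficients["Ag"]
        se = model.standard_errors["Ag"]
        assert abs(est - 0.4) < 3 * se

    def test_stored_ers_matches_independent_recomputation(self, cohort, termset):
        model = hierarchical_refit(["Ag", "Sn^2", "La:Ce"], termset,
                                   cohort["depressed"], cohort[COVARIATES])
        Z = termset.values[termset.metal_names]
        manual = np.zeros(len(Z))
        for lab, b in model.term_coefficients.items():
            if ":" in lab:
                a, c = lab.split(":")
                manual += b * (Z[a].to_numpy() * Z[c].to_numpy())
            elif lab.endswith("^2"):
                z = Z[lab[:-2]].to_numpy()
                manual += b * (z * z)
            else:
                manual += b * Z[lab].to_numpy()
        np.testing.assert_array_equal(model.ers_values, manual)


class TestComputeErs:
    def test_all_zero_coefficients(self, termset):
        model = _model_with_coefs(termset, {"Ag": 0.0, "Sn^2": 0.0})
        np.testing.assert_array_equal(
            compute_ers(model, termset.values[termset.metal_names]), 0.0)

    def test_single_term_unit_exposure(self, termset):
        model = _model_with_coefs(termset, {"Ag": 0.174})
        Z = pd.DataFrame({m: [1.0 if m == "Ag" else 0.0] for m in METAL_PANEL})
        assert compute_ers(model, Z)[0] == pytest.approx(0.174)

    def test_full_refit_column_at_unit_z(self, termset):
        # all five metals at Z = 1: every term contributes its coefficient
        model = _model_with_coefs(termset, REFIT_COEFS)
        Z = pd.DataFrame({m: [1.0 if m in ("Ag", "Sb", "Sn", "La", "Ce") else 0.0]
                          for m in METAL_PANEL})
        assert compute_ers(model, Z)[0] == pytest.approx(sum(REFIT_COEFS.values()))
        assert compute_ers(model, Z)[0] == pytest.approx(-0.606)

    def test_missing_metal_named(self, termset):
        model = _model_with_coefs(termset, {"Ag": 1.0})
        with pytest.raises(KeyError, match="Ag"):
            compute_ers(model, pd.DataFrame({"Sb": [1.0]}))


class TestContinuousAssociation:
    def test_planted_unit_log_or_recovered(self, rng):
        ers = rng.normal(size=50_000)
        y = (rng.random(len(ers)) < expit(-4.0 + 1.0 * ers)).astype(int)
        r = continuous_association(ers, y)
        assert abs(r.estimate - 1.0) < 3 * r.se
        assert r.ci_low < r.or_ < r.ci_high
        assert r.or_ == pytest.approx(np.exp(r.estimate))

    def test_independent_covariate_barely_moves_estimate(self, rng):
        ers = rng.normal(size=20_000)
        y = (rng.random(len(ers)) < expit(-3.0 + 0.4 * ers)).astype(int)
        crude = continuous_association(ers, y)
        cov = pd.DataFrame({"age": rng.normal(40, 5, len(ers))})
        adj = continuous_association(ers, y, cov)
        assert abs(adj.estimate - crude.estimate) < 2 * crude.se

    def test_degenerate_outcome_refused(self, rng):
        with pytest.raises(ValueError, match="single class"):
            continuous_association(rng.normal(size=50), np.zeros(50))

    def test_constant_exposure_refused(self):
        with pytest.raises(ValueError, match="constant"):
            continuous_association(np.ones(50), np.r_[np.ones(25), np.zeros(25)])


class TestQuintiles:
    def test_group_sizes_conserve_subjects(self, rng):
        v = rng.normal(size=1003)
        groups, breaks = quintile_groups(v)
        sizes = np.bincount(groups)
        assert sizes.sum() == 1003
        assert sizes.max() - sizes.min() <= 1
        assert len(breaks) == 4

    def test_logistic_ors_equal_contingency_oracle(self, rng):
        v = rng.normal(size=2000)
        y = (rng.random(2000) < expit(-2.0 + 0.5 * v)).astype(int)
        results = quintile_association(v, y)
        groups, _ = quintile_groups(v)
        for g, r in zip(range(1, 5), results):
            a = ((groups == g) & (y == 1)).sum()
            b = ((groups == g) & (y == 0)).sum()
            c = ((groups == 0) & (y == 1)).sum()
            d = ((groups == 0) & (y == 0)).sum()
            assert r.or_ == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_structural_separation_flagged_not_raised(self):
        # all cases sit above the 80th percentile: the Q5-vs-Q1 table has an
        # infinite contingency OR (and Q1 has no cases at all), so results
        # come back flagged rather than raising
        v = np.arange(1.0, 101.0)
        y = (v > 80).astype(int)
        results = quintile_association(v, y)
        assert results[-1].non_estimable
        assert np.isnan(results[-1].or_)
        assert len(results) == 4

    def test_monotone_risk_gives_increasing_or(self, rng):
        # Q5 OR exceeds Q2 OR in expectation under an increasing dose effect
        wins = 0
        for s in range(25):
            r = np.random.default_rng(1000 + s)
            v = r.normal(size=3000)
            y = (r.random(3000) < expit(-2.5 + 0.8 * v)).astype(int)
            res = quintile_association(v, y)
            wins += res[3].estimate > res[0].estimate
        assert wins >= 20

    def test_ties_collapsing_a_group_raise(self):
        v = np.r_[np.zeros(96), [1, 2, 3, 4.0]]
        with pytest.raises(ValueError, match="tie"):
            quintile_association(v, np.r_[np.ones(50), np.zeros(50)])


class TestStratified:
    def test_identical_strata_have_zero_difference(self, rng):
        ers = rng.normal(size=2000)
        y = (rng.random(2000) < expit(-2.0 + 0.5 * ers)).astype(int)
        v2, y2 = np.r_[ers, ers], np.r_[y, y]
        strata = np.r_[np.zeros(2000), np.ones(2000)]
        cmp = stratified_association(v2, y2, None, strata)
        assert cmp.z == pytest.approx(0.0, abs=1e-10)
        assert cmp.p_value == pytest.approx(1.0)

    def test_equal_effects_rarely_rejected(self):
        rejections = 0
        n_seeds = 40
        for s in range(n_seeds):
            r = np.random.default_rng(2000 + s)
            ers = r.normal(size=8000)
            strata = (np.arange(8000) < 4000).astype(int)
            y = (r.random(8000) < expit(-2.5 + 1.0 * ers)).astype(int)
            cmp = stratified_association(ers, y, None, strata)
            rejections += cmp.p_value < 0.05
        assert rejections <= 6  # ~5% type-I error

    def test_different_effects_usually_rejected(self):
        rejections = 0
        n_seeds = 20
        for s in range(n_seeds):
            r = np.random.default_rng(3000 + s)
            ers = r.normal(size=8000)
            strata = (np.arange(8000) < 4000).astype(int)
            lp = np.where(strata == 0, -2.5 + 0.0 * ers, -2.5 + 1.5 * ers)
            y = (r.random(8000) < expit(lp)).astype(int)
            cmp = stratified_association(ers, y, None, strata)
            rejections += cmp.p_value < 0.05
        assert rejections >= 19

    def test_stratum_without_cases_raises(self, rng):
        ers = rng.normal(size=100)
        y = np.r_[np.ones(10), np.zeros(90)].astype(int)
        strata = np.r_[np.zeros(50), np.ones(50)]
        with pytest.raises(ValueError, match="outcome classes"):
            stratified_association(ers, y[::-1] * 0, None, strata)


class TestSensitivity:
    def test_primary_variant_is_idempotent(self, cohort, termset):
        model = hierarchical_refit(["Ag", "La:Ce"], termset,
                                   cohort["depressed"], cohort[COVARIATES])
        y = cohort["depressed"].to_numpy()
        base = continuous_association(model.ers_values, y, cohort[COVARIATES])
        table = sensitivity_refits(model.ers_values, y, cohort[COVARIATES],
                                   {"primary": COVARIATES})
        assert table.loc[0, "log_or"] == pytest.approx(base.estimate, abs=1e-10)

    def test_noise_covariate_barely_shifts_estimate(self, cohort, termset, rng):
        model = hierarchical_refit(["Ag", "La:Ce"], termset,
                                   cohort["depressed"], cohort[COVARIATES])
        y = cohort["depressed"].to_numpy()
        cov = cohort[COVARIATES].copy()
        cov["noise"] = rng.normal(size=len(cov))
        base = continuous_association(model.ers_values, y, cohort[COVARIATES])
        table = sensitivity_refits(
            model.ers_values, y, cov,
            {"plus_noise": COVARIATES + ["noise"], "crude": []})
        assert abs(table.loc[0, "log_or"] - base.estimate) < 2 * base.se
        assert abs(table.loc[1, "log_or"] - base.estimate) < 2 * base.se


def test_covariate_design_encoding(cohort):
    cd = covariate_design(cohort[COVARIATES])
    assert set(cd.columns) >= {"age", "bmi", "sex_male", "smoking"}
    assert cd["sex_male"].isin([0.0, 1.0]).all()
    income_cols = [c for c in cd.columns if c.startswith("income_")]
    assert len(income_cols) == 4  # 5 levels, lowest is reference
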