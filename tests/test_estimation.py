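"""Conditional logit estimation: oracle checks, invariances, covariance."""

import math

import numpy as np
import pandas as pd
import pytest

from fact8d.descriptive import DIMENSIONS
from fact8d.estimation import (
    ConditionalLogitQALY,
    ConvergenceError,
    build_design_matrix,
    cluster_sandwich_vcov,
    compare_fits,
    difference_features,
    feature_names,
    features_from_levels,
    loglik_and_gradient,
    normalize_merge_map,
)
from fact8d.simulate import TrueParameters, simulate_cohort


# ----------------------------------------------------------------------
# Brute-force oracle: pure-Python per-choice-set probability enumeration,
# with its own dummy coding, independent of the vectorized implementation.
# ----------------------------------------------------------------------
def oracle_loglik_grad(choices: pd.DataFrame, coef: np.ndarray, names: list[str]):
    def features(row):
        x = {"TIME": float(row["duration_years"])}
        for dim in DIMENSIONS:
            for level in (2, 3, 4, 5):
                key = f"{dim}_L{level}xTIME"
                x[key] = float(row["duration_years"]) if row[dim] == level else 0.0
        return np.array([x[n] for n in names])

    ll = 0.0
    grad = np.zeros(len(coef))
    for (_, _), task in choices.groupby(["respondent_id", "set_id"]):
        assert len(task) == 2
        xs = [features(r) for _, r in task.iterrows()]
        vs = [float(x @ coef) for x in xs]
        denom = math.exp(vs[0]) + math.exp(vs[1])
        probs = [math.exp(v) / denom for v in vs]
        chosen = int(np.flatnonzero(task["chosen"].to_numpy())[0])
        ll += math.log(probs[chosen])
        grad += xs[chosen] - (probs[0] * xs[0] + probs[1] * xs[1])
    return ll, grad


class TestDesignMatrix:
    def test_model1_has_33_columns(self):
        assert len(feature_names()) == 33

    def test_merging_two_levels_drops_one_column(self):
        names = feature_names({"pain": [(2, 3), (4,), (5,)]})
        assert len(names) == 32
        assert "pain_L2-3xTIME" in names

    def test_reference_state_contributes_only_time(self):
        x = features_from_levels(np.ones((1, 8), dtype=int), np.array([10.0]))
        assert x[0, 0] == 10.0
        assert np.all(x[0, 1:] == 0.0)

    def test_dummies_are_level_indicators_times_time(self):
        lv = np.ones((1, 8), dtype=int)
        lv[0, 0] = 3  # pain level 3
        x = features_from_levels(lv, np.array([5.0]))
        names = feature_names()
        assert x[0, names.index("pain_L3xTIME")] == 5.0
        assert x[0].sum() == 10.0  # TIME + the single active dummy

    def test_invalid_levels_and_merge_maps_rejected(self):
        with pytest.raises(ValueError):
            features_from_levels(np.full((1, 8), 6), np.array([1.0]))
        with pytest.raises(ValueError):
            normalize_merge_map({"pain": [(2, 4), (3,), (5,)]})  # not adjacent
        with pytest.raises(ValueError):
            normalize_merge_map({"vigour": [(2,), (3,), (4,), (5,)]})

    def test_malformed_choice_data_rejected(self, cohort_small):
        df = cohort_small.choices.copy()
        with pytest.raises(ValueError):
            build_design_matrix(df.iloc[:-1])  # odd number of rows for one task
        df2 = cohort_small.choices.copy()
        df2["chosen"] = 0
        with pytest.raises(ValueError):
            build_design_matrix(df2)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("scale", [0.0, 0.5, 1.0])
    def test_loglik_and_gradient_match_enumeration(self, tiny_choices, scale):
        cm = build_design_matrix(tiny_choices)
        rng = np.random.default_rng(42)
        coef = scale * rng.normal(size=len(cm.names)) * 0.1
        ll, grad = loglik_and_gradient(cm.x, cm.y, coef)
        ll0, grad0 = oracle_loglik_grad(tiny_choices, coef, cm.names)
        assert ll == pytest.approx(ll0, abs=1e-10)
        np.testing.assert_allclose(grad, grad0, atol=1e-10)

    def test_fitted_probability_is_logit_of_utility_difference(self, fit_small, cohort_small):
        probs = fit_small.predict_proba(cohort_small.choices)
        x, _ = difference_features(
            cohort_small.choices, keys=["respondent_id", "set_id"]
        )
        manual = 1 / (1 + np.exp(-(x @ fit_small.coef_)))
        np.testing.assert_allclose(probs, manual)
        assert np.all((probs > 0) & (probs < 1))


class TestFit:
    def test_matches_statsmodels_logit(self, cohort_small):
        sm = pytest.importorskip("statsmodels.api")
        cm = build_design_matrix(cohort_small.choices)
        ours = ConditionalLogitQALY().fit(cohort_small.choices)
        ref = sm.Logit(cm.y, cm.x).fit(disp=0, method="newton")
        np.testing.assert_allclose(ours.coef_, ref.params, rtol=1e-6, atol=1e-8)
        assert ours.loglik_ == pytest.approx(ref.llf, rel=1e-9)

    def test_loglik_at_mle_beats_zero_and_gradient_vanishes(self, fit_small, cohort_small):
        cm = build_design_matrix(cohort_small.choices)
        ll_zero, _ = loglik_and_gradient(cm.x, cm.y, np.zeros(33))
        assert fit_small.loglik_ >= ll_zero
        _, grad = loglik_and_gradient(cm.x, cm.y, fit_small.coef_)
        assert np.max(np.abs(grad)) < 1e-5

    def test_pseudo_r2_uses_equal_share_null(self, fit_small):
        assert fit_small.null_loglik_ == pytest.approx(-fit_small.n_choicesets_ * np.log(2))
        assert 0 <= fit_small.pseudo_r2_ <= 1

    def test_unit_weights_equal_unweighted_bit_for_bit(self, cohort_small, fit_small):
        ids = pd.unique(cohort_small.choices["respondent_id"])
        ones = pd.Series(1.0, index=ids)
        wfit = ConditionalLogitQALY().fit(cohort_small.choices, sample_weight=ones)
        assert np.array_equal(wfit.coef_, fit_small.coef_)
        assert wfit.loglik_ == fit_small.loglik_
        assert np.array_equal(wfit.vcov_, fit_small.vcov_)

    def test_flipping_presented_sides_leaves_fit_identical(self, cohort_small, fit_small):
        flipped = cohort_small.choices.copy()
        flipped["option"] = flipped["option"].map({"A": "B", "B": "A"})
        refit = ConditionalLogitQALY().fit(flipped)
        np.testing.assert_allclose(refit.coef_, fit_small.coef_, rtol=1e-8)
        assert refit.loglik_ == pytest.approx(fit_small.loglik_, rel=1e-10)

    def test_estimates_recover_truth_at_study_scale(self, fit_medium, truth):
        est = pd.Series(fit_medium.coef_, index=fit_medium.feature_names_)
        se = fit_medium.se_
        true = pd.Series({"TIME": truth.alpha})
        for (dim, level), b in truth.beta.items():
            true[f"{dim}_L{level}xTIME"] = b
        z = ((est - true[est.index]) / se).abs()
        assert z.max() < 4.5  # all coefficients within ~4.5 robust SEs
        betas = est.drop("TIME")
        assert np.corrcoef(betas, true[betas.index])[0, 1] > 0.95

    def test_separation_warns_then_fails_to_converge(self):
        rows = []
        for s in range(3):
            lv = {d: 1 for d in DIMENSIONS}
            rows.append({"respondent_id": 0, "set_id": s, "option": "A",
                         **lv, "duration_years": 10, "chosen": 1})
            rows.append({"respondent_id": 0, "set_id": s, "option": "B",
                         **lv, "duration_years": 1, "chosen": 0})
        df = pd.DataFrame(rows)
        with pytest.warns(RuntimeWarning, match="separation"):
            with pytest.raises((ConvergenceError, np.linalg.LinAlgError)):
                ConditionalLogitQALY().fit(df)


class TestClusteredCovariance:
    def test_degenerate_clusters_match_heteroskedastic_sandwich(self, cohort_small):
        sm = pytest.importorskip("statsmodels.api")
        cm = build_design_matrix(cohort_small.choices)
        fit = ConditionalLogitQALY().fit(cohort_small.choices)
        per_set = np.arange(len(cm.y))  # one cluster per choice set
        ours = cluster_sandwich_vcov(
            cm.x, cm.y, np.ones(len(cm.y)), fit.coef_, per_set, correction=False
        )
        ref = sm.Logit(cm.y, cm.x).fit(disp=0, cov_type="HC0")
        np.testing.assert_allclose(ours, ref.cov_params(), rtol=1e-5, atol=1e-10)

    def test_vcov_symmetric_positive_semidefinite(self, fit_small):
        v = fit_small.vcov_
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) > -1e-12)

    def test_taste_heterogeneity_inflates_clustered_ses(self, choice_sets, truth):
        # latent taste classes perturbing every coefficient, with little
        # choice noise -> strong persistent within-respondent correlation
        rng = np.random.default_rng(99)
        frames = []
        for g in range(20):
            mult = np.exp(rng.normal(0, 2.0, size=33))
            beta = {k: v * float(mult[i + 1]) for i, (k, v) in enumerate(truth.beta.items())}
            params = TrueParameters(
                alpha=truth.alpha * float(np.exp(rng.normal(0, 0.6))),
                beta=beta,
                noise_scale=0.2,
            )
            c = simulate_cohort(choice_sets, n_respondents=40, params=params, seed=200 + g).choices
            frames.append(c.assign(respondent_id=c["respondent_id"] + 1000 * g))
        fit = ConditionalLogitQALY().fit(pd.concat(frames, ignore_index=True))
        naive_se = np.sqrt(np.diag(fit.vcov_naive_))
        frac_larger = (fit.se_.to_numpy() >= naive_se).mean()
        assert frac_larger > 0.75


class TestCompareFits:
    def test_fit_versus_itself_is_null_report(self, fit_small):
        rep = compare_fits(fit_small, fit_small)
        assert rep["delta_pseudo_r2"] == 0.0
        assert rep["mean_se_inflation_pct"] == 0.0

    def test_different_data_rejected(self, fit_small, cohort_medium):
        other = ConditionalLogitQALY().fit(
            cohort_medium.choices[cohort_medium.choices["respondent_id"] < 300]
        )
        with pytest.raises(ValueError, match="different data"):
            compare_fits(fit_small, other)
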