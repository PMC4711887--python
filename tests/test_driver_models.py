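"""Logistic issue-driver models: fitting, AIC selection, pseudo-R², profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from taxonvet.driver_models import (
    IssueDriverModel,
    ModelSpec,
    build_design,
    enumerate_interaction_sets,
    fit_issue_model,
    pseudo_r2,
    select_model_aic,
)
from taxonvet.synthetic import simulate_covariates, simulate_issue_outcomes


def covariate_frame(n, seed=0):
    return simulate_covariates(n, np.random.default_rng(seed))


class TestFitIssueModel:
    def test_intercept_only_recovers_logit_of_mean(self):
        df = covariate_frame(2000, seed=1)
        rng = np.random.default_rng(2)
        df["hasIssue"] = (rng.random(len(df)) < 0.3).astype(int)
        res = fit_issue_model(df, ModelSpec(response="hasIssue", main_effects=()))
        assert res.params["Intercept"] == pytest.approx(
            logit(df["hasIssue"].mean()), abs=1e-6
        )

    def test_constant_response_is_error(self):
        df = covariate_frame(100, seed=1)
        df["hasIssue"] = 1
        with pytest.raises(ValueError, match="constant"):
            fit_issue_model(df, ModelSpec(response="hasIssue"))

    def test_indeterminate_responses_dropped(self):
        df = covariate_frame(300, seed=3)
        rng = np.random.default_rng(4)
        df["isSynonym"] = rng.choice(["yes", "no", "indeterminate"], size=len(df))
        model = IssueDriverModel(df, ModelSpec(response="isSynonym"))
        assert len(model.frame) == (df["isSynonym"] != "indeterminate").sum()

    def test_aic_identity(self):
        df = covariate_frame(2000, seed=5)
        X = build_design(df)
        beta = {"Intercept": -0.5, "standardize(year)": 0.5}
        df["hasIssue"] = simulate_issue_outcomes(X, beta, np.random.default_rng(6))
        res = fit_issue_model(df, ModelSpec(response="hasIssue"))
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_params, abs=1e-9)

    def test_coefficient_recovery_at_moderate_n(self):
        beta = {
            "Intercept": -1.0,
            "basisOfRecord[T.FossilSpecimen]": 0.8,
            "standardize(year)": -0.4,
        }
        df = covariate_frame(20000, seed=7)
        X = build_design(df)
        df["hasIssue"] = simulate_issue_outcomes(X, beta, np.random.default_rng(8))
        res = fit_issue_model(df, ModelSpec(response="hasIssue"))
        for name, true in beta.items():
            assert abs(res.params[name] - true) < 3 * res.bse[name]

    def test_interaction_nesting_never_decreases_loglik(self):
        df = covariate_frame(4000, seed=9)
        X = build_design(df)
        df["hasIssue"] = simulate_issue_outcomes(
            X, {"Intercept": -0.5, "standardize(year)": 0.4},
            np.random.default_rng(10),
        )
        base = fit_issue_model(
            df, ModelSpec(response="hasIssue",
                          main_effects=("basisOfRecord", "year"))
        )
        nested = fit_issue_model(
            df,
            ModelSpec(
                response="hasIssue",
                main_effects=("basisOfRecord", "year"),
                interactions=(("basisOfRecord", "year"),),
            ),
        )
        assert nested.llf >= base.llf - 1e-8

    def test_interaction_without_main_effect_rejected(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelSpec(
                response="hasIssue",
                main_effects=("year",),
                interactions=(("basisOfRecord", "year"),),
            )


class TestPseudoR2:
    def test_null_model_is_zero_zero(self):
        df = covariate_frame(500, seed=11)
        rng = np.random.default_rng(12)
        df["hasIssue"] = (rng.random(len(df)) < 0.4).astype(int)
        res = fit_issue_model(df, ModelSpec(response="hasIssue", main_effects=()))
        mcf, nag = pseudo_r2(res.llf, res.llnull, res.nobs)
        assert mcf == pytest.approx(0.0, abs=1e-12)
        assert nag == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_twenty_row_fixture(self):
        # 20 rows, binary predictor: group x=0 has 3/12 positives, group x=1
        # has 5/8.  The saturated-by-group MLE gives closed-form likelihoods.
        y = [1] * 3 + [0] * 9 + [1] * 5 + [0] * 3
        x = [0] * 12 + [1] * 8
        df = pd.DataFrame(
            {
                "hasIssue": y,
                "basisOfRecord": ["PreservedSpecimen" if v == 0 else
                                  "FossilSpecimen" for v in x],
            }
        )
        res = fit_issue_model(
            df, ModelSpec(response="hasIssue", main_effects=("basisOfRecord",))
        )

        def bern_ll(k, n):
            p = k / n
            return k * math.log(p) + (n - k) * math.log(1 - p)

        llf_hand = bern_ll(3, 12) + bern_ll(5, 8)
        llnull_hand = bern_ll(8, 20)
        assert res.llf == pytest.approx(llf_hand, abs=1e-8)
        assert res.llnull == pytest.approx(llnull_hand, abs=1e-8)
        mcf, nag = pseudo_r2(res.llf, res.llnull, res.nobs)
        assert mcf == pytest.approx(1 - llf_hand / llnull_hand, abs=1e-10)
        cs = 1 - math.exp((2 / 20) * (llnull_hand - llf_hand))
        assert nag == pytest.approx(cs / (1 - math.exp((2 / 20) * llnull_hand)),
                                    abs=1e-10)

    def test_strong_signal_gives_high_r2(self):
        df = covariate_frame(5000, seed=13)
        X = build_design(df)
        df["hasIssue"] = simulate_issue_outcomes(
            X, {"Intercept": 0.0, "standardize(year)": 4.0},
            np.random.default_rng(14),
        )
        res = fit_issue_model(
            df, ModelSpec(response="hasIssue", main_effects=("year",))
        )
        assert res.mcfadden_r2 > 0.5
        assert res.nagelkerke_r2 > 0.5


class TestModelSelection:
    def test_enumeration_counts(self):
        assert len(enumerate_interaction_sets(["a", "b", "c"])) == 8
        assert len(enumerate_interaction_sets(["a", "b", "c", "d"])) == 64
        assert len(enumerate_interaction_sets()) == 1024

    def test_every_interaction_set_is_distinct(self):
        sets = enumerate_interaction_sets(["a", "b", "c"])
        assert len({frozenset(s) for s in sets}) == 8

    def test_injected_interaction_ranks_best(self):
        covs = ["basisOfRecord", "clade", "year"]
        df = covariate_frame(20000, seed=15)
        X = build_design(df, covariates=covs,
                         interactions=[("basisOfRecord", "year")])
        beta = {
            "Intercept": -0.5,
            "basisOfRecord[T.FossilSpecimen]": 0.5,
            "standardize(year)": -0.3,
            "basisOfRecord[T.FossilSpecimen]:standardize(year)": 1.5,
        }
        df["hasIssue"] = simulate_issue_outcomes(X, beta,
                                                 np.random.default_rng(16))
        ranked = select_model_aic(df, "hasIssue", covariates=covs)
        assert len(ranked) == 8
        assert ("basisOfRecord", "year") in ranked[0].spec.interactions
        assert ranked[0].delta_aic == 0.0
        assert all(
            ranked[i].aic <= ranked[i + 1].aic for i in range(len(ranked) - 1)
        )


class TestEffectProfile:
    def test_single_covariate_closed_form(self):
        # with an effectively zero intercept and unit slope the profile at
        # the covariate mean must be 0.5
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"year": rng.normal(1950, 20, size=20000)})
        eta = (df["year"] - df["year"].mean()) / df["year"].std()
        df["hasIssue"] = (rng.random(len(df)) < expit(eta)).astype(int)
        res = fit_issue_model(
            df, ModelSpec(response="hasIssue", main_effects=("year",))
        )
        prof = res.effect_profile("year", grid=[df["year"].mean()])
        assert prof["probability"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_profile_equals_direct_inverse_logit(self):
        df = covariate_frame(3000, seed=18)
        X = build_design(df)
        df["hasIssue"] = simulate_issue_outcomes(
            X, {"Intercept": -0.6, "standardize(year)": 0.7},
            np.random.default_rng(19),
        )
        res = fit_issue_model(
            df, ModelSpec(response="hasIssue", main_effects=("year",))
        )
        grid = [1910.0, 1950.0, 2000.0]
        prof = res.effect_profile("year", grid=grid)
        mu = df["year"].mean()
        sd = df["year"].std(ddof=0)  # in-formula scaling uses population std
        for g, p in zip(grid, prof["probability"]):
            eta = (
                res.params["Intercept"]
                + res.params["standardize(year)"] * (g - mu) / sd
            )
            assert p == pytest.approx(expit(eta), abs=1e-8)

    def test_monotone_in_year_for_positive_coefficient(self):
        df = covariate_frame(3000, seed=20)
        X = build_design(df)
        df["hasIssue"] = simulate_issue_outcomes(
            X, {"Intercept": 0.0, "standardize(year)": 0.8},
            np.random.default_rng(21),
        )
        res = fit_issue_model(
            df, ModelSpec(response="hasIssue", main_effects=("year",))
        )
        prof = res.effect_profile("year")
        assert prof["probability"].is_monotonic_increasing

    def test_out_of_range_grid_annotated_not_rejected(self):
        df = covariate_frame(1000, seed=22)
        rng = np.random.default_rng(23)
        df["hasIssue"] = (rng.random(len(df)) < 0.4).astype(int)
        res = fit_issue_model(
            df, ModelSpec(response="hasIssue", main_effects=("year",))
        )
        prof = res.effect_profile("year", grid=[1600.0])
        assert bool(prof["outside_observed_range"].iloc[0])
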