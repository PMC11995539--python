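"""Compositional regression: design building, OLS in ilr coordinates,
behaviour rotations, and the joint composition F-test."""

import numpy as np
import pandas as pd
import pytest
from skbio.stats.composition import clr

from coda24.coda import PARTS, pivot_ilr_values, rotated_order
from coda24.regression import (
    DEFAULT_COVARIATES, CovariateSpec, MissingDataError, behaviour_effects,
    build_design, composition_matrix, effects_table, fit_ilr_model,
    overall_model_test,
)
from coda24.synthetic import (
    DEFAULT_BEHAVIOUR_BETAS, GeneratorConfig, generate_cohort,
)
from conftest import random_compositions


def cohort_frame(X, y, **extra):
    df = pd.DataFrame(X, columns=["mvpa_min", "lpa_min", "st_min", "sleep_min"])
    df["bdi"] = y
    df.insert(0, "id", np.arange(1, len(df) + 1))
    for k, v in extra.items():
        df[k] = v
    return df


class TestBuildDesign:
    def test_single_record_no_covariates(self, rng):
        df = cohort_frame(random_compositions(rng, 1), [5.0])
        X, y = build_design(df)
        assert X.shape == (1, 4)
        assert list(X.columns) == ["const", "ilr_1", "ilr_2", "ilr_3"]
        assert y.iloc[0] == 5.0

    def test_three_level_categorical_two_indicators(self, rng):
        spec = CovariateSpec(categorical={"smoking": ("never", "former", "current")})
        df = cohort_frame(random_compositions(rng, 3), [1.0, 2.0, 3.0],
                          smoking=["never", "former", "current"])
        X, _ = build_design(df, covariate_spec=spec)
        assert "smoking[former]" in X and "smoking[current]" in X
        assert "smoking[never]" not in X  # first declared level is reference
        assert X["smoking[former]"].tolist() == [0.0, 1.0, 0.0]

    def test_toy_matrix_matches_hand_built_oracle(self, rng):
        comp = random_compositions(rng, 5)
        spec = CovariateSpec(categorical={"sex": ("male", "female")},
                             continuous=("waist",))
        waist = [80.0, 85, 90, 95, 100]
        sex = ["male", "female", "female", "male", "female"]
        df = cohort_frame(comp, np.arange(5.0), sex=sex, waist=waist)
        X, _ = build_design(df, covariate_spec=spec)

        # independent hand evaluation of the pivot formula, term by term
        Z = np.column_stack([
            np.sqrt(3 / 4) * np.log(comp[:, 0] / (comp[:, 1] * comp[:, 2] * comp[:, 3]) ** (1 / 3)),
            np.sqrt(2 / 3) * np.log(comp[:, 1] / (comp[:, 2] * comp[:, 3]) ** (1 / 2)),
            np.sqrt(1 / 2) * np.log(comp[:, 2] / comp[:, 3]),
        ])
        assert np.allclose(X[["ilr_1", "ilr_2", "ilr_3"]].to_numpy(), Z, atol=1e-12)
        assert np.allclose(X["sex[female]"],
                           [0.0, 1.0, 1.0, 0.0, 1.0])
        assert np.allclose(X["waist"], waist)

    def test_missing_values_listed_by_id(self, rng):
        df = cohort_frame(random_compositions(rng, 3), [1.0, np.nan, 3.0])
        with pytest.raises(MissingDataError, match="2"):
            build_design(df)

    def test_unknown_categorical_level_rejected(self, rng):
        spec = CovariateSpec(categorical={"sex": ("male", "female")})
        df = cohort_frame(random_compositions(rng, 1), [1.0], sex=["other"])
        with pytest.raises(ValueError, match="sex"):
            build_design(df, covariate_spec=spec)


class TestFit:
    def test_constant_outcome_zero_slopes(self, rng):
        df = cohort_frame(random_compositions(rng, 30), np.full(30, 7.0))
        fit = fit_ilr_model(df)
        assert np.allclose(fit.ilr_beta, 0.0, atol=1e-8)
        assert fit.r_squared == 0.0

    def test_noise_free_recovery(self, rng):
        X = random_compositions(rng, 200)
        Z = pivot_ilr_values(X)
        beta = np.array([1.5, -2.0, 0.7])
        df = cohort_frame(X, 3.0 + Z @ beta)
        fit = fit_ilr_model(df)
        assert np.allclose(fit.ilr_beta, beta, atol=1e-8)
        assert fit.params["const"] == pytest.approx(3.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        X = random_compositions(rng, 20)
        y = rng.normal(5, 2, size=20)
        df = cohort_frame(X, y)
        fit = fit_ilr_model(df)
        M = np.column_stack([np.ones(20), pivot_ilr_values(X)])
        beta_oracle = np.linalg.solve(M.T @ M, M.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta_oracle, atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        spec = CovariateSpec(continuous=("a", "b"))
        df = cohort_frame(random_compositions(rng, 10), rng.normal(size=10))
        df["a"] = np.arange(10.0)
        df["b"] = 2.0 * df["a"]  # exactly collinear
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ilr_model(df, covariate_spec=spec)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(
        n_urban=300, n_rural=200, seed=11, outcome_mode="linear_gaussian"))


class TestRotations:
    def test_fit_statistics_invariant_across_rotations(self, cohort):
        fits = {b: fit_ilr_model(cohort, rotated_order(b), DEFAULT_COVARIATES)
                for b in PARTS}
        r2 = [f.r_squared for f in fits.values()]
        p = [f.overall_p for f in fits.values()]
        assert np.ptp(r2) < 1e-9 and np.ptp(p) < 1e-9
        # fitted values identical too
        fitted = []
        for b, f in fits.items():
            X, _ = build_design(cohort, rotated_order(b), DEFAULT_COVARIATES)
            fitted.append(X.to_numpy() @ f.params.to_numpy())
        for other in fitted[1:]:
            assert np.abs(other - fitted[0]).max() < 1e-9

    def test_behaviour_betas_sum_to_zero_and_match_clr_oracle(self, cohort):
        effects = behaviour_effects(cohort, DEFAULT_COVARIATES)
        betas = np.array([e.beta for e in effects])
        assert abs(betas.sum()) < 1e-8

        # independent clr-regression oracle: regress on clr coordinates with
        # the sum-zero constraint absorbed by dropping one and centring
        comp = composition_matrix(cohort)
        C = clr(comp / comp.sum(axis=1, keepdims=True))
        Xcov, y = build_design(cohort, PARTS, DEFAULT_COVARIATES)
        other = Xcov.drop(columns=["ilr_1", "ilr_2", "ilr_3"]).to_numpy()
        M = np.column_stack([other, C[:, :3]])  # drop last clr column
        coef, *_ = np.linalg.lstsq(M, y.to_numpy(), rcond=None)
        a_free = coef[-3:]
        a = np.append(a_free, 0.0)
        a -= a.mean()  # centred clr coefficients
        assert np.allclose(betas, 2.0 / np.sqrt(3.0) * a, atol=1e-8)

    def test_known_positive_st_effect_detected(self):
        cohort = generate_cohort(GeneratorConfig(
            n_urban=1000, n_rural=1000, seed=3, outcome_mode="linear_gaussian"))
        effects = {e.behaviour: e for e in behaviour_effects(cohort, DEFAULT_COVARIATES)}
        assert effects["ST"].beta > 0 and effects["ST"].p < 0.05
        assert effects["sleep"].beta < 0 and effects["sleep"].p < 0.05

    def test_wald_ci_brackets_beta(self, cohort):
        for e in behaviour_effects(cohort, DEFAULT_COVARIATES):
            assert e.ci_low <= e.beta <= e.ci_high


class TestOverallTest:
    def test_ilr_block_adding_nothing_gives_p_one(self, rng):
        # outcome depends only on the covariate, exactly: both fits are
        # perfect, F = 0, p = 1
        spec = CovariateSpec(continuous=("waist",))
        waist = rng.uniform(70, 110, size=30)
        df = cohort_frame(random_compositions(rng, 30), 2.0 * waist, waist=waist)
        fit = fit_ilr_model(df, covariate_spec=spec)
        assert fit.overall_p == pytest.approx(1.0)

    def test_strong_composition_effect_significant(self):
        cohort = generate_cohort(GeneratorConfig(
            n_urban=1500, n_rural=500, seed=5, outcome_mode="linear_gaussian"))
        fit = fit_ilr_model(cohort, PARTS, DEFAULT_COVARIATES)
        assert fit.overall_p < 0.001

    def test_f_statistic_matches_sum_of_squares_oracle(self, rng):
        X = random_compositions(rng, 40)
        y = rng.normal(size=40)
        df = cohort_frame(X, y)
        full = fit_ilr_model(df)
        M_full = np.column_stack([np.ones(40), pivot_ilr_values(X)])
        M_red = np.ones((40, 1))

        def rss(M):
            coef, *_ = np.linalg.lstsq(M, y, rcond=None)
            return np.sum((y - M @ coef) ** 2)

        from scipy import stats as ss
        f = ((rss(M_red) - rss(M_full)) / 3) / (rss(M_full) / (40 - 4))
        p_oracle = ss.f.sf(f, 3, 36)
        assert full.overall_p == pytest.approx(p_oracle, abs=1e-10)

    def test_non_nested_models_rejected(self, rng):
        df1 = cohort_frame(random_compositions(rng, 30), rng.normal(size=30))
        df2 = cohort_frame(random_compositions(rng, 25), rng.normal(size=25))
        with pytest.raises(ValueError, match="nested"):
            overall_model_test(fit_ilr_model(df1), fit_ilr_model(df2))


def test_effects_table_shape(small_cohort):
    tab = effects_table(small_cohort, DEFAULT_COVARIATES)
    assert list(tab["behaviour"]) == list(PARTS)
    assert tab["model_r2"].nunique() == 1 and tab["n"].nunique() == 1
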