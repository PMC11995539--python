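"""Compositional multiple linear regression of an outcome on ilr coordinates.

The outcome (a bounded symptom score) is regressed by OLS on the three
pivot-ilr coordinates of the 24-h composition plus covariates.  A
per-behaviour effect is read off by rotating that behaviour into the first
pivot position and refitting: the first coordinate then contrasts the
behaviour against the geometric mean of the other three, and its
coefficient is the behaviour's beta.  All four rotations are orthogonal
changes of basis, so fitted values, residuals, R-squared and the joint
composition test are identical across them.

The model p-value is the F-test of the three ilr coordinates jointly
against the covariates-only model.  Confidence intervals are Wald
intervals with t critical values at the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coda import PARTS, pivot_ilr_values, rotated_order

#: Cohort-table column for each behaviour's daily minutes.
PART_COLUMNS: dict[str, str] = {
    "MVPA": "mvpa_min", "LPA": "lpa_min", "ST": "st_min", "sleep": "sleep_min",
}
OUTCOME_COLUMN = "bdi"


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate encoding: treatment coding with the first declared level as
    reference for categoricals; continuous entered as given."""

    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)
    continuous: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.categorical) + self.continuous

    def n_terms(self) -> int:
        return sum(len(v) - 1 for v in self.categorical.values()) + len(self.continuous)


#: Adjustment set of the main analysis.
DEFAULT_COVARIATES = CovariateSpec(
    categorical={
        "sex": ("male", "female"),
        "education": ("comprehensive", "vocational", "tertiary"),
        "employment": ("employed", "unemployed", "other"),
        "marital": ("married", "divorced", "unmarried"),
        "smoking": ("never", "former", "current"),
        "season": ("summer", "winter"),
    },
    continuous=("work_strenuousness", "harm_avoidance", "alcohol", "waist"),
)

NO_COVARIATES = CovariateSpec()


@dataclass
class IlrModelFit:
    """OLS fit in ilr coordinates: coefficients, covariance and fit stats."""

    params: pd.Series
    cov: pd.DataFrame
    r_squared: float
    overall_p: float
    n: int
    df_resid: float
    rss: float
    tss: float
    parts_order: tuple[str, ...]

    @property
    def ilr_columns(self) -> list[str]:
        return [c for c in self.params.index if c.startswith("ilr_")]

    @property
    def ilr_beta(self) -> np.ndarray:
        return self.params[self.ilr_columns].to_numpy()

    @property
    def ilr_cov(self) -> np.ndarray:
        return self.cov.loc[self.ilr_columns, self.ilr_columns].to_numpy()


@dataclass
class BehaviourEffect:
    """First-pivot-coordinate coefficient for one behaviour with Wald CI."""

    behaviour: str
    beta: float
    ci_low: float
    ci_high: float
    p: float


class MissingDataError(ValueError):
    pass


def composition_matrix(records: pd.DataFrame, parts_order: tuple[str, ...] = PARTS) -> np.ndarray:
    """(n, 4) raw minutes matrix in the requested behaviour order."""
    return records[[PART_COLUMNS[b] for b in parts_order]].to_numpy(dtype=float)


def build_design(
    records: pd.DataFrame,
    parts_order: tuple[str, ...] = PARTS,
    covariate_spec: CovariateSpec = NO_COVARIATES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (intercept, ilr_1..ilr_3, covariate terms) and response.

    Requires complete cases: any missing value raises, listing offending
    ids, because the complete-case filter belongs upstream.
    """
    needed = ([PART_COLUMNS[b] for b in parts_order] + [OUTCOME_COLUMN]
              + list(covariate_spec.columns))
    missing = records[needed].isna().any(axis=1)
    if missing.any():
        ids = (records.loc[missing, "id"].tolist() if "id" in records
               else records.index[missing].tolist())
        raise MissingDataError(f"missing values in records: {ids}")

    Z = pivot_ilr_values(composition_matrix(records, parts_order))
    X = pd.DataFrame({"const": np.ones(len(records))}, index=records.index)
    for j in range(Z.shape[1]):
        X[f"ilr_{j + 1}"] = Z[:, j]
    for name, levels in covariate_spec.categorical.items():
        col = records[name]
        unknown = set(col.unique()) - set(levels)
        if unknown:
            raise ValueError(f"unknown level(s) {unknown} in covariate {name!r}")
        for level in levels[1:]:  # first declared level is the reference
            X[f"{name}[{level}]"] = (col == level).astype(float)
    for name in covariate_spec.continuous:
        X[name] = records[name].to_numpy(dtype=float)
    y = records[OUTCOME_COLUMN].astype(float)
    return X, y


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        cols = list(X.columns)
        collinear = []
        M = X.to_numpy()
        for i in range(M.shape[1]):
            others = np.delete(M, i, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(cols[i])
        raise np.linalg.LinAlgError(
            f"design matrix rank deficient; collinear columns include {collinear}"
        )


def fit_ilr_model(
    records: pd.DataFrame,
    parts_order: tuple[str, ...] = PARTS,
    covariate_spec: CovariateSpec = NO_COVARIATES,
) -> IlrModelFit:
    """OLS of the outcome on pivot-ilr coordinates plus covariates.

    ``overall_p`` is the joint F-test of the ilr block against the
    covariates-only fit on the same rows.
    """
    X, y = build_design(records, parts_order, covariate_spec)
    _check_full_rank(X)
    res = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, X.drop(columns=[c for c in X if c.startswith("ilr_")])).fit()
    r2 = float(res.rsquared)
    if not np.isfinite(r2):  # constant outcome: no variance to explain
        r2 = 0.0
    fit = IlrModelFit(
        params=res.params, cov=res.cov_params(),
        r_squared=r2, overall_p=np.nan,
        n=int(res.nobs), df_resid=float(res.df_resid),
        rss=float(res.ssr), tss=float(res.centered_tss),
        parts_order=tuple(parts_order),
    )
    reduced_fit = IlrModelFit(
        params=reduced.params, cov=reduced.cov_params(),
        r_squared=0.0, overall_p=np.nan,
        n=int(reduced.nobs), df_resid=float(reduced.df_resid),
        rss=float(reduced.ssr), tss=float(reduced.centered_tss),
        parts_order=tuple(parts_order),
    )
    _, fit.overall_p = overall_model_test(fit, reduced_fit)
    return fit


def overall_model_test(fit_full: IlrModelFit, fit_reduced: IlrModelFit) -> tuple[float, float]:
    """(R-squared of the full model, F-test p of the ilr block).

    The reduced model must be nested in the full one on identical rows.
    """
    q = len(fit_full.params) - len(fit_reduced.params)
    nested = (
        fit_full.n == fit_reduced.n
        and q > 0
        and set(fit_reduced.params.index) <= set(fit_full.params.index)
    )
    if not nested:
        raise ValueError("models are not nested on identical rows")
    # noise floor: RSS differences below numerical round-off (relative to
    # the outcome's total variation) carry no evidence
    floor = 1e-10 * (fit_full.tss + fit_reduced.rss) + 1e-20
    num_ss = fit_reduced.rss - fit_full.rss
    if num_ss <= floor:
        return fit_full.r_squared, 1.0
    if fit_full.rss <= floor:
        return fit_full.r_squared, 0.0
    f = (num_ss / q) / (fit_full.rss / fit_full.df_resid)
    p = float(stats.f.sf(f, q, fit_full.df_resid))
    return fit_full.r_squared, p


def behaviour_effects(
    records: pd.DataFrame,
    covariate_spec: CovariateSpec = NO_COVARIATES,
    base_order: tuple[str, ...] = PARTS,
    level: float = 0.95,
) -> list[BehaviourEffect]:
    """Per-behaviour betas from the four pivot rotations.

    For each behaviour the composition is re-expressed with that behaviour
    first and the model refit; the reported effect is the first ilr
    coordinate's coefficient with its Wald t-interval and p-value.
    """
    effects = []
    for b in base_order:
        fit = fit_ilr_model(records, rotated_order(b, base_order), covariate_spec)
        beta = float(fit.params["ilr_1"])
        se = float(np.sqrt(fit.cov.loc["ilr_1", "ilr_1"]))
        tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, fit.df_resid)
        p = 2.0 * float(stats.t.sf(abs(beta / se), fit.df_resid)) if se > 0 else (
            1.0 if beta == 0 else 0.0)
        effects.append(BehaviourEffect(
            behaviour=b, beta=beta,
            ci_low=beta - tcrit * se, ci_high=beta + tcrit * se, p=p,
        ))
    return effects


def effects_table(
    records: pd.DataFrame,
    covariate_spec: CovariateSpec = NO_COVARIATES,
    base_order: tuple[str, ...] = PARTS,
) -> pd.DataFrame:
    """One-row-per-behaviour results table with shared model fit statistics."""
    fit = fit_ilr_model(records, base_order, covariate_spec)
    rows = [
        {"behaviour": e.behaviour, "beta": e.beta, "ci_low": e.ci_low,
         "ci_high": e.ci_high, "p": e.p,
         "model_r2": fit.r_squared, "model_p": fit.overall_p, "n": fit.n}
        for e in behaviour_effects(records, covariate_spec, base_order)
    ]
    return pd.DataFrame(rows)
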