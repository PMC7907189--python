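"""Linear models of mean cortical thickness.

The study question is whether disease duration predicts global cortical
thinning, whether the decline is steeper with a right-sided seizure focus,
and whether posterior (tail) sclerosis modifies the right-sided decline.
The response is each subject's whole-brain mean cortical thickness (mm);
age at diagnosis or age at surgery enter as alternative covariates (never
both in one fit, since duration = age at surgery - age at onset makes the
triple collinear).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_volumes import SubjectRecord, records_to_frame
from .errors import DesignError, ValidationError

#: predictors understood by ModelSpec, mapped to design-matrix builders
PREDICTORS = (
    "duration",
    "laterality",
    "duration_x_laterality",
    "age_at_onset",
    "age_at_surgery",
    "lesion_volume",
    "has_tail",
    "duration_x_has_tail",
)

COVARIATE_COLUMNS = {"age_at_diagnosis": "age_at_onset", "age_at_surgery": "age_at_surgery"}

CONDITION_LIMIT = 1e10


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A thickness model: which predictors enter, and which age covariate.

    The two presets mirror the study's alternative adjustments: age at
    diagnosis (isolating disease exposure from normal aging) and age at
    surgery (absorbing the age-duration covariance).
    """

    predictors: tuple[str, ...]
    covariate_mode: str | None = None

    def __post_init__(self):
        unknown = [p for p in self.predictors if p not in PREDICTORS]
        if unknown:
            raise ValidationError(f"unknown predictors: {unknown}")
        if self.covariate_mode is not None and self.covariate_mode not in COVARIATE_COLUMNS:
            raise ValidationError(
                f"covariate_mode must be one of {tuple(COVARIATE_COLUMNS)} or None"
            )
        both = {"age_at_onset", "age_at_surgery"} <= set(self.columns())
        if both:
            raise ValidationError(
                "age covariates are mutually exclusive within a single fit"
            )

    def columns(self) -> list[str]:
        cols = list(self.predictors)
        if self.covariate_mode is not None:
            col = COVARIATE_COLUMNS[self.covariate_mode]
            if col not in cols:
                cols.append(col)
        return cols


PRESET_AGE_AT_DIAGNOSIS = ModelSpec(
    predictors=("duration", "laterality", "duration_x_laterality"),
    covariate_mode="age_at_diagnosis",
)
PRESET_AGE_AT_SURGERY = ModelSpec(
    predictors=("duration", "laterality", "duration_x_laterality"),
    covariate_mode="age_at_surgery",
)


@dataclasses.dataclass
class FitResult:
    """OLS fit summary: coefficient table plus fit-level statistics."""

    table: pd.DataFrame  # index: term; columns: coef, se, p
    n: int
    r_squared: float
    residual_sd: float
    df_resid: int
    cov_params: pd.DataFrame

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def conf_int(self, term: str, level: float = 0.95):
        from scipy import stats as _st

        t = _st.t.ppf(0.5 + level / 2.0, self.df_resid)
        c, s = self.coef(term), self.se(term)
        return c - t * s, c + t * s


def _design(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    right = (df["laterality"] == "right").astype(float)
    for col in columns:
        if col == "laterality":
            X["right"] = right
        elif col == "duration_x_laterality":
            X["duration:right"] = df["duration"] * right
        elif col == "has_tail":
            if df["has_tail"].isna().any():
                raise ValidationError("has_tail flags are missing for some subjects")
            X["has_tail"] = df["has_tail"].astype(float)
        elif col == "duration_x_has_tail":
            X["duration:has_tail"] = df["duration"] * df["has_tail"].astype(float)
        else:
            X[col] = df[col].astype(float)
    return X


def _check_design(X: pd.DataFrame, n: int) -> None:
    if n < X.shape[1] + 2:
        raise DesignError(f"need at least {X.shape[1] + 2} complete records, got {n}")
    const_cols = [c for c in X.columns if np.std(X[c].to_numpy()) == 0]
    if const_cols:
        raise DesignError(f"predictors with zero variance: {const_cols}")
    scaled = X.to_numpy() / np.abs(X.to_numpy()).max(axis=0)
    with_const = np.column_stack([np.ones(len(X)), scaled])
    cond = np.linalg.cond(with_const)
    if cond > CONDITION_LIMIT:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        pairs = [
            f"{X.columns[i]}~{X.columns[j]}"
            for i in range(len(X.columns))
            for j in range(i + 1, len(X.columns))
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise DesignError(
            f"collinear design (condition number {cond:.3g}); "
            f"near-duplicate columns: {pairs or list(X.columns)}"
        )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "duration" not in df.columns:
            df["duration"] = df["age_at_surgery"] - df["age_at_onset"]
        return df
    return records_to_frame(list(records))


def fit_thickness(records: Iterable[SubjectRecord] | pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Ordinary least squares of mean thickness on the chosen predictors."""
    df = _as_frame(records)
    X = _design(df, spec.columns())
    keep = X.notna().all(axis=1) & df["mean_thickness"].notna()
    X, yv = X[keep], df.loc[keep, "mean_thickness"].astype(float)
    _check_design(X, len(X))
    Xc = sm.add_constant(X, prepend=True)
    fit = sm.OLS(yv, Xc).fit()
    table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    return FitResult(
        table=table,
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        df_resid=int(fit.df_resid),
        cov_params=fit.cov_params(),
    )


@dataclasses.dataclass
class LateralitySlopes:
    """Duration slope of thickness per seizure-focus side, from the interaction model."""

    left_slope: float
    left_se: float
    left_p: float
    right_slope: float
    right_se: float
    right_p: float
    interaction_coef: float
    interaction_p: float
    fit: FitResult


def slope_by_laterality(
    records: Iterable[SubjectRecord] | pd.DataFrame,
    covariate_mode: str | None = None,
) -> LateralitySlopes:
    """Per-side thickness-vs-duration slopes from the interaction model.

    The left slope is the duration coefficient; the right slope is the sum
    of the duration and interaction coefficients, with its standard error
    from the coefficient covariance (linear combination, hence exact).
    """
    from scipy import stats as _st

    spec = ModelSpec(
        predictors=("duration", "laterality", "duration_x_laterality"),
        covariate_mode=covariate_mode,
    )
    res = fit_thickness(records, spec)
    b_d = res.coef("duration")
    b_i = res.coef("duration:right")
    var_d = float(res.cov_params.loc["duration", "duration"])
    var_i = float(res.cov_params.loc["duration:right", "duration:right"])
    cov_di = float(res.cov_params.loc["duration", "duration:right"])
    right_slope = b_d + b_i
    right_se = float(np.sqrt(var_d + var_i + 2 * cov_di))
    left_se = res.se("duration")

    def _p(est, se):
        if se == 0:
            return float("nan")
        return float(2 * _st.t.sf(abs(est / se), res.df_resid))

    return LateralitySlopes(
        left_slope=b_d,
        left_se=left_se,
        left_p=_p(b_d, left_se),
        right_slope=right_slope,
        right_se=right_se,
        right_p=_p(right_slope, right_se),
        interaction_coef=b_i,
        interaction_p=res.p("duration:right"),
        fit=res,
    )


def tail_interaction(
    records: Iterable[SubjectRecord] | pd.DataFrame,
    covariate_mode: str | None = None,
) -> FitResult:
    """Duration x tail-sclerosis interaction among right-laterality subjects.

    Fits thickness ~ duration + has_tail + duration:has_tail (plus the
    optional age covariate) on the right-sided subgroup, probing whether
    posterior sclerosis accelerates the thickness decline.
    """
    df = _as_frame(records)
    df = df[df["laterality"] == "right"]
    predictors = ["duration", "has_tail", "duration_x_has_tail"]
    spec = ModelSpec(predictors=tuple(predictors), covariate_mode=covariate_mode)
    return fit_thickness(df, spec)
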