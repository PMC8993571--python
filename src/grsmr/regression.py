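"""Covariate-adjusted association models, tertile grouping and trend tests.

Two adjustment models mirror the cohort analysis: model 1 adjusts for age and
sex; model 2 adds waist-to-hip ratio. Both phenotypes are natural-log
transformed before modelling. Coefficients are unstandardized with classical
(non-robust) standard errors and fixed-multiplier 95% intervals (beta +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.96  # fixed normal multiplier for all reported intervals

MODEL1_COVARIATES = ("age", "sex")
MODEL2_COVARIATES = ("age", "sex", "whr")


@dataclass
class RegressionResult:
    """One term's estimate under one adjustment model.

    For linear fits ``beta`` is the unstandardized coefficient and the interval
    is beta +/- 1.96 se. For logistic fits ``beta`` is the odds ratio, ``se`` is
    the standard error of the log-odds coefficient, and the interval is
    exp(log-OR +/- 1.96 se).
    """

    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model_label: str
    scale: str = "linear"  # "linear" or "odds_ratio"


def ln_transform(values: pd.Series) -> tuple[pd.Series, int]:
    """Natural log, elementwise; non-positive entries become missing.

    Returns the transformed series and the count of non-positive values that
    were flagged as missing. Raises if nothing is transformable.
    """
    values = pd.to_numeric(values, errors="coerce")
    nonpositive = int(((values <= 0) & values.notna()).sum())
    usable = values.where(values > 0)
    if usable.notna().sum() == 0:
        raise ValueError("all values are non-positive or missing; nothing to log-transform")
    return np.log(usable), nonpositive


def _design(
    predictor: pd.Series, covariates: pd.DataFrame | None
) -> tuple[pd.DataFrame, str]:
    name = predictor.name or "x"
    parts = [predictor.rename(name)]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates)
    X = pd.concat(parts, axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X, name


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns: those whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _listwise(
    outcome: pd.Series, predictor: pd.Series, covariates: pd.DataFrame | None
) -> tuple[pd.Series, pd.Series, pd.DataFrame | None]:
    frame = pd.concat(
        [outcome.rename("__y"), predictor.rename(predictor.name or "x")], axis=1
    )
    if covariates is not None and covariates.shape[1] > 0:
        frame = pd.concat([frame, covariates], axis=1)
    frame = frame.dropna()
    y = frame["__y"]
    x = frame.iloc[:, 1]
    covs = frame.iloc[:, 2:] if frame.shape[1] > 2 else None
    return y, x, covs


def ols_fit(
    outcome: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    model_label: str = "model 2",
) -> RegressionResult:
    """Ordinary least squares; reports the predictor's coefficient.

    Listwise deletion of rows with any missing value among the used columns;
    classical standard errors; CI via the fixed 1.96 multiplier.
    """
    y, x, covs = _listwise(outcome, predictor, covariates)
    X, name = _design(x, covs)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} parameters")
    _check_full_rank(X)
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    idx = list(X.columns).index(name)
    beta = float(fit.params[idx])
    se = float(fit.bse[idx])
    return RegressionResult(
        term=name,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=float(fit.pvalues[idx]),
        n=int(fit.nobs),
        model_label=model_label,
    )


def logistic_fit(
    outcome: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    model_label: str = "model 2",
) -> RegressionResult:
    """Maximum-likelihood logistic regression; reports the predictor as an odds ratio."""
    y, x, covs = _listwise(outcome, predictor, covariates)
    classes = set(pd.unique(y.dropna()))
    if not classes.issubset({0, 1}) or len(classes) < 2:
        raise ValueError(f"outcome must contain both classes coded 0/1; saw {sorted(classes)}")
    X, name = _design(x, covs)
    _check_full_rank(X)
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y.to_numpy(), X.to_numpy()).fit(disp=0)
    except Exception as exc:  # separation warning-as-error or LinAlgError
        raise ValueError(f"logistic fit failed (possible perfect separation): {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise ValueError("logistic fit produced non-finite standard errors (perfect separation?)")
    idx = list(X.columns).index(name)
    log_or = float(fit.params[idx])
    se = float(fit.bse[idx])
    return RegressionResult(
        term=name,
        beta=float(np.exp(log_or)),
        se=se,
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p=float(fit.pvalues[idx]),
        n=int(fit.nobs),
        model_label=model_label,
        scale="odds_ratio",
    )


@dataclass
class TertileAssignment:
    """Thirds of a score's distribution: two interior cutpoints and Q1/Q2/Q3 labels."""

    variable: str
    cutpoints: tuple[float, float]
    labels: pd.Series  # values "Q1"/"Q2"/"Q3", NaN where the input was missing

    def indices(self) -> pd.Series:
        """Ordinal group index 1/2/3 (for linear-trend terms)."""
        return self.labels.map({"Q1": 1, "Q2": 2, "Q3": 3})


def assign_tertiles(values: pd.Series, variable: str | None = None) -> TertileAssignment:
    """Empirical-tertile grouping with ties at a cutpoint assigned downward.

    Cutpoints are the 1/3 and 2/3 empirical quantiles; an individual equal to a
    cutpoint goes to the lower group.
    """
    clean = values.dropna()
    if clean.nunique() < 3:
        raise ValueError(
            f"need at least 3 distinct values to form tertiles; got {clean.nunique()}"
        )
    q1, q2 = np.quantile(clean.to_numpy(), [1 / 3, 2 / 3])
    labels = pd.Series(
        np.select(
            [values <= q1, values <= q2, values.notna()],
            ["Q1", "Q2", "Q3"],
            default=None,
        ),
        index=values.index,
        dtype="object",
    )
    return TertileAssignment(
        variable=variable or (values.name or "value"),
        cutpoints=(float(q1), float(q2)),
        labels=labels,
    )


def trend_tests(
    cohort: pd.DataFrame,
    grouping: TertileAssignment,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Across-tertile trend tests: one-way ANOVA for continuous variables,
    Pearson chi-square for categorical ones."""
    groups = [g for g in ("Q1", "Q2", "Q3") if (grouping.labels == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty tertile groups")
    rows = []
    for var in continuous:
        samples = [
            cohort.loc[grouping.labels == g, var].dropna().to_numpy() for g in groups
        ]
        if any(len(s) == 0 for s in samples):
            raise ValueError(f"empty group for variable {var!r}")
        stat, p = stats.f_oneway(*samples)
        rows.append({"variable": var, "test": "anova", "statistic": float(stat), "p": float(p)})
    for var in categorical:
        table = pd.crosstab(grouping.labels, cohort[var])
        if (table.sum(axis=1) == 0).any():
            raise ValueError(f"empty group for variable {var!r}")
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"variable": var, "test": "chi-square", "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)


def ordinal_trend_fit(
    outcome: pd.Series,
    grouping: TertileAssignment,
    covariates: pd.DataFrame | None = None,
    model_label: str = "model 2",
) -> RegressionResult:
    """P-for-trend across tertiles: the group index 1/2/3 entered as a linear
    ordinal term in the adjusted regression."""
    idx = grouping.indices().astype(float).rename(f"{grouping.variable}_tertile_index")
    return ols_fit(outcome, idx, covariates, model_label=model_label)


def adjustment_set(
    cohort: pd.DataFrame,
    outcome_name: str,
    covariates: Iterable[str] = MODEL2_COVARIATES,
) -> pd.DataFrame:
    """Covariate frame with the self-adjustment rule applied.

    When the modelled outcome is itself a covariate it is dropped from the
    adjustment set, and adiposity measures (BMI, waist-to-hip ratio) are never
    co-adjusted: a BMI outcome drops WHR from the set as well.
    """
    keep = [c for c in covariates if c != outcome_name]
    if outcome_name == "bmi":
        keep = [c for c in keep if c != "whr"]
    if outcome_name == "whr":
        keep = [c for c in keep if c != "bmi"]
    return cohort[keep]


def tertile_characteristics(
    cohort: pd.DataFrame,
    grouping: TertileAssignment,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-tertile mean +/- SD (continuous) or percentage (categorical) with trend p."""
    trend = trend_tests(cohort, grouping, continuous, categorical).set_index("variable")
    rows = []
    for var in continuous:
        row = {"variable": var}
        for g in ("Q1", "Q2", "Q3"):
            vals = cohort.loc[grouping.labels == g, var].dropna()
            row[g] = f"{vals.mean():.2f} +/- {vals.std(ddof=1):.2f}"
        row["p_trend"] = trend.loc[var, "p"]
        rows.append(row)
    for var in categorical:
        row = {"variable": f"{var} (%)"}
        for g in ("Q1", "Q2", "Q3"):
            vals = cohort.loc[grouping.labels == g, var].dropna()
            row[g] = f"{100.0 * vals.mean():.1f}"
        row["p_trend"] = trend.loc[var, "p"]
        rows.append(row)
    counts = {g: int((grouping.labels == g).sum()) for g in ("Q1", "Q2", "Q3")}
    rows.insert(0, {"variable": "N", **{g: str(c) for g, c in counts.items()}, "p_trend": np.nan})
    return pd.DataFrame(rows)
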