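"""Bidirectional allele-score Mendelian randomization by the IV ratio method.

Each direction uses a single weighted genetic risk score (GRS) as the
instrument. With beta_exp the coefficient of the GRS on the ln-exposure and
beta_out its coefficient on the ln-outcome (both from the same covariate-
adjusted linear model), the causal effect of exposure on outcome is the Wald
ratio

    beta_IV = beta_out / beta_exp,

with first-order (delta-method) standard error

    se_IV = |beta_IV| * sqrt((se_exp/beta_exp)^2 + (se_out/beta_out)^2)

and symmetric normal 95% interval beta_IV +/- 1.96 se_IV. Instrument strength
is summarised by F = R^2 (n-2) / (1-R^2), where R^2 is the incremental
variance in the exposure explained by the GRS over the covariates; F below 10
is flagged as a weak instrument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import genetics
from .genetics import GenotypeMatrix, SNPSpec, weighted_grs
from .regression import (
    MODEL2_COVARIATES,
    Z95,
    RegressionResult,
    adjustment_set,
    logistic_fit,
    ols_fit,
)

WEAK_INSTRUMENT_F = 10.0
#: Denominators smaller than this are treated as a null first stage rather than
#: allowed to produce an astronomically large ratio.
MIN_DENOMINATOR = 1e-10

FORWARD = "25ohd->tpoab"
REVERSE = "tpoab->25ohd"


@dataclass
class InstrumentDiagnostics:
    """First-stage strength of one allele score.

    ``r_squared`` is the incremental R^2 of the GRS over the adjustment
    covariates; ``f_statistic`` applies the R^2-based approximation above.
    """

    grs_label: str
    r_squared: float
    n: int
    f_statistic: float

    @property
    def weak(self) -> bool:
        return self.f_statistic < WEAK_INSTRUMENT_F


@dataclass
class IVEstimate:
    """Wald-ratio causal estimate for one direction with delta-method interval."""

    direction: str
    beta_iv: float
    se_iv: float
    ci_low: float
    ci_high: float
    exposure_fit: RegressionResult | None = None
    outcome_fit: RegressionResult | None = None
    diagnostics: InstrumentDiagnostics | None = None

    @property
    def weak_instrument(self) -> bool:
        return self.diagnostics is not None and self.diagnostics.weak


def f_statistic(r_squared: float, n: int) -> float:
    """Instrument-strength F approximated from the explained variance fraction."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError(f"r_squared must be in [0, 1), got {r_squared}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    return r_squared * (n - 2) / (1.0 - r_squared)


def wald_ratio(beta_grs_outcome: float, beta_grs_exposure: float) -> float:
    """Causal effect as the ratio of reduced-form coefficients."""
    if abs(beta_grs_exposure) < MIN_DENOMINATOR:
        raise ZeroDivisionError(
            "GRS->exposure coefficient is (numerically) zero: the instrument has "
            "no first stage, the ratio estimate is undefined"
        )
    return beta_grs_outcome / beta_grs_exposure


def delta_se(
    beta_iv: float,
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
) -> tuple[float, float, float]:
    """Delta-method SE and 95% CI for a Wald ratio.

    Uses the first-order propagation of the two component coefficients'
    sampling errors. When the numerator coefficient is exactly zero the
    general formula is indeterminate (0 * inf); the limit form
    se_IV = |se_out / beta_exp| is used instead.
    """
    if se_exp < 0 or se_out < 0:
        raise ValueError("standard errors must be non-negative")
    if abs(beta_exp) < MIN_DENOMINATOR:
        raise ZeroDivisionError("GRS->exposure coefficient is (numerically) zero")
    if beta_out == 0.0:
        se_iv = abs(se_out / beta_exp)
    else:
        se_iv = abs(beta_iv) * np.sqrt((se_exp / beta_exp) ** 2 + (se_out / beta_out) ** 2)
    return float(se_iv), float(beta_iv - Z95 * se_iv), float(beta_iv + Z95 * se_iv)


def iv_from_components(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    direction: str = FORWARD,
    exposure_fit: RegressionResult | None = None,
    outcome_fit: RegressionResult | None = None,
    diagnostics: InstrumentDiagnostics | None = None,
) -> IVEstimate:
    """Assemble an IV estimate from the two reduced-form coefficients.

    This is the injection surface: published (or externally fitted) GRS->exposure
    and GRS->outcome coefficients can be fed in directly, bypassing the fitting
    stage.
    """
    beta_iv = wald_ratio(beta_out, beta_exp)
    se_iv, lo, hi = delta_se(beta_iv, beta_exp, se_exp, beta_out, se_out)
    return IVEstimate(
        direction=direction,
        beta_iv=beta_iv,
        se_iv=se_iv,
        ci_low=lo,
        ci_high=hi,
        exposure_fit=exposure_fit,
        outcome_fit=outcome_fit,
        diagnostics=diagnostics,
    )


def instrument_diagnostics(
    exposure: pd.Series,
    grs: pd.Series,
    covariates: pd.DataFrame | None,
    grs_label: str,
) -> InstrumentDiagnostics:
    """Incremental-R^2 instrument strength of a GRS for its exposure."""
    frame = pd.concat([exposure.rename("__y"), grs.rename("__g")], axis=1)
    if covariates is not None and covariates.shape[1] > 0:
        frame = pd.concat([frame, covariates], axis=1)
    frame = frame.dropna()
    y = frame["__y"].to_numpy()
    X_full = sm.add_constant(frame.drop(columns="__y").to_numpy())
    full = sm.OLS(y, X_full).fit()
    if frame.shape[1] > 2:
        X_red = sm.add_constant(frame.drop(columns=["__y", "__g"]).to_numpy())
        reduced = sm.OLS(y, X_red).fit()
        r2 = max(0.0, float(full.rsquared - reduced.rsquared))
    else:
        r2 = float(full.rsquared)
    n = int(full.nobs)
    return InstrumentDiagnostics(
        grs_label=grs_label, r_squared=r2, n=n, f_statistic=f_statistic(r2, n)
    )


def _direction_estimate(
    ln_exposure: pd.Series,
    ln_outcome: pd.Series,
    grs: pd.Series,
    covariates: pd.DataFrame,
    direction: str,
    grs_label: str,
) -> IVEstimate:
    exposure_fit = ols_fit(ln_exposure, grs, covariates)
    outcome_fit = ols_fit(ln_outcome, grs, covariates)
    diag = instrument_diagnostics(ln_exposure, grs, covariates, grs_label)
    return iv_from_components(
        beta_exp=exposure_fit.beta,
        se_exp=exposure_fit.se,
        beta_out=outcome_fit.beta,
        se_out=outcome_fit.se,
        direction=direction,
        exposure_fit=exposure_fit,
        outcome_fit=outcome_fit,
        diagnostics=diag,
    )


def bidirectional_mr(
    cohort: pd.DataFrame,
    panel: Iterable[SNPSpec],
    covariates: Sequence[str] = MODEL2_COVARIATES,
) -> dict[str, IVEstimate]:
    """Both causal directions from a filtered cohort table.

    Forward: the vitamin-D GRS instruments ln 25(OH)D as exposure, ln TPOAb as
    outcome. Reverse: the TPOAb GRS instruments ln TPOAb as exposure,
    ln 25(OH)D as outcome. Both component regressions use the same covariate
    set (age, sex, waist-to-hip ratio by default).
    """
    panel = genetics.validate_panel(panel)
    gm = GenotypeMatrix(cohort[[s.rsid for s in panel]])
    ln_vd = np.log(cohort["vd"].where(cohort["vd"] > 0))
    ln_tpo = np.log(cohort["tpoab"].where(cohort["tpoab"] > 0))
    covs = cohort[list(covariates)]
    vd_grs = weighted_grs(gm, panel, genetics.VITAMIN_D).grs.rename("vd_grs")
    tpo_grs = weighted_grs(gm, panel, genetics.TPOAB).grs.rename("tpoab_grs")
    return {
        FORWARD: _direction_estimate(ln_vd, ln_tpo, vd_grs, covs, FORWARD, "vd_grs"),
        REVERSE: _direction_estimate(ln_tpo, ln_vd, tpo_grs, covs, REVERSE, "tpoab_grs"),
    }


DEFAULT_CONFOUNDERS = ("age", "whr", "bmi", "sex")


def pleiotropy_screen(
    cohort: pd.DataFrame,
    panel: Iterable[SNPSpec],
    confounders: Sequence[str] = DEFAULT_CONFOUNDERS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Instrument-confounder association screen.

    Each SNP (additive dosage) and each GRS is regressed against every listed
    confounder: linear models for continuous confounders, logistic for sex.
    The adjustment set follows the self-adjustment rule (the modelled outcome
    is dropped from its own adjustment; BMI and WHR are never co-adjusted).
    Rows with p < alpha are flagged as potentially pleiotropic.
    """
    panel = genetics.validate_panel(panel)
    gm = GenotypeMatrix(cohort[[s.rsid for s in panel]])
    instruments: list[tuple[str, pd.Series]] = [
        (s.rsid, cohort[s.rsid].rename(s.rsid)) for s in panel
    ]
    instruments.append(("vd_grs", weighted_grs(gm, panel, genetics.VITAMIN_D).grs.rename("vd_grs")))
    instruments.append(("tpoab_grs", weighted_grs(gm, panel, genetics.TPOAB).grs.rename("tpoab_grs")))

    rows = []
    for name, values in instruments:
        for conf in confounders:
            covs = adjustment_set(cohort, conf)
            if conf == "sex":
                res = logistic_fit(cohort[conf], values, covs)
            else:
                res = ols_fit(cohort[conf], values, covs)
            rows.append(
                {
                    "instrument": name,
                    "confounder": conf,
                    "scale": res.scale,
                    "estimate": res.beta,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "flagged": res.p < alpha,
                }
            )
    return pd.DataFrame(rows)


def iv_from_coefficient_table(table: pd.DataFrame) -> dict[str, IVEstimate]:
    """IV estimates from a long table of precomputed component coefficients.

    Expects columns ``direction``, ``role`` ("exposure" or "outcome"),
    ``beta``, ``se``, with one exposure and one outcome row per direction —
    the format used to re-estimate causal effects from published GRS
    regression coefficients without individual-level data.
    """
    required = {"direction", "role", "beta", "se"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"coefficient table is missing columns: {sorted(missing)}")
    estimates: dict[str, IVEstimate] = {}
    for direction, block in table.groupby("direction", sort=False):
        roles = block.set_index("role")
        if not {"exposure", "outcome"}.issubset(roles.index):
            raise ValueError(
                f"direction {direction!r} needs one 'exposure' and one 'outcome' row"
            )
        estimates[str(direction)] = iv_from_components(
            beta_exp=float(roles.loc["exposure", "beta"]),
            se_exp=float(roles.loc["exposure", "se"]),
            beta_out=float(roles.loc["outcome", "beta"]),
            se_out=float(roles.loc["outcome", "se"]),
            direction=str(direction),
        )
    return estimates


def published_coefficients() -> pd.DataFrame:
    """The shipped table of published model-2 GRS regression coefficients."""
    from importlib import resources

    ref = resources.files("grsmr.data").joinpath("published_grs_coefficients.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def mr_report(estimates: dict[str, IVEstimate]) -> pd.DataFrame:
    """Flat per-direction table of the IV estimates (analogue of a forest row)."""
    rows = []
    for direction, est in estimates.items():
        rows.append(
            {
                "direction": direction,
                "beta_iv": est.beta_iv,
                "se_iv": est.se_iv,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "f_statistic": est.diagnostics.f_statistic if est.diagnostics else np.nan,
                "n": est.diagnostics.n if est.diagnostics else (est.exposure_fit.n if est.exposure_fit else np.nan),
                "weak_instrument": est.weak_instrument,
            }
        )
    return pd.DataFrame(rows)
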