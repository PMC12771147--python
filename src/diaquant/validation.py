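"""Analytical validation: recovery, precision, detection limits, diagnostics.

Implements the standard figures of merit for validating a quantitative
method:

* recovery of a known spike, ``R = (C1 - C2) / C3 * 100`` with acceptance in
  [80 %, 120 %];
* precision as the coefficient of variation, ``CV = SD / mean * 100``,
  accepted when at most 20 % (the bound is an upper limit on dispersion);
* detection and quantification limits ``LOD = 3.3 sigma / m`` and
  ``LOQ = 10 sigma / m``, where sigma is the standard deviation of ten blank
  measurements or of the lowest calibration level and m the calibration
  slope (use ``slope_m=1`` when sigma is already in concentration units);
* regression diagnostics on the calibration line: significance by ANOVA,
  homoscedasticity by Breusch-Pagan, residual normality by Shapiro-Wilk.

Sample standard deviations use the n-1 denominator throughout, as usual for
small replicate groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "RecoveryResult",
    "DetectionLimits",
    "DiagnosticsReport",
    "recovery",
    "coefficient_of_variation",
    "detection_limits",
    "regression_anova",
    "breusch_pagan",
    "shapiro_wilk",
    "diagnose",
]

RECOVERY_RANGE = (80.0, 120.0)  # acceptable recovery, percent
CV_LIMIT = 20.0  # maximum acceptable coefficient of variation, percent


@dataclass(frozen=True)
class RecoveryResult:
    """Spike-recovery outcome; all concentrations in mg/mL."""

    c1_fortified: float
    c2_unfortified: float
    c3_added: float
    recovery_pct: float
    passes: bool


@dataclass(frozen=True)
class DetectionLimits:
    """LOD/LOQ pair; the ratio loq/lod is 10/3.3 by construction."""

    sigma: float
    slope_m: float
    lod: float
    loq: float


@dataclass(frozen=True)
class DiagnosticsReport:
    """Regression diagnostics with pass/fail flags at the chosen alpha."""

    anova_f: float
    anova_p: float
    bp_stat: float
    bp_p: float
    sw_w: float
    sw_p: float
    alpha: float = 0.05

    @property
    def significant_regression(self) -> bool:
        return self.anova_p < self.alpha

    @property
    def homoscedastic(self) -> bool:
        return self.bp_p > self.alpha

    @property
    def normal_residuals(self) -> bool:
        return self.sw_p > self.alpha


def recovery(c1: float, c2: float, c3: float) -> RecoveryResult:
    """Spike recovery ``(c1 - c2) / c3 * 100`` with the [80, 120] % gate.

    *c1* is the concentration measured in the fortified sample, *c2* in the
    unfortified sample and *c3* the concentration added.
    """
    if c3 <= 0:
        raise ValueError(f"added concentration must be positive, got {c3}")
    pct = (c1 - c2) / c3 * 100.0
    return RecoveryResult(
        c1_fortified=c1,
        c2_unfortified=c2,
        c3_added=c3,
        recovery_pct=pct,
        passes=RECOVERY_RANGE[0] <= pct <= RECOVERY_RANGE[1],
    )


def coefficient_of_variation(values) -> float:
    """Sample coefficient of variation in percent, ``SD(n-1) / mean * 100``."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two values")
    mean = float(values.mean())
    if mean == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return float(values.std(ddof=1)) / mean * 100.0


def detection_limits(sigma: float, slope_m: float = 1.0) -> DetectionLimits:
    """LOD and LOQ from the blank/low-level dispersion and calibration slope.

    With *sigma* in response units divide by the slope; with *sigma* already
    in concentration units leave ``slope_m=1``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if slope_m <= 0:
        raise ValueError(f"slope must be positive, got {slope_m}")
    return DetectionLimits(
        sigma=sigma,
        slope_m=slope_m,
        lod=3.3 * sigma / slope_m,
        loq=10.0 * sigma / slope_m,
    )


def regression_anova(fit) -> tuple[float, float]:
    """Significance F test of a fitted calibration line.

    ``F = MS_regression / MS_residual`` with (1, n-2) degrees of freedom.
    An exact fit (zero residual variance) is reported as ``(inf, 0.0)``.
    """
    residuals = np.asarray(fit.residuals, dtype=float)
    fitted = np.asarray(fit.fitted, dtype=float)
    n = residuals.size
    if n < 3:
        raise ValueError("need at least three observations")
    ss_reg = float(np.sum((fitted - fitted.mean()) ** 2))
    ss_res = float(np.sum(residuals**2))
    if ss_res == 0.0:
        return float("inf"), 0.0
    f_stat = ss_reg / (ss_res / (n - 2))
    return f_stat, float(stats.f.sf(f_stat, 1, n - 2))


def breusch_pagan(residuals, predictors) -> tuple[float, float]:
    """Breusch-Pagan LM test for heteroscedastic residuals.

    Squared residuals (scaled by their mean) are regressed on the predictors;
    the statistic is ``n * R^2`` of that auxiliary regression, chi-squared
    with as many degrees of freedom as predictors.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    predictors = np.asarray(predictors, dtype=float)
    if predictors.ndim == 1:
        predictors = predictors[:, None]
    n = residuals.size
    if n < 4:
        raise ValueError("need at least four observations")
    if predictors.shape[0] != n:
        raise ValueError("residuals and predictors lengths differ")
    if not np.all(predictors.std(axis=0) > 0):
        raise ValueError("a predictor is constant; auxiliary regression degenerate")
    if np.all(residuals == residuals[0]):
        return 0.0, 1.0
    exog = np.column_stack([np.ones(n), predictors])
    lm, lm_p, _, _ = het_breuschpagan(residuals, exog)
    return float(lm), float(lm_p)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value for residual normality."""
    values = np.asarray(values, dtype=float).ravel()
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk supports 3 to 5000 observations")
    if np.ptp(values) == 0.0:
        raise ValueError("all values identical; W undefined")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def diagnose(fit, alpha: float = 0.05) -> DiagnosticsReport:
    """Full diagnostic panel for a fitted calibration line.

    Runs the regression ANOVA, Breusch-Pagan (against the concentration
    levels) and Shapiro-Wilk on the residuals of *fit*.
    """
    f_stat, f_p = regression_anova(fit)
    bp_stat, bp_p = breusch_pagan(fit.residuals, fit.model.concentration)
    sw_w, sw_p = shapiro_wilk(fit.residuals)
    return DiagnosticsReport(
        anova_f=f_stat,
        anova_p=f_p,
        bp_stat=bp_stat,
        bp_p=bp_p,
        sw_w=sw_w,
        sw_p=sw_p,
        alpha=alpha,
    )
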