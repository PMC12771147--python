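"""Univariate and PLS1 calibration models mapping colour signals to concentration.

Two model classes follow the model/results pattern: construct a model from
data, call :meth:`fit`, and work with the returned results object.

* :class:`LinearCalibration` — classical univariate calibration.  The line
  ``response = m * concentration + b`` is fitted by ordinary least squares;
  unknowns are quantified by inverse prediction ``c = (response - b) / m``.
* :class:`PLSCalibration` — PLS1 regression fitted by NIPALS on mean-centred
  data, with the latent-variable count chosen by leave-one-out
  cross-validation under a parsimony rule when not given.

Negative predicted concentrations (signal brighter than the blank) are
returned as-is, never clipped; clipping would bias validation metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SingularDesignError",
    "DegenerateFitError",
    "LinearCalibration",
    "LinearCalibrationResults",
    "PLSCalibration",
    "PLSCalibrationResults",
    "loo_rmsecv",
    "select_n_components",
    "CalibrationMetrics",
    "calibration_metrics",
]

#: the six calibration levels of the default analytical curve, mg/mL
DEFAULT_LEVELS = (2.00e-4, 5.00e-4, 1.00e-3, 5.00e-3, 1.00e-2, 2.00e-2)


class SingularDesignError(ValueError):
    """All concentrations identical: the calibration line is undefined."""


class DegenerateFitError(ValueError):
    """Constant responses: R-squared is undefined (zero total sum of squares)."""


# ---------------------------------------------------------------------------
# univariate calibration
# ---------------------------------------------------------------------------


class LinearCalibration:
    """Ordinary least-squares calibration line for a single response channel.

    Parameters
    ----------
    concentration : array-like, shape (n,)
        Analyte concentrations of the standards, mg/mL.
    response : array-like, shape (n,)
        Measured response (absorbance, reflectance, channel mean, ...).
    """

    def __init__(self, concentration, response) -> None:
        self.concentration = np.asarray(concentration, dtype=float).ravel()
        self.response = np.asarray(response, dtype=float).ravel()
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response lengths differ")
        if self.concentration.size < 2:
            raise ValueError("need at least two observations")
        if np.unique(self.concentration).size < 2:
            raise SingularDesignError("all concentrations are identical")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, concentration: str = "concentration", response: str = "response"
    ) -> "LinearCalibration":
        return cls(data[concentration].to_numpy(), data[response].to_numpy())

    def fit(self) -> "LinearCalibrationResults":
        x, y = self.concentration, self.response
        sstot = float(np.sum((y - y.mean()) ** 2))
        if sstot == 0.0:
            raise DegenerateFitError("responses are constant; R^2 undefined")
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        intercept = float(y.mean() - slope * x.mean())
        fitted = slope * x + intercept
        residuals = y - fitted
        r_squared = 1.0 - float(np.sum(residuals**2)) / sstot
        return LinearCalibrationResults(
            model=self,
            slope=slope,
            intercept=intercept,
            r_squared=r_squared,
            fitted=fitted,
            residuals=residuals,
        )


@dataclass
class LinearCalibrationResults:
    """Fitted calibration line.

    ``slope`` has units of response per (mg/mL); ``r_squared`` is
    ``1 - SSres/SStot`` exactly.
    """

    model: LinearCalibration
    slope: float
    intercept: float
    r_squared: float
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def nobs(self) -> int:
        return self.model.concentration.size

    def predict(self, response) -> np.ndarray:
        """Inverse prediction: concentration from measured response.

        Negative values indicate a signal beyond the blank and are returned
        unclipped.
        """
        response = np.atleast_1d(np.asarray(response, dtype=float))
        return (response - self.intercept) / self.slope

    def predict_response(self, concentration) -> np.ndarray:
        """Forward evaluation of the calibration line."""
        concentration = np.atleast_1d(np.asarray(concentration, dtype=float))
        return self.slope * concentration + self.intercept

    def summary(self) -> str:
        lines = [
            "Linear calibration (OLS)",
            "-" * 40,
            f"n observations      {self.nobs:>12d}",
            f"slope (resp/mg/mL)  {self.slope:>12.6g}",
            f"intercept           {self.intercept:>12.6g}",
            f"R-squared           {self.r_squared:>12.6f}",
            f"residual SD         {float(np.std(self.residuals, ddof=2)):>12.6g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the standards with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.concentration, self.model.response
        ax.plot(x, y, "o", label="standards")
        xs = np.linspace(x.min(), x.max(), 100)
        ax.plot(xs, self.predict_response(xs), "-", label=f"fit (R$^2$={self.r_squared:.4f})")
        ax.set_xlabel("concentration (mg/mL)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# PLS1 / NIPALS
# ---------------------------------------------------------------------------


class PLSCalibration:
    """PLS1 calibration fitted by NIPALS.

    Parameters
    ----------
    X : array-like, shape (n, p)
        Feature matrix, one row per standard (e.g. the three blank-referenced
        reflectances, optionally augmented with the raw channel means).
    y : array-like, shape (n,)
        Concentrations, mg/mL.
    n_components : int, optional
        Latent-variable count.  When omitted, :meth:`fit` selects it by
        leave-one-out cross-validation with a 5 %-of-minimum parsimony rule.
    scale : bool
        Divide each column by its standard deviation after centring.  Off by
        default: reflectance channels already share one scale.
    """

    def __init__(self, X, y, n_components: int | None = None, scale: bool = False) -> None:
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        n, p = self.X.shape
        if self.y.size != n:
            raise ValueError("X and y lengths differ")
        if n < 3:
            raise ValueError("need at least three observations")
        if not np.any(self.X.var(axis=0) > 0):
            raise DegenerateFitError("X has no column with positive variance")
        max_lv = min(n - 1, p)
        if n_components is not None and not (1 <= n_components <= max_lv):
            raise ValueError(
                f"n_components must be in [1, {max_lv}] for n={n}, p={p}; got {n_components}"
            )
        self.n_components = n_components
        self.scale = scale

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        feature_columns,
        concentration: str = "concentration",
        **kwargs,
    ) -> "PLSCalibration":
        return cls(data[list(feature_columns)].to_numpy(), data[concentration].to_numpy(), **kwargs)

    def fit(self) -> "PLSCalibrationResults":
        n, p = self.X.shape
        if self.n_components is None:
            rmsecv = loo_rmsecv(self.X, self.y, scale=self.scale)
            n_lv = _parsimonious_choice(rmsecv)
        else:
            n_lv, rmsecv = self.n_components, None
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        x_scale = self.X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
        Xc = (self.X - x_mean) / x_scale
        W, P, q, T = _nipals_pls1(Xc, self.y - y_mean, n_lv)
        # b = W (P'W)^{-1} q maps centred X directly to centred y
        coef = W @ np.linalg.solve(P.T @ W, q)
        results = PLSCalibrationResults(
            model=self,
            n_components=n_lv,
            x_mean=x_mean,
            y_mean=y_mean,
            x_scale=x_scale,
            weights=W,
            x_loadings=P,
            y_loadings=q,
            coef=coef,
            rmsecv=rmsecv,
        )
        results.fitted = results.predict(self.X)
        results.residuals = self.y - results.fitted
        return results


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS deflation for a single response.

    Per latent variable: weight w ∝ X'y (unit norm), scores t = Xw, X-loading
    p = X't/(t't), y-loading q = y't/(t't), then deflate X and y.
    """
    X, y = Xc.copy(), yc.copy()
    p_dim = X.shape[1]
    W = np.zeros((p_dim, n_lv))
    P = np.zeros((p_dim, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((X.shape[0], n_lv))
    for a in range(n_lv):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0.0:  # deflated X carries no covariance with y
            w = np.zeros(p_dim)
            w[a % p_dim] = 1.0
        else:
            w = w / norm
        t = X @ w
        tt = float(t @ t)
        if tt == 0.0:
            W[:, a] = w
            continue
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T


@dataclass
class PLSCalibrationResults:
    """Fitted PLS1 model: centring parameters, weights, loadings, coefficients."""

    model: PLSCalibration
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    rmsecv: np.ndarray | None = None
    fitted: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    residuals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def _centred(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"feature dimension {X_new.shape[1]} does not match model ({self.x_mean.size})"
            )
        return (X_new - self.x_mean) / self.x_scale

    def predict(self, X_new) -> np.ndarray:
        """Predicted concentrations via the assembled regression vector."""
        return self.y_mean + self._centred(X_new) @ self.coef

    def predict_via_deflation(self, X_new) -> np.ndarray:
        """Predicted concentrations by sequential latent-variable deflation.

        Numerically equivalent to :meth:`predict`; kept as an internal
        consistency route.
        """
        Xd = self._centred(X_new)
        yhat = np.full(Xd.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xd @ self.weights[:, a]
            yhat = yhat + self.y_loadings[a] * t
            Xd = Xd - np.outer(t, self.x_loadings[:, a])
        return yhat

    def summary(self) -> str:
        lines = [
            "PLS1 calibration (NIPALS)",
            "-" * 40,
            f"n observations      {self.model.X.shape[0]:>12d}",
            f"n features          {self.model.X.shape[1]:>12d}",
            f"latent variables    {self.n_components:>12d}",
            f"column scaling      {'on' if self.model.scale else 'off':>12s}",
        ]
        if self.rmsecv is not None:
            lines.append("LOO RMSECV by LV    "
                         + ", ".join(f"{v:.3g}" for v in self.rmsecv))
        if self.residuals is not None:
            rmsec = float(np.sqrt(np.mean(self.residuals**2)))
            lines.append(f"RMSEC (mg/mL)       {rmsec:>12.6g}")
        lines.append("regression vector   "
                     + ", ".join(f"{v:.4g}" for v in self.coef))
        return "\n".join(lines)


def loo_rmsecv(X, y, max_components: int | None = None, scale: bool = False) -> np.ndarray:
    """Leave-one-out RMSECV for each candidate latent-variable count.

    Deterministic given the data: every observation is left out once and the
    model refitted on the remainder.  Returns an array of length
    ``max_components`` (default ``min(n-1, p)``), entry ``a-1`` holding the
    RMSECV of an ``a``-component model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cap = min(n - 2, p)  # each LOO fold has n-1 rows, so at most n-2 components
    if max_components is None:
        max_components = cap
    if not (1 <= max_components <= cap):
        raise ValueError(f"max_components must be in [1, {cap}]")
    press = np.zeros(max_components)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        for a in range(1, max_components + 1):
            fit = PLSCalibration(X[mask], y[mask], n_components=a, scale=scale).fit()
            press[a - 1] += float((fit.predict(X[i : i + 1])[0] - y[i]) ** 2)
    return np.sqrt(press / n)


def select_n_components(
    X, y, max_components: int | None = None, scale: bool = False, parsimony: float = 0.05
) -> int:
    """Smallest LV count whose LOO RMSECV is within *parsimony* of the minimum.

    The 5 % default trades a marginal cross-validation gain for a simpler
    model, and makes the choice deterministic and reproducible.
    """
    rmsecv = loo_rmsecv(X, y, max_components=max_components, scale=scale)
    return _parsimonious_choice(rmsecv, parsimony)


def _parsimonious_choice(rmsecv: np.ndarray, parsimony: float = 0.05) -> int:
    threshold = (1.0 + parsimony) * float(rmsecv.min())
    return int(np.argmax(rmsecv <= threshold)) + 1


# ---------------------------------------------------------------------------
# figures of merit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationMetrics:
    """Figures of merit of a calibration.

    ``rmsec``/``rmsep`` and ``bias`` are in mg/mL; ``relative_error_pct`` is
    the mean absolute percentage error against the reference concentrations
    (on the validation set when one is supplied, else on the calibration set,
    with the calibration-set value always reported separately).
    """

    rmsec: float
    r_squared: float
    relative_error_cal_pct: float
    rmsep: float | None = None
    bias: float | None = None
    relative_error_pct: float | None = None

    def as_dict(self) -> dict:
        return {
            "rmsec": self.rmsec,
            "rmsep": self.rmsep,
            "bias": self.bias,
            "relative_error_pct": self.relative_error_pct,
            "relative_error_cal_pct": self.relative_error_cal_pct,
            "r_squared": self.r_squared,
        }


def _mape_pct(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    nonzero = y_true != 0
    if not np.all(nonzero):
        warnings.warn("zero reference concentration excluded from relative error")
    if not np.any(nonzero):
        return float("nan")
    return float(np.mean(np.abs(y_pred[nonzero] - y_true[nonzero]) / y_true[nonzero]) * 100.0)


def calibration_metrics(results, X_cal, y_cal, X_val=None, y_val=None) -> CalibrationMetrics:
    """RMSEC, RMSEP, bias, relative error (%) and R-squared for a fitted model.

    *results* is any fitted results object with a ``predict`` method mapping
    features to concentration.  RMSEC is computed on the calibration set;
    RMSEP and bias require a validation set and are ``None`` without one.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    yhat_cal = np.asarray(results.predict(X_cal), dtype=float).ravel()
    rmsec = float(np.sqrt(np.mean((yhat_cal - y_cal) ** 2)))
    sstot = float(np.sum((y_cal - y_cal.mean()) ** 2))
    r_squared = 1.0 - float(np.sum((y_cal - yhat_cal) ** 2)) / sstot if sstot > 0 else float("nan")
    re_cal = _mape_pct(y_cal, yhat_cal)
    rmsep = bias = re_val = None
    if X_val is not None and y_val is not None and len(np.atleast_1d(y_val)) > 0:
        y_val = np.asarray(y_val, dtype=float).ravel()
        yhat_val = np.asarray(results.predict(X_val), dtype=float).ravel()
        rmsep = float(np.sqrt(np.mean((yhat_val - y_val) ** 2)))
        bias = float(np.mean(yhat_val - y_val))
        re_val = _mape_pct(y_val, yhat_val)
    return CalibrationMetrics(
        rmsec=rmsec,
        rmsep=rmsep,
        bias=bias,
        relative_error_pct=re_val,
        relative_error_cal_pct=re_cal,
        r_squared=r_squared,
    )
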