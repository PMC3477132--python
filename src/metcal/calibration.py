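"""Random-coefficients count->MET calibration.

The calibration model is a linear mixed model

    MET_ij = (a + alpha_i) + (b + beta_i) * counts_ij + e_ij

with fixed intercept/slope (a, b), participant-level random intercept and
slope (alpha_i, beta_i, mutually independent), and residual e_ij.  It is fit
by maximum likelihood on the equation-development group.  Goodness of fit is
summarized by Lin's concordance correlation coefficient between observed MET
and the population-level (fixed-effects) prediction, and by the standard
error of the estimate.  Intensity thresholds follow by inverting the fixed
line at the moderate (3 MET) and vigorous (6 MET) anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "IntensityAnchors",
    "CalibrationFit",
    "CalibrationError",
    "fit_random_coefficients",
    "concordance_cc",
    "standard_error_estimate",
    "solve_threshold",
]

# Counts are rescaled before fitting so the slope is O(1) for the optimizer.
_COUNT_SCALE = 1000.0


class CalibrationError(RuntimeError):
    """Raised for degenerate designs or non-convergent fits."""


@dataclass(frozen=True)
class IntensityAnchors:
    """MET anchors separating intensity bands (moderate 3-5.99, vigorous 6+)."""

    moderate_met: float = 3.0
    vigorous_met: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.moderate_met < self.vigorous_met:
            raise ValueError("need 0 < moderate_met < vigorous_met")


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted random-coefficients calibration.

    Slope units are MET per count/15 s; variance components are on the MET
    scale.  ``ccc`` and ``see`` compare observations with the fixed-effects
    prediction over the fitting data.
    """

    fixed_intercept: float
    fixed_slope: float
    fixed_slope_se: float
    random_intercept_var: float
    random_slope_var: float
    residual_var: float
    ccc: float
    see: float
    n_obs: int
    n_participants: int
    converged: bool

    def predict(self, counts) -> np.ndarray:
        """Population-level predicted MET at the given counts/15 s."""
        return self.fixed_intercept + self.fixed_slope * np.asarray(counts, float)


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        pid = data.iloc[:, 0].to_numpy()
        counts = data.iloc[:, 1].to_numpy(float)
        met = data.iloc[:, 2].to_numpy(float)
    else:
        pid = np.asarray([r[0] for r in data])
        counts = np.asarray([r[1] for r in data], float)
        met = np.asarray([r[2] for r in data], float)
    return pid, counts, met


def fit_random_coefficients(data, covariates: pd.DataFrame | None = None) -> CalibrationFit:
    """Fit the mixed calibration model to ``(participant_id, counts, met)`` rows.

    Parameters
    ----------
    data
        Iterable of ``(participant_id, counts, met)`` triples or a DataFrame
        with those columns first.  Needs >= 2 participants, each with >= 2
        distinct count values.
    covariates
        Optional extra fixed-effect columns (e.g. age/height/weight), row
        aligned with ``data``; used for covariate screening.

    Notes
    -----
    Fitting is maximum likelihood with a diagonal random-effects covariance
    (independent random intercept and slope).  Data lying exactly on one
    line (zero residual) sit on the boundary of the variance parameter
    space where the likelihood is improper, and are handled by a pooled
    least-squares fast path with zero variance components.
    """
    pid, counts, met = _as_arrays(data)
    if len(counts) != len(met) or len(counts) == 0:
        raise CalibrationError("empty or mismatched calibration data")
    uniq = pd.unique(pid)
    if len(uniq) < 2:
        raise CalibrationError("need at least 2 participants")
    for p in uniq:
        if len(np.unique(counts[pid == p])) < 2:
            raise CalibrationError(f"participant {p!r} has < 2 distinct count values")

    x = counts / _COUNT_SCALE
    exog = np.column_stack([np.ones_like(x), x])
    names = ["intercept", "counts_k"]
    if covariates is not None:
        if len(covariates) != len(x):
            raise CalibrationError("covariates not aligned with data")
        exog = np.column_stack([exog, covariates.to_numpy(float)])
        names += list(covariates.columns)

    # Exact-fit fast path: pooled OLS with (numerically) zero residual.
    ols = np.linalg.lstsq(exog, met, rcond=None)[0]
    resid = met - exog @ ols
    scale = max(1.0, float(np.abs(met).max()))
    if np.abs(resid).max() < 1e-8 * scale:
        pred = exog @ ols
        return CalibrationFit(
            fixed_intercept=float(ols[0]),
            fixed_slope=float(ols[1]) / _COUNT_SCALE,
            fixed_slope_se=0.0,
            random_intercept_var=0.0,
            random_slope_var=0.0,
            residual_var=0.0,
            ccc=concordance_cc(met, pred),
            see=standard_error_estimate(met, pred),
            n_obs=len(met),
            n_participants=len(uniq),
            converged=True,
        )

    exog_re = np.column_stack([np.ones_like(x), x])
    model = sm.MixedLM(met, exog, groups=pid, exog_re=exog_re)
    free = MixedLMParams.from_components(
        fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=False, free=free, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise CalibrationError(f"mixed-model fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise CalibrationError(
            f"mixed-model fit did not converge (params {res.params})"
        )

    pred = exog @ res.fe_params
    cov_re = np.asarray(res.cov_re)
    return CalibrationFit(
        fixed_intercept=float(res.fe_params[0]),
        fixed_slope=float(res.fe_params[1]) / _COUNT_SCALE,
        fixed_slope_se=float(res.bse_fe[1]) / _COUNT_SCALE,
        random_intercept_var=float(cov_re[0, 0]),
        random_slope_var=float(cov_re[1, 1]) / _COUNT_SCALE**2,
        residual_var=float(res.scale),
        ccc=concordance_cc(met, pred),
        see=standard_error_estimate(met, pred),
        n_obs=len(met),
        n_participants=len(uniq),
        converged=bool(getattr(res, "converged", True)),
    )


def concordance_cc(actual, predicted) -> float:
    """Lin's concordance correlation coefficient (population-variance form).

    ``2*cov(a, p) / (var(a) + var(p) + (mean(a) - mean(p))**2)``; equals 1
    only for perfect agreement, and penalizes both scale and location shifts
    relative to the identity line.
    """
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    va = a.var()
    vp = p.var()
    cov = ((a - a.mean()) * (p - p.mean())).mean()
    denom = va + vp + (a.mean() - p.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined for two identical constant vectors")
    return float(2 * cov / denom)


def standard_error_estimate(actual, predicted) -> float:
    """Standard error of the estimate: sqrt(sum((a - p)^2) / (n - 2))."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if len(a) <= 2:
        raise ValueError("need n > 2 for the n - 2 denominator")
    return float(np.sqrt(np.sum((a - p) ** 2) / (len(a) - 2)))


def solve_threshold(fit: CalibrationFit, met_target: float) -> tuple[float, int]:
    """Invert the fixed-effects line at a MET anchor.

    Returns ``(exact, rounded)`` counts/15 s at which the population-level
    predicted MET equals ``met_target``.  Requires a positive fixed slope
    (otherwise the calibration is not invertible).
    """
    if fit.fixed_slope <= 0:
        raise CalibrationError("non-positive slope: calibration not invertible")
    exact = (met_target - fit.fixed_intercept) / fit.fixed_slope
    return float(exact), int(round(exact))
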