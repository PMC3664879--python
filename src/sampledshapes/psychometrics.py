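"""Weibull psychometric fitting and log-log power-law slope estimation.

2AFC percent-correct data are fitted with the Weibull function

    P(x) = 1 - 0.5 * exp(-(x / alpha)^beta)

(guess rate fixed at 0.5, no lapses) by maximizing the binomial log
likelihood; the threshold is read at 75% correct, ``alpha * ln(2)^(1/beta)``.
Set-size and spacing effects are quantified as the slope of ordinary least
squares on log10-log10 axes.

``WeibullPsychometric`` follows the model/results convention: build it from
a dataset, call ``fit()``, read estimates and ``summary()`` off the results
object (:class:`WeibullFit`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize

__all__ = [
    "PsychometricDataset",
    "WeibullFit",
    "WeibullPsychometric",
    "SlopeFit",
    "fit_weibull",
    "threshold_at",
    "fit_loglog_slope",
]

_BETA_BOUNDS = (0.2, 20.0)
_LL_TOL = 1e-8


@dataclass(frozen=True)
class PsychometricDataset:
    """Per-level 2AFC trial counts."""

    levels: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, float)
        n = np.asarray(self.n_trials, int)
        k = np.asarray(self.n_correct, int)
        if not (len(levels) == len(n) == len(k)):
            raise ValueError("levels, n_trials and n_correct must have equal length")
        if np.any(levels < 0):
            raise ValueError("levels must be non-negative")
        if len(np.unique(levels)) != len(levels):
            raise ValueError("levels must be distinct")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_correct <= n_trials")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n_trials", n)
        object.__setattr__(self, "n_correct", k)

    @property
    def proportions(self) -> np.ndarray:
        return self.n_correct / np.maximum(self.n_trials, 1)


def _weibull_p(x, alpha, beta):
    x = np.asarray(x, float)
    with np.errstate(divide="ignore"):
        z = np.where(x > 0, (x / alpha) ** beta, 0.0)
    return 1.0 - 0.5 * np.exp(-z)


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull fit of one psychometric function.

    ``threshold75`` is censored (+/- inf with ``censored`` set) when the
    data do not bracket 75% correct and the fit is flagged non-converged.
    """

    alpha: float
    beta: float
    log_likelihood: float
    threshold75: float
    converged: bool
    censored: str | None = None
    data: PsychometricDataset | None = None

    def predict(self, x) -> np.ndarray:
        return _weibull_p(x, self.alpha, self.beta)

    def summary(self) -> str:
        status = "converged" if self.converged else f"censored ({self.censored})"
        return "\n".join(
            [
                "Weibull psychometric fit (guess 0.5, no lapse)",
                "-" * 46,
                f"alpha (scale, deg): {self.alpha:.4f}",
                f"beta (slope):       {self.beta:.4f}",
                f"75% threshold:      {self.threshold75:.4f} deg",
                f"log-likelihood:     {self.log_likelihood:.4f}",
                f"status:             {status}",
            ]
        )


class WeibullPsychometric:
    """Binomial MLE of the 2AFC Weibull psychometric function."""

    def __init__(self, data: PsychometricDataset) -> None:
        if len(data.levels) < 3:
            raise ValueError("need at least 3 stimulus levels")
        self.data = data

    def _nll(self, log_alpha: float, log_beta: float) -> float:
        beta = math.exp(log_beta)
        if not _BETA_BOUNDS[0] <= beta <= _BETA_BOUNDS[1]:
            return np.inf
        p = _weibull_p(self.data.levels, math.exp(log_alpha), beta)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        k = self.data.n_correct
        n = self.data.n_trials
        return -float(k @ np.log(p) + (n - k) @ np.log1p(-p))

    def _bracketed(self) -> str | None:
        """None if the data bracket 75% correct, else which side is missing."""
        props = self.data.proportions
        if np.all(props <= 0.75):
            return "above"
        if np.all(props >= 0.75):
            return "below"
        return None

    def fit(self, init: tuple[float, float] | None = None) -> WeibullFit:
        """Multi-start Nelder-Mead maximization of the binomial likelihood."""
        missing = self._bracketed()
        pos = self.data.levels[self.data.levels > 0]
        if missing == "above":
            return WeibullFit(
                alpha=math.inf,
                beta=math.nan,
                log_likelihood=-self._nll_at_chance(),
                threshold75=math.inf,
                converged=False,
                censored=f"> {self.data.levels.max():g}",
                data=self.data,
            )
        lo, hi = float(pos.min()), float(pos.max())
        starts = []
        if init is not None:
            starts.append((math.log(init[0]), math.log(init[1])))
        alpha_grid = np.geomspace(max(lo, 1e-6), hi, 6)
        for a in alpha_grid:
            for b in (1.0, 3.0):
                starts.append((math.log(a), math.log(b)))
        best = None
        for s in starts:
            res = minimize(
                lambda t: self._nll(t[0], t[1]),
                x0=np.asarray(s),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": _LL_TOL, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        alpha = math.exp(best.x[0])
        beta = math.exp(best.x[1])
        fit = WeibullFit(
            alpha=alpha,
            beta=beta,
            log_likelihood=-float(best.fun),
            threshold75=alpha * math.log(2.0) ** (1.0 / beta),
            converged=True,
            data=self.data,
        )
        if missing == "below":
            # all points above 75%: the threshold lies below the tested range
            fit.converged = False
            fit.censored = f"< {lo:g}"
        return fit

    def _nll_at_chance(self) -> float:
        n = self.data.n_trials
        k = self.data.n_correct
        return -float((k + (n - k)) @ np.log(np.full(len(n), 0.5)))


def fit_weibull(
    data: PsychometricDataset, init: tuple[float, float] | None = None
) -> WeibullFit:
    """Fit the 2AFC Weibull psychometric function by maximum likelihood."""
    return WeibullPsychometric(data).fit(init=init)


def threshold_at(fit: WeibullFit, p: float) -> float:
    """Stimulus level at probability-correct ``p`` (0.5 < p < 1)."""
    if not 0.5 < p < 1.0:
        raise ValueError("p must be strictly between 0.5 and 1")
    return fit.alpha * (-math.log(2.0 * (1.0 - p))) ** (1.0 / fit.beta)


@dataclass(frozen=True)
class SlopeFit:
    """OLS power-law fit on log10-log10 axes."""

    slope: float
    intercept: float
    slope_se: float
    covariates: np.ndarray

    def predict(self, x) -> np.ndarray:
        return 10.0 ** (self.intercept + self.slope * np.log10(np.asarray(x, float)))


def fit_loglog_slope(x, thresholds) -> SlopeFit:
    """Slope of log10(threshold) against log10(x) by ordinary least squares."""
    x = np.asarray(x, float)
    t = np.asarray(thresholds, float)
    if len(x) != len(t):
        raise ValueError("x and thresholds must have equal length")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct x values")
    if np.any(x <= 0) or np.any(t <= 0):
        raise ValueError("power-law fitting needs positive values")
    exog = sm.add_constant(np.log10(x))
    res = sm.OLS(np.log10(t), exog).fit()
    se = float(res.bse[1]) if len(x) > 2 else float("nan")
    return SlopeFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=se,
        covariates=x,
    )
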