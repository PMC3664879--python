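"""Stochastic min-rule 2AFC observer built on noisy arc units.

The observer implements the late-noise account of heterogeneity detection:
each arc (contour segment of constant curvature sign) is represented by one
arc unit whose noise-free response is the *product* of the local responses
of its elements; a Gaussian orientation-tuning function maps each element's
misalignment onto its local response, so a single misaligned element
depresses exactly one arc unit. Strong additive noise is injected at the
arc-unit stage — independently per unit, interval and trial — and the
observer picks the interval whose *minimum* arc-unit response is smaller
(the decrement analogue of the visual-search max rule).

A generic signal-detection benchmark (`simulate_sdt_setsize`) runs the same
min-rule decision over S independent standard-noise units with a linear
transducer, the regime in which classic probability-summation analysis
predicts log-log set-size slopes of roughly 0.2-0.35.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .geometry import ArcSegment, TWO_PI
from .model import ModelCondition, ModelParams, threshold_factors
from .psychometrics import PsychometricDataset, WeibullFit, fit_loglog_slope, fit_weibull
from .stimulus import StimulusPattern

__all__ = [
    "ObserverParams",
    "calibrate_observer",
    "arc_unit_signal",
    "decide_2afc",
    "simulate_psychometric",
    "simulate_sdt_setsize",
    "SetSizeSimResult",
]


@dataclass(frozen=True)
class ObserverParams:
    """Arc-unit observer parameters.

    ``tuning_sigma`` (deg) is the width of the Gaussian orientation tuning
    of the local curvature response; ``noise_sd`` the standard deviation of
    the late noise added to each arc unit (in units of the unit's maximal
    response, which is 1 for a perfectly aligned pattern);
    ``noise_family`` selects the late-noise distribution. No lapses.
    """

    tuning_sigma: float = 15.0
    noise_sd: float = 0.12
    noise_family: str = "gaussian"
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.tuning_sigma > 0:
            raise ValueError("tuning_sigma must be positive")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.noise_family not in ("gaussian", "weibull-tail"):
            raise ValueError(f"unknown noise_family {self.noise_family!r}")

    def local_response(self, delta_theta_deg):
        """Gaussian tuning g(dtheta) = exp(-dtheta^2 / (2 sigma^2))."""
        d = np.asarray(delta_theta_deg, float)
        return np.exp(-(d * d) / (2.0 * self.tuning_sigma**2))


def calibrate_observer(
    tuning_sigma: float = 15.0,
    baseline_threshold: float = 7.4,
    noise_family: str = "gaussian",
) -> ObserverParams:
    """Choose the late-noise scale so the baseline condition hits threshold.

    For the baseline (a closed circle: one arc unit, unit factors) the
    min-rule 2AFC reduces to comparing two Gaussian draws, so P(correct) =
    Phi(d / (noise_sd * sqrt(2))) with d the signal decrement. Solving for
    75% correct at the anchor threshold gives the noise scale in closed
    form.
    """
    d = 1.0 - math.exp(-(baseline_threshold**2) / (2.0 * tuning_sigma**2))
    noise_sd = d / (math.sqrt(2.0) * norm.ppf(0.75))
    return ObserverParams(
        tuning_sigma=tuning_sigma, noise_sd=noise_sd, noise_family=noise_family
    )


def _fold_orientation_diff(a_deg, b_deg):
    """Smallest angle between two orientations (period 180), in [0, 90]."""
    d = np.abs(np.asarray(a_deg, float) - np.asarray(b_deg, float)) % 180.0
    return np.minimum(d, 180.0 - d)


def arc_unit_signal(
    pattern: StimulusPattern,
    arcs: list[ArcSegment],
    observer: ObserverParams,
) -> np.ndarray:
    """Noise-free per-arc signals for an aligned pattern.

    Each element contributes ``g(dtheta)`` with ``dtheta`` its deviation
    from the contour tangent; an arc's signal is the product over its
    elements (empty arcs respond at their maximum, 1). A perfectly aligned
    pattern therefore yields 1 for every arc.
    """
    if pattern.mode != "aligned":
        raise ValueError("arc-unit signals are defined for aligned patterns")
    d = _fold_orientation_diff(pattern.element_orientations, pattern.layout.tangents)
    g = observer.local_response(d)
    phi = pattern.layout.phi
    signals = np.ones(len(arcs))
    assigned = np.zeros(len(phi), bool)
    for j, arc in enumerate(arcs):
        lo, hi = arc.phi_start, arc.phi_end
        # membership on the unwrapped walk coordinate, tolerant of 2*pi shifts
        rel = (phi - lo) % TWO_PI
        inside = (rel <= (hi - lo) + 1e-12) & ~assigned
        assigned |= inside
        if np.any(inside):
            signals[j] = float(np.prod(g[inside]))
    if not np.all(assigned):
        raise ValueError("pattern elements do not all fall inside the given arcs")
    return signals


def _late_noise(observer: ObserverParams, rng: np.random.Generator, size) -> np.ndarray:
    if observer.noise_family == "gaussian":
        return observer.noise_sd * rng.standard_normal(size)
    # "weibull-tail": heavy lower tail — negated, standardized Weibull(k=2)
    k = 2.0
    w = rng.weibull(k, size)
    mean = math.gamma(1.0 + 1.0 / k)
    sd = math.sqrt(math.gamma(1.0 + 2.0 / k) - mean**2)
    return observer.noise_sd * (mean - w) / sd


def decide_2afc(
    responses_a: np.ndarray, responses_b: np.ndarray, rng: np.random.Generator
) -> int:
    """Min rule: report the interval whose smallest arc-unit response is smaller.

    Returns 0 for interval A, 1 for interval B; exact ties are broken by a
    fair coin.
    """
    a = float(np.min(responses_a))
    b = float(np.min(responses_b))
    if a < b:
        return 0
    if b < a:
        return 1
    return int(rng.random() < 0.5)


def simulate_psychometric(
    condition: ModelCondition,
    increments,
    n_trials: int,
    observer: ObserverParams,
    rng: np.random.Generator,
    model_params: ModelParams | None = None,
    transducer: str = "linear",
) -> PsychometricDataset:
    """Simulate 2AFC performance across orientation increments.

    One of ``ceil(S)`` arc units carries a signal decrement that grows with
    the orientation increment and shrinks with the condition's curvature and
    spacing factors (larger factors mean lower sensitivity); independent
    late noise is added to every unit in both intervals. Returns per-level
    correct counts.

    ``transducer="linear"`` (default) maps the increment onto the decrement
    linearly, ``d = inc * d75 / (T_base * factor)`` saturating at 1, with
    ``d75`` the decrement a single unit needs for 75% correct; this bakes in
    the baseline anchor (a closed circle thresholds at ``T_base`` for any
    noise scale) and keeps simulated thresholds proportional to the
    threshold equation across conditions. ``transducer="gaussian"`` instead
    uses the tuning-function decrement ``(1 - g(inc)) / factor``, whose
    quadratic small-angle behaviour compresses large predicted thresholds.
    """
    increments = np.asarray(increments, float)
    if np.any((increments < 0) | (increments > 90)):
        raise ValueError("increments must lie in [0, 90] degrees")
    if transducer not in ("linear", "gaussian"):
        raise ValueError(f"unknown transducer {transducer!r}")
    model_params = model_params or ModelParams()
    _, f_curv, f_space = threshold_factors(condition, model_params)
    factor = f_curv * f_space
    d75 = math.sqrt(2.0) * norm.ppf(0.75) * observer.noise_sd
    s_units = max(int(math.ceil(condition.S)), 1)
    n_correct = np.empty(len(increments), int)
    for i, inc in enumerate(increments):
        if transducer == "linear":
            d = min(inc * d75 / (model_params.baseline_threshold * factor), 1.0)
        else:
            d = (1.0 - float(observer.local_response(inc))) / factor
        base = 1.0 + _late_noise(observer, rng, (n_trials, s_units))
        target = np.ones(s_units)
        target[0] = 1.0 - d
        incr = target + _late_noise(observer, rng, (n_trials, s_units))
        m_inc = incr.min(axis=1)
        m_base = base.min(axis=1)
        correct = m_inc < m_base
        ties = m_inc == m_base
        if np.any(ties):
            correct = correct | (ties & (rng.random(n_trials) < 0.5))
        n_correct[i] = int(correct.sum())
    return PsychometricDataset(
        levels=increments,
        n_trials=np.full(len(increments), n_trials),
        n_correct=n_correct,
    )


@dataclass
class SetSizeSimResult:
    """Outcome of the min-rule set-size benchmark."""

    arc_counts: np.ndarray
    thresholds: np.ndarray
    fits: list[WeibullFit]
    slope: float
    slope_se: float
    intercept: float

    def summary(self) -> str:
        rows = "\n".join(
            f"  S={int(s):>3d}  threshold={t:.4f}"
            for s, t in zip(self.arc_counts, self.thresholds)
        )
        return (
            "Min-rule set-size benchmark (linear transducer)\n"
            + "-" * 48
            + f"\n{rows}\n"
            + f"log-log slope: {self.slope:.4f} (SE {self.slope_se:.4f})"
        )


def simulate_sdt_setsize(
    arc_counts,
    observer: ObserverParams,
    n_trials: int,
    rng: np.random.Generator,
    levels_per_count: int = 7,
) -> SetSizeSimResult:
    """Log-log slope of simulated thresholds against independent unit count.

    For each S, one of S independent units carries a decrement proportional
    to the stimulus level (linear transducer); late noise is Gaussian with
    the observer's scale; the min rule decides the 2AFC. Weibull thresholds
    (75% correct) are fitted per S and regressed on S in log-log
    coordinates. Levels are laid out geometrically around the expected
    threshold so every psychometric function is bracketed; non-convergent
    fits are excluded from the regression.
    """
    arc_counts = np.asarray(arc_counts, int)
    if len(arc_counts) < 2 or len(np.unique(arc_counts)) < 2:
        raise ValueError("the set-size slope needs at least 2 distinct unit counts")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    d75_pair = math.sqrt(2.0) * norm.ppf(0.75) * observer.noise_sd
    thresholds, fits, kept = [], [], []
    for s in arc_counts:
        guess = d75_pair * s**0.3
        levels = guess * np.geomspace(0.25, 4.0, levels_per_count)
        n_correct = np.empty(levels_per_count, int)
        for i, lev in enumerate(levels):
            base = 1.0 + observer.noise_sd * rng.standard_normal((n_trials, s))
            target = np.ones(s)
            target[0] = 1.0 - lev
            incr = target + observer.noise_sd * rng.standard_normal((n_trials, s))
            n_correct[i] = int((incr.min(axis=1) < base.min(axis=1)).sum())
        data = PsychometricDataset(
            levels=levels, n_trials=np.full(levels_per_count, n_trials), n_correct=n_correct
        )
        fit = fit_weibull(data)
        fits.append(fit)
        if fit.converged:
            thresholds.append(fit.threshold75)
            kept.append(s)
    if len(kept) < 2:
        raise RuntimeError("too few convergent psychometric fits for a slope")
    slope_fit = fit_loglog_slope(np.asarray(kept, float), np.asarray(thresholds))
    return SetSizeSimResult(
        arc_counts=np.asarray(kept),
        thresholds=np.asarray(thresholds),
        fits=fits,
        slope=slope_fit.slope,
        slope_se=slope_fit.slope_se,
        intercept=slope_fit.intercept,
    )
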