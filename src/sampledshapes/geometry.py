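"""Analytic geometry of radial-frequency (RF) contours.

An RF pattern is a sinusoidally modulated circle,

    R(phi) = r0 * (1 + A * sin(N * phi + theta)),

with mean radius ``r0`` (degrees of visual angle), modulation amplitude
``A``, integer radial frequency ``N`` (number of lobes) and phase ``theta``.
This module provides the signed curvature of such contours, their inflection
points and arc segmentation (segments of constant curvature sign), and the
placement of Gabor sample elements along the contour, including the
positional jitter used to break accidental symmetries.

Conventions: polar angle in radians internally, counter-clockwise from the
positive x axis; all lengths in degrees of visual angle; curvature in
1/degree, positive on convex segments; element orientations in degrees
folded into [0, 180).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "RFShapeSpec",
    "CurvatureProfile",
    "ArcSegment",
    "ElementLayout",
    "InvalidLayoutError",
    "InfeasibleSpacingError",
    "rf_radius",
    "signed_curvature",
    "tangent_orientation",
    "find_inflections",
    "segment_arcs",
    "curvature_profile",
    "average_unsigned_curvature",
    "contains_concavities",
    "perimeter",
    "arc_length",
    "layout_elements",
    "apply_jitter",
    "max_jitter_deg",
    "layout_to_csv",
]

TWO_PI = 2.0 * math.pi

#: samples per modulation period used for inflection bracketing (D8 grid: 4096
#: total for the default shapes).
_MIN_SAMPLES_PER_PERIOD = 512


class InvalidLayoutError(ValueError):
    """A layout request that is degenerate (e.g. fewer than 2 elements)."""


class InfeasibleSpacingError(ValueError):
    """The requested inter-element spacing cannot be realised on the contour."""


@dataclass(frozen=True)
class RFShapeSpec:
    """Parametric description of a radial-frequency contour.

    Parameters
    ----------
    r0 : float
        Mean radius (radius of the unmodulated circle), degrees of visual
        angle. Must be positive.
    amplitude : float
        Modulation amplitude ``A`` (dimensionless, >= 0). ``A = 0`` gives a
        circle.
    frequency : int
        Radial frequency ``N`` (number of modulation lobes, >= 0). ``N = 0``
        gives a circle.
    phase_deg : float
        Shape phase ``theta`` in degrees; rotates the lobe positions.
    """

    r0: float
    amplitude: float = 0.0
    frequency: int = 0
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.r0 > 0:
            raise ValueError(f"r0 must be positive, got {self.r0}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.frequency < 0 or int(self.frequency) != self.frequency:
            raise ValueError(
                f"frequency must be a non-negative integer, got {self.frequency}"
            )
        object.__setattr__(self, "frequency", int(self.frequency))

    @property
    def is_circle(self) -> bool:
        return self.frequency == 0 or self.amplitude == 0.0

    @property
    def phase_rad(self) -> float:
        return math.radians(self.phase_deg)

    # -- radius and derivatives with respect to phi ------------------------
    def radius(self, phi):
        """R(phi) in degrees of visual angle."""
        if self.is_circle:
            return np.broadcast_to(np.float64(self.r0), np.shape(phi)).copy() \
                if np.ndim(phi) else float(self.r0)
        return self.r0 * (
            1.0 + self.amplitude * np.sin(self.frequency * np.asarray(phi, float) + self.phase_rad)
        )

    def radius_d1(self, phi):
        if self.is_circle:
            return np.zeros(np.shape(phi)) if np.ndim(phi) else 0.0
        n = self.frequency
        return self.r0 * self.amplitude * n * np.cos(n * np.asarray(phi, float) + self.phase_rad)

    def radius_d2(self, phi):
        if self.is_circle:
            return np.zeros(np.shape(phi)) if np.ndim(phi) else 0.0
        n = self.frequency
        return -self.r0 * self.amplitude * n * n * np.sin(
            n * np.asarray(phi, float) + self.phase_rad
        )

    def point(self, phi):
        """Cartesian (x, y) of the contour at polar angle(s) ``phi``."""
        r = self.radius(phi)
        phi = np.asarray(phi, float)
        return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=-1)

    def rotated(self, angle_deg: float) -> "RFShapeSpec":
        """The same shape rigidly rotated CCW by ``angle_deg``.

        Rotation by ``a`` maps the contour so that ``R_new(phi + a) =
        R_old(phi)``, i.e. theta decreases by ``N * a``.
        """
        if self.frequency == 0:
            return self
        return replace(self, phase_deg=self.phase_deg - self.frequency * angle_deg)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "r0_deg": self.r0,
            "amplitude": self.amplitude,
            "radial_frequency": self.frequency,
            "phase_deg": self.phase_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RFShapeSpec":
        return cls(
            r0=d["r0_deg"],
            amplitude=d.get("amplitude", 0.0),
            frequency=d.get("radial_frequency", 0),
            phase_deg=d.get("phase_deg", 0.0),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RFShapeSpec":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class ArcSegment:
    """A contour segment over which signed curvature does not change sign."""

    phi_start: float
    phi_end: float
    sign: int  # +1 convex, -1 concave
    arc_length: float  # degrees of visual angle

    @property
    def span(self) -> float:
        return self.phi_end - self.phi_start


@dataclass(frozen=True)
class CurvatureProfile:
    """Signed curvature sampled along a contour plus its landmarks."""

    phi_grid: np.ndarray
    kappa: np.ndarray
    inflections: np.ndarray
    c_min: float
    c_max: float
    c_abs_min: float


@dataclass(frozen=True)
class ElementLayout:
    """Positions of the Gabor samples along a contour.

    ``phi`` is strictly increasing along the walk (it may exceed 2*pi for
    layouts that wrap); ``centers`` are Cartesian coordinates in degrees;
    ``tangents`` are contour tangent orientations in degrees in [0, 180);
    ``mean_spacing`` is the mean adjacent centre-to-centre chord distance
    (including the wrap-around pair for closed layouts).
    """

    shape: RFShapeSpec
    phi: np.ndarray
    centers: np.ndarray
    tangents: np.ndarray
    closed: bool
    mean_spacing: float
    span_arc_length: float  # arc length from first to last element

    @property
    def n(self) -> int:
        return len(self.phi)

    @property
    def coverage(self) -> float:
        """Fraction of the contour perimeter spanned (1 for closed layouts)."""
        if self.closed:
            return 1.0
        return min(1.0, self.span_arc_length / perimeter(self.shape))


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def rf_radius(phi, shape: RFShapeSpec):
    """Radial distance of the contour from its centre at polar angle ``phi``."""
    return shape.radius(phi)


def signed_curvature(phi, shape: RFShapeSpec):
    """Signed curvature (1/degree) of the polar curve at ``phi``.

    Uses the polar-curve formula
    ``kappa = (R^2 + 2 R'^2 - R R'') / (R^2 + R'^2)^{3/2}``;
    positive where the contour is convex (centre of the osculating circle
    toward the shape interior), negative on concavities. A circle returns
    ``1/r0`` everywhere.
    """
    r = shape.radius(phi)
    r1 = shape.radius_d1(phi)
    r2 = shape.radius_d2(phi)
    return (r * r + 2.0 * r1 * r1 - r * r2) / (r * r + r1 * r1) ** 1.5


def tangent_orientation(phi, shape: RFShapeSpec):
    """Contour tangent orientation at ``phi``, degrees folded into [0, 180)."""
    phi = np.asarray(phi, float)
    r = shape.radius(phi)
    r1 = shape.radius_d1(phi)
    dx = r1 * np.cos(phi) - r * np.sin(phi)
    dy = r1 * np.sin(phi) + r * np.cos(phi)
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    return ang if ang.ndim else float(ang)


def _resolution_for(shape: RFShapeSpec, resolution: int | None) -> int:
    periods = max(shape.frequency, 1)
    base = _MIN_SAMPLES_PER_PERIOD * periods
    return max(base, int(resolution or 0), 4096)


def find_inflections(shape: RFShapeSpec, resolution: int | None = None) -> np.ndarray:
    """Polar angles in [0, 2*pi) where signed curvature crosses zero.

    Zero crossings are bracketed on a uniform grid (at least 512 samples per
    modulation period) and refined by bisection. A circle, and any shape
    that is everywhere convex, has none; a high-amplitude RF N has exactly
    2N.
    """
    if shape.is_circle:
        return np.empty(0)
    m = _resolution_for(shape, resolution)
    phi = np.linspace(0.0, TWO_PI, m, endpoint=False)
    k = signed_curvature(phi, shape)
    roots = []
    for i in range(m):
        a, b = phi[i], phi[i] + TWO_PI / m
        ka, kb = k[i], k[(i + 1) % m]
        if ka == 0.0:
            roots.append(a)
        elif ka * kb < 0.0:
            roots.append(brentq(lambda p: signed_curvature(p, shape), a, b, xtol=1e-13))
    return np.asarray(sorted(r % TWO_PI for r in roots))


def curvature_profile(shape: RFShapeSpec, resolution: int | None = None) -> CurvatureProfile:
    """Sampled curvature along the full contour with extrema and inflections."""
    m = _resolution_for(shape, resolution)
    phi = np.linspace(0.0, TWO_PI, m, endpoint=False)
    k = signed_curvature(phi, shape)
    return CurvatureProfile(
        phi_grid=phi,
        kappa=k,
        inflections=find_inflections(shape, resolution),
        c_min=float(k.min()),
        c_max=float(k.max()),
        c_abs_min=float(np.abs(k).min()),
    )


def contains_concavities(shape: RFShapeSpec, resolution: int | None = None) -> bool:
    """True if the signed curvature goes negative anywhere on the contour."""
    if shape.is_circle:
        return False
    m = _resolution_for(shape, resolution)
    phi = np.linspace(0.0, TWO_PI, m, endpoint=False)
    return bool(signed_curvature(phi, shape).min() < 0.0)


def average_unsigned_curvature(shape: RFShapeSpec, weighting: str = "arclength") -> float:
    """Mean of |kappa| over the full contour, in 1/degree.

    ``weighting="arclength"`` (default) averages along the length of the
    contour, i.e. weights |kappa| by the local line element ds; this is the
    convention under which the curvature-discrimination literature states
    the average-curvature effect. ``weighting="polar"`` averages uniformly
    in the polar angle phi. The two agree exactly for a circle (1/r0) and
    differ by a few percent for high-amplitude RF shapes; both are scale
    invariant in the sense that the product with r0 is independent of r0.
    """
    if shape.is_circle:
        return 1.0 / shape.r0
    m = 1 << 16
    phi = np.linspace(0.0, TWO_PI, m, endpoint=False)
    k = np.abs(signed_curvature(phi, shape))
    if weighting == "polar":
        return float(k.mean())
    if weighting == "arclength":
        r = shape.radius(phi)
        r1 = shape.radius_d1(phi)
        ds = np.hypot(r, r1)
        return float((k * ds).sum() / ds.sum())
    raise ValueError(f"unknown weighting {weighting!r}")


def segment_arcs(
    shape: RFShapeSpec,
    span: tuple[float, float] | None = None,
    resolution: int | None = None,
) -> list[ArcSegment]:
    """Split the contour into arcs of constant curvature sign.

    ``span`` is an optional polar-angle interval ``(phi0, phi1)`` with
    ``phi1 > phi0`` (radians, ``phi1 - phi0 <= 2*pi``); by default the full
    closed contour is segmented. A full circle yields one convex segment, a
    full high-amplitude RF N yields 2N alternating segments; a span cuts the
    end arcs into fractional pieces, which are returned with their actual
    (fractional) arc length.
    """
    infl = find_inflections(shape, resolution)
    if span is None:
        if infl.size == 0:
            sgn = 1 if signed_curvature(0.0, shape) >= 0 else -1
            return [ArcSegment(0.0, TWO_PI, sgn, perimeter(shape))]
        bounds = np.concatenate([infl, [infl[0] + TWO_PI]])
    else:
        a, b = span
        if not b > a:
            raise ValueError("span must have phi_end > phi_start")
        if b - a > TWO_PI + 1e-12:
            raise ValueError("span cannot exceed a full revolution")
        if infl.size == 0:
            sgn = 1 if signed_curvature(a, shape) >= 0 else -1
            return [ArcSegment(a, b, sgn, arc_length(shape, a, b))]
        # inflection angles unwrapped into (a, b)
        inner = []
        for base in (np.floor(a / TWO_PI) * TWO_PI, np.floor(a / TWO_PI) * TWO_PI + TWO_PI):
            cand = infl + base
            inner.extend(cand[(cand > a + 1e-12) & (cand < b - 1e-12)])
        bounds = np.asarray([a] + sorted(inner) + [b])
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        sgn = 1 if signed_curvature(mid, shape) >= 0 else -1
        segments.append(ArcSegment(float(lo), float(hi), sgn, arc_length(shape, lo, hi)))
    return segments


# ---------------------------------------------------------------------------
# arc length and element placement
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _arclength_table(shape: RFShapeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Dense cumulative arc length s(phi) over one revolution (cached)."""
    m = 1 << 15
    phi = np.linspace(0.0, TWO_PI, m + 1)
    r = shape.radius(phi)
    r1 = shape.radius_d1(phi)
    ds = np.hypot(r, r1)
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) * 0.5 * np.diff(phi))])
    return phi, s


def perimeter(shape: RFShapeSpec) -> float:
    """Total contour length, degrees of visual angle."""
    if shape.is_circle:
        return TWO_PI * shape.r0
    _, s = _arclength_table(shape)
    return float(s[-1])


def arc_length(shape: RFShapeSpec, phi_a: float, phi_b: float) -> float:
    """Arc length along the contour from ``phi_a`` to ``phi_b`` (phi_b >= phi_a)."""
    if phi_b < phi_a:
        raise ValueError("phi_b must be >= phi_a")
    if shape.is_circle:
        return shape.r0 * (phi_b - phi_a)
    phi, s = _arclength_table(shape)
    total = s[-1]

    def s_of(p: float) -> float:
        turns, rem = divmod(p, TWO_PI)
        return turns * total + float(np.interp(rem, phi, s))

    return s_of(phi_b) - s_of(phi_a)


def _phi_at_arclength(shape: RFShapeSpec, s_target):
    """Inverse of the cumulative arc length; accepts values beyond one turn."""
    if shape.is_circle:
        return np.asarray(s_target, float) / shape.r0
    phi, s = _arclength_table(shape)
    total = s[-1]
    s_target = np.asarray(s_target, float)
    turns, rem = np.divmod(s_target, total)
    return turns * TWO_PI + np.interp(rem, s, phi)


def _chord(shape: RFShapeSpec, phi_a, phi_b) -> float:
    pa = shape.point(phi_a)
    pb = shape.point(phi_b)
    return float(np.hypot(*(pb - pa)))


def _build_layout(shape: RFShapeSpec, phi: np.ndarray, closed: bool) -> ElementLayout:
    centers = shape.point(phi)
    tangents = np.atleast_1d(tangent_orientation(phi, shape))
    chords = np.hypot(*(np.diff(centers, axis=0).T))
    if closed:
        wrap = float(np.hypot(*(centers[0] - centers[-1])))
        chords = np.concatenate([chords, [wrap]])
    span = arc_length(shape, float(phi[0]), float(phi[-1]))
    return ElementLayout(
        shape=shape,
        phi=np.asarray(phi, float),
        centers=centers,
        tangents=tangents,
        closed=closed,
        mean_spacing=float(chords.mean()) if len(chords) else 0.0,
        span_arc_length=span,
    )


def layout_elements(
    shape: RFShapeSpec,
    n: int,
    mode: str = "full",
    target_spacing: float | None = None,
    start_phi: float = 0.0,
) -> ElementLayout:
    """Place ``n`` Gabor sample positions on the contour.

    ``mode="full"`` distributes the elements at equal arc-length intervals
    around the closed contour, starting at ``start_phi``. ``mode="partial"``
    walks along the contour from ``start_phi`` placing each successive
    element at the first point whose straight-line (chord) distance from the
    previous one equals ``target_spacing``; the layout is open and covers
    only part of the contour.

    Raises
    ------
    InvalidLayoutError
        for ``n < 2``.
    InfeasibleSpacingError
        in partial mode, when the walk would wrap past a full revolution or
        the requested chord is longer than the contour admits.
    """
    if n < 2:
        raise InvalidLayoutError(f"a layout needs at least 2 elements, got n={n}")
    if mode == "full":
        total = perimeter(shape)
        s0 = arc_length(shape, 0.0, start_phi % TWO_PI)
        s_vals = s0 + np.arange(n) * total / n
        phi = _phi_at_arclength(shape, s_vals)
        return _build_layout(shape, phi, closed=True)
    if mode == "partial":
        if target_spacing is None or target_spacing <= 0:
            raise InvalidLayoutError("partial mode requires a positive target_spacing")
        total = perimeter(shape)
        phi_list = [start_phi]
        s_prev = arc_length(shape, 0.0, start_phi % TWO_PI)
        for _ in range(n - 1):
            s_next = _next_chord_crossing(shape, s_prev, target_spacing, total)
            phi_list.append(float(_phi_at_arclength(shape, s_next)))
            s_prev = s_next
        s_first = arc_length(shape, 0.0, start_phi % TWO_PI)
        if s_prev - s_first > total:
            raise InfeasibleSpacingError(
                f"{n} elements at spacing {target_spacing} wrap past the full contour"
            )
        return _build_layout(shape, np.asarray(phi_list), closed=False)
    raise ValueError(f"unknown layout mode {mode!r}")


def _next_chord_crossing(
    shape: RFShapeSpec, s_prev: float, target: float, total: float
) -> float:
    """First arc-length position past ``s_prev`` at chord ``target`` from it."""
    phi_prev = float(_phi_at_arclength(shape, s_prev))
    step = target / 8.0
    s_lo = s_prev
    f_lo = -target
    s = s_prev
    while s - s_prev <= total:
        s += step
        f = _chord(shape, phi_prev, float(_phi_at_arclength(shape, s))) - target
        if f >= 0.0:
            return brentq(
                lambda ss: _chord(shape, phi_prev, float(_phi_at_arclength(shape, ss)))
                - target,
                s_lo,
                s,
                xtol=1e-12,
            )
        s_lo, f_lo = s, f
    raise InfeasibleSpacingError(
        f"no contour point at chord distance {target} from phi={phi_prev:.4f}"
    )


# ---------------------------------------------------------------------------
# jitter
# ---------------------------------------------------------------------------

def max_jitter_deg(n: int) -> float:
    """Maximum positional jitter (polar angle, degrees) for ``n`` elements.

    ``delta_max = 0.4 * 360 / n - 3``; negative values (n > 48) are clamped
    to zero with a warning, since the bound is only meaningful for the
    element counts it was designed for.
    """
    d = 0.4 * 360.0 / n - 3.0
    if d < 0.0:
        warnings.warn(
            f"jitter bound is negative for n={n}; clamping to 0", stacklevel=2
        )
        return 0.0
    return d


def apply_jitter(layout: ElementLayout, rng: np.random.Generator) -> ElementLayout:
    """Shift each element along the contour by delta_i = delta_max * rand.

    ``rand`` is i.i.d. Uniform(0, 1), so the shift is one-sided (forward
    along the contour). To keep the element ordering intact for densely
    sampled partial layouts, where ``delta_max`` can exceed the polar-angle
    gap between neighbours, each shift is additionally capped at 95% of the
    gap to the next nominal element; the cap never binds for closed
    equally-spaced layouts. Reproducible bit-for-bit under a fixed seed.
    """
    n = layout.n
    d_max = max_jitter_deg(n)
    delta = np.radians(d_max * rng.random(n))
    gaps = np.diff(layout.phi)
    if layout.closed:
        gaps = np.concatenate([gaps, [layout.phi[0] + TWO_PI - layout.phi[-1]]])
    else:
        gaps = np.concatenate([gaps, [np.inf]])
    delta = np.minimum(delta, 0.95 * gaps)
    return _build_layout(layout.shape, layout.phi + delta, closed=layout.closed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def layout_to_csv(layout: ElementLayout, path) -> None:
    """Write element positions as CSV (element_index, phi_deg, x_deg, y_deg, tangent_deg)."""
    df = pd.DataFrame(
        {
            "element_index": np.arange(layout.n),
            "phi_deg": np.degrees(layout.phi % TWO_PI),
            "x_deg": layout.centers[:, 0],
            "y_deg": layout.centers[:, 1],
            "tangent_deg": layout.tangents,
        }
    )
    df.to_csv(path, index=False)


def layout_from_spec(spec: dict) -> ElementLayout:
    """Build a (possibly jittered) layout from a JSON-style spec dict.

    Recognised keys: ``r0_deg, amplitude, radial_frequency, phase_deg,
    n_elements, mode, target_spacing_deg, jitter_seed``.
    """
    shape = RFShapeSpec.from_dict(spec)
    layout = layout_elements(
        shape,
        n=spec["n_elements"],
        mode=spec.get("mode", "full"),
        target_spacing=spec.get("target_spacing_deg"),
    )
    seed = spec.get("jitter_seed")
    if seed is not None:
        layout = apply_jitter(layout, np.random.default_rng(seed))
    return layout
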