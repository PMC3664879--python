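"""Gabor-sampled stimulus patterns and luminance rendering.

Each sample element is a Gabor patch: a one-dimensional cosine carrier
(7 cycles/degree, cosine phase, contrast -1, so the patch centre is a
luminance minimum) under an isotropic Gaussian envelope (sigma 0.085 deg).
A ``StimulusPattern`` assigns one orientation per element according to the
condition: ``aligned`` (tangential to the sampled contour), ``parallel``
(one common orientation) or ``random`` (i.i.d. uniform in [0, 180)), with at
most one "increment" element whose orientation deviates from its base value
by a signed orientation increment. Patterns render to normalized luminance
images in [0, 1] around a mean level of 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image

from .geometry import ElementLayout, RFShapeSpec

__all__ = [
    "GaborSpec",
    "DisplaySpec",
    "StimulusPattern",
    "Trial",
    "make_pattern",
    "render",
    "build_trial",
    "save_png",
]

#: global pattern rotations used to break positional learning, degrees.
GLOBAL_PHASES_DEG = (100.0, 111.25, 122.5)


@dataclass(frozen=True)
class GaborSpec:
    """Carrier/envelope parameters of one sample element."""

    carrier_sf: float = 7.0  # cycles per degree
    envelope_sigma: float = 0.085  # degrees
    carrier_phase: float = 0.0  # cosine phase
    contrast: float = -1.0  # luminance minimum at patch centre


@dataclass(frozen=True)
class DisplaySpec:
    """Pixel geometry and luminance normalization of the rendered image.

    The physical mean luminance of the original display (138 cd/m^2) is
    metadata only; images are normalized with the mean level at 0.5.
    """

    pixel_size: float = 0.0177  # degrees per pixel
    image_extent: float | None = None  # degrees; None = auto from pattern
    mean_level: float = 0.5
    bit_depth: int = 8

    def extent_for(self, pattern: "StimulusPattern", gabor: GaborSpec) -> float:
        if self.image_extent is not None:
            return self.image_extent
        radius = float(np.max(np.hypot(*pattern.layout.centers.T)))
        return 2.0 * (radius + 3.0 * gabor.envelope_sigma + self.pixel_size)


@dataclass(frozen=True)
class StimulusPattern:
    """One stimulus: a layout plus per-element orientations.

    ``element_orientations`` are final orientations in degrees in [0, 180);
    ``increment_index`` marks the (single) heterogeneous element, if any, and
    ``increment_deg`` its unsigned orientation deviation from base.
    """

    shape: RFShapeSpec
    layout: ElementLayout
    mode: str
    global_phase_deg: float
    increment_index: int | None
    increment_deg: float
    element_orientations: np.ndarray
    base_orientations: np.ndarray

    @property
    def n(self) -> int:
        return self.layout.n


@dataclass(frozen=True)
class Trial:
    """An ordered 2AFC presentation pair with the correct-interval label."""

    first: StimulusPattern
    second: StimulusPattern
    increment_interval: int  # 0 if the increment pattern came first, else 1


def _rotate_layout(layout: ElementLayout, shape: RFShapeSpec, angle_deg: float) -> ElementLayout:
    """Rigidly rotate a layout (and its tangents) about the pattern centre."""
    if angle_deg == 0.0:
        return layout
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    return replace(
        layout,
        shape=shape,
        phi=layout.phi + a,
        centers=layout.centers @ rot.T,
        tangents=(layout.tangents + angle_deg) % 180.0,
    )


def make_pattern(
    shape: RFShapeSpec,
    layout: ElementLayout,
    mode: str = "aligned",
    increment_index: int | None = None,
    increment_deg: float = 0.0,
    global_phase_deg: float = 0.0,
    rng: np.random.Generator | None = None,
    common_orientation: float | None = None,
) -> StimulusPattern:
    """Assign element orientations for one stimulus.

    ``aligned`` uses the contour tangents; ``parallel`` one common
    orientation for all elements (drawn uniformly from [0, 180) when not
    given); ``random`` draws i.i.d. uniform orientations. The increment
    element's orientation deviates from its base value by ``increment_deg``,
    with the sign (clockwise/anti-clockwise) chosen at random. The whole
    configuration (positions, tangents and orientations) is rigidly rotated
    by ``global_phase_deg``.
    """
    if mode not in ("aligned", "parallel", "random"):
        raise ValueError(f"unknown pattern mode {mode!r}")
    if not 0.0 <= increment_deg <= 90.0:
        raise ValueError(f"increment_deg must be in [0, 90], got {increment_deg}")
    if increment_index is not None and not 0 <= increment_index < layout.n:
        raise ValueError(f"increment_index {increment_index} out of range")
    rotated_shape = shape.rotated(global_phase_deg) if mode == "aligned" else shape
    layout = _rotate_layout(layout, rotated_shape, global_phase_deg)
    if mode == "aligned":
        base = layout.tangents.copy()
    elif mode == "parallel":
        if common_orientation is None:
            if rng is None:
                raise ValueError("parallel mode needs a common_orientation or an rng")
            common_orientation = 180.0 * rng.random()
        base = np.full(layout.n, common_orientation % 180.0)
    else:  # random
        if rng is None:
            raise ValueError("random mode needs an rng")
        base = 180.0 * rng.random(layout.n)
    final = base.copy()
    if increment_index is not None and increment_deg > 0.0:
        sign = 1.0 if rng is None or rng.random() < 0.5 else -1.0
        final[increment_index] = (base[increment_index] + sign * increment_deg) % 180.0
    return StimulusPattern(
        shape=shape,
        layout=layout,
        mode=mode,
        global_phase_deg=global_phase_deg,
        increment_index=increment_index,
        increment_deg=float(increment_deg),
        element_orientations=final,
        base_orientations=base,
    )


def render(
    pattern: StimulusPattern,
    display: DisplaySpec | None = None,
    gabor: GaborSpec | None = None,
) -> np.ndarray:
    """Render a pattern to a normalized luminance image, values in [0, 1].

    Each patch adds ``contrast * cos(2 pi f u) * exp(-(u^2+v^2)/(2 sigma^2))
    * 0.5`` about the mean level, with ``u`` the local coordinate along the
    carrier (modulation) direction, i.e. perpendicular to the element's
    stated orientation (the stripe direction). Overlapping patches sum about
    the mean; pixels are clipped to [0, 1] at the end.
    """
    display = display or DisplaySpec()
    gabor = gabor or GaborSpec()
    extent = display.extent_for(pattern, gabor)
    npix = int(math.ceil(extent / display.pixel_size))
    coords = (np.arange(npix) - (npix - 1) / 2.0) * display.pixel_size
    img = np.zeros((npix, npix))
    half = 4.0 * gabor.envelope_sigma
    for (cx, cy), ori in zip(pattern.layout.centers, pattern.element_orientations):
        ix = np.searchsorted(coords, [cx - half, cx + half])
        iy = np.searchsorted(coords, [cy - half, cy + half])
        xs = coords[ix[0] : ix[1]] - cx
        ys = coords[iy[0] : iy[1]] - cy
        if not len(xs) or not len(ys):
            continue
        X, Y = np.meshgrid(xs, ys)
        # carrier modulates perpendicular to the stripe orientation
        t = math.radians(ori)
        u = -X * math.sin(t) + Y * math.cos(t)
        env = np.exp(-(X * X + Y * Y) / (2.0 * gabor.envelope_sigma**2))
        patch = (
            gabor.contrast
            * np.cos(2.0 * math.pi * gabor.carrier_sf * u + gabor.carrier_phase)
            * env
            * 0.5
        )
        img[iy[0] : iy[1], ix[0] : ix[1]] += patch
    return np.clip(display.mean_level + img, 0.0, 1.0)


def build_trial(
    base: StimulusPattern, increment: StimulusPattern, rng: np.random.Generator
) -> Trial:
    """Randomize the 2AFC presentation order of a base/increment pair.

    The two patterns must agree everywhere except (at most) at the increment
    element.
    """
    if base.n != increment.n:
        raise ValueError("base and increment patterns have different sizes")
    diff = ~np.isclose(base.element_orientations, increment.element_orientations)
    allowed = np.zeros(base.n, bool)
    if increment.increment_index is not None:
        allowed[increment.increment_index] = True
    if np.any(diff & ~allowed):
        raise ValueError("patterns differ at a non-increment element")
    if rng.random() < 0.5:
        return Trial(first=increment, second=base, increment_interval=0)
    return Trial(first=base, second=increment, increment_interval=1)


def save_png(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Save a [0, 1] luminance image as an 8- or 16-bit grayscale PNG."""
    if bit_depth == 8:
        arr = np.round(image * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
    elif bit_depth == 16:
        arr = np.round(image * 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")
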