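"""ROI-based transparency of a cleared brain photographed over a grating.

The brain is photographed (focal plane on a background grating) before and
after clearing.  Four rectangular ROIs are placed on the post-clearing,
grating-focus image: ``a``/``b`` on a light/dark bar pair beside the brain,
``c``/``d`` on a light/dark pair seen through it.  From the ROI mean
intensities the Michelson contrast

    C = (I_max - I_min) / (I_max + I_min)

is formed for each pair, and the transparency is the contrast ratio

    t = C_brain / C_ctrl,

i.e. the fraction of grating contrast surviving passage through the whole
tissue thickness (1 = perfectly clear).  Because thicker brains attenuate
more, t is normalized by the medulla height h of the freshly fixed brain
relative to the cohort maximum:

    t_norm = t * h / h_max.

Note that t is invariant to a multiplicative gain applied to the image but
*not* to an additive offset (stray light or camera pedestal depresses both
contrasts), so dark-frame subtraction is the user's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    BoundsError,
    CohortError,
    ContrastError,
    SwappedRoiError,
    TransparencyError,
)
from .image_io import AnnotatedImagePair, Image2D, RoiRect
from .morphometry import medulla_height

__all__ = [
    "ContrastPair",
    "TransparencyResult",
    "roi_mean_intensity",
    "michelson_contrast",
    "transparency",
    "normalize_transparency",
    "compute_transparency",
]


@dataclass(frozen=True)
class ContrastPair:
    """Mean intensities of a light/dark ROI pair and their Michelson contrast."""

    i_max: float
    i_min: float
    c: float


@dataclass(frozen=True)
class TransparencyResult:
    """Transparency of one specimen, raw and thickness-normalized."""

    c_brain: float
    c_ctrl: float
    t: float
    h_um: float
    h_max_um: float
    t_norm: float
    #: True when noise pushed t above 1; the value is reported unclamped.
    t_above_one: bool = False


def roi_mean_intensity(image: Image2D, roi: RoiRect) -> float:
    """Arithmetic mean intensity over a half-open ROI rectangle."""
    h, w = image.shape
    if roi.x0 < 0 or roi.y0 < 0 or roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise BoundsError(
            f"ROI '{roi.label}' [{roi.x0},{roi.y0},{roi.width}x{roi.height}] "
            f"outside {w}x{h} image"
        )
    block = image.pixels[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width]
    return float(np.mean(np.asarray(block, dtype=float)))


def michelson_contrast(i_light: float, i_dark: float) -> ContrastPair:
    """Michelson contrast of a light/dark intensity pair.

    Raises
    ------
    ContrastError
        If both intensities are zero (contrast undefined).
    SwappedRoiError
        If the nominally light ROI is darker than the dark one — almost
        always a label swap in the annotation, so it is refused rather
        than silently returning a negative contrast.
    """
    if i_light < 0 or i_dark < 0:
        raise ContrastError("intensities must be non-negative")
    if i_light == 0 and i_dark == 0:
        raise ContrastError("contrast undefined: both ROI means are zero")
    if i_light < i_dark:
        raise SwappedRoiError(
            f"light ROI mean ({i_light:.6g}) below dark ROI mean ({i_dark:.6g}); "
            "check the a/b (or c/d) labels"
        )
    return ContrastPair(
        i_max=float(i_light),
        i_min=float(i_dark),
        c=(i_light - i_dark) / (i_light + i_dark),
    )


def transparency(c_brain: float, c_ctrl: float) -> float:
    """Contrast ratio t = C_brain / C_ctrl."""
    if c_ctrl <= 0:
        raise TransparencyError("transparency undefined: control contrast is zero")
    return c_brain / c_ctrl


def normalize_transparency(t: float, h_um: float, h_max_um: float) -> float:
    """Thickness-normalized transparency t_norm = t * h / h_max."""
    if h_um <= 0 or h_max_um <= 0:
        raise CohortError("medulla heights must be positive")
    if h_um > h_max_um:
        raise CohortError(
            f"medulla height {h_um:.6g} um exceeds cohort maximum {h_max_um:.6g} um"
        )
    return t * h_um / h_max_um


def compute_transparency(pair: AnnotatedImagePair, h_max_um: float) -> TransparencyResult:
    """Full per-specimen transparency computation from an annotated pair.

    ROIs a (light) and b (dark) give the control contrast, c (light) and
    d (dark) the through-brain contrast; h is the medulla-height landmark
    of the uncleared image converted to micrometres.
    """
    img = pair.post_image
    means = {lab: roi_mean_intensity(img, pair.rois_post[lab]) for lab in "abcd"}
    ctrl = michelson_contrast(means["a"], means["b"])
    brain = michelson_contrast(means["c"], means["d"])
    t = transparency(brain.c, ctrl.c)
    above = t > 1.0
    if above:
        warnings.warn(
            f"specimen {pair.specimen_id}: t = {t:.4f} > 1 (noise); reported unclamped",
            stacklevel=2,
        )
    h_um = medulla_height(pair)
    t_norm = normalize_transparency(t, h_um, h_max_um)
    return TransparencyResult(
        c_brain=brain.c,
        c_ctrl=ctrl.c,
        t=t,
        h_um=h_um,
        h_max_um=float(h_max_um),
        t_norm=t_norm,
        t_above_one=above,
    )
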