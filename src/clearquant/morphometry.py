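"""Landmark-distance morphometry: shrinkage as retained size.

The same anatomical landmark pair (typically the full brain length between
the lamina/outer-medulla margins of the two hemispheres) is identified on
the pre- and post-clearing photographs; the retained size is the physical
length ratio

    R = D_post / D_pre,

with R < 1 indicating shrinkage and R > 1 swelling.  Distances are computed
in micrometres so the two images may carry different magnifications.

The vertical extent of the medulla ("medulla height"), measured only on the
uncleared image, serves as the thickness proxy h for transparency
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import AnnotationError, DegenerateLandmarkError
from .image_io import AnnotatedImagePair, LandmarkSegment

__all__ = [
    "RetainedSizeResult",
    "segment_length",
    "retained_size",
    "medulla_height",
    "compute_retained_size",
]


@dataclass(frozen=True)
class RetainedSizeResult:
    d_pre_um: float
    d_post_um: float
    r: float


def segment_length(seg: LandmarkSegment, pixel_size_um: float) -> float:
    """Euclidean length of a landmark segment in micrometres."""
    if pixel_size_um <= 0:
        raise DegenerateLandmarkError("pixel_size_um must be positive")
    dx = seg.p2[0] - seg.p1[0]
    dy = seg.p2[1] - seg.p1[1]
    if dx == 0 and dy == 0:
        raise DegenerateLandmarkError(f"landmark '{seg.label}' has zero length")
    return math.hypot(dx, dy) * pixel_size_um


def retained_size(d_post_um: float, d_pre_um: float) -> float:
    """Retained size R = D_post / D_pre (not capped at 1)."""
    if d_pre_um <= 0 or d_post_um <= 0:
        raise DegenerateLandmarkError("landmark distances must be positive")
    return d_post_um / d_pre_um


def medulla_height(pair: AnnotatedImagePair) -> float:
    """Medulla height h (um) from the uncleared-image annotation."""
    if pair.medulla_height_pre is None:
        raise AnnotationError(
            f"specimen {pair.specimen_id}: medulla_height_pre annotation missing"
        )
    return segment_length(pair.medulla_height_pre, pair.pre_image.pixel_size_um)


def compute_retained_size(pair: AnnotatedImagePair) -> RetainedSizeResult:
    """Retained size of one specimen from its pre/post brain-length landmarks."""
    d_pre = segment_length(pair.brain_length_pre, pair.pre_image.pixel_size_um)
    d_post = segment_length(pair.brain_length_post, pair.post_image.pixel_size_um)
    return RetainedSizeResult(d_pre_um=d_pre, d_post_um=d_post, r=retained_size(d_post, d_pre))
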