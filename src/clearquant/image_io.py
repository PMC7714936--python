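"""Image and annotation I/O.

Reads the 2-D brain photographs and 3-D confocal bead stacks the pipeline
consumes (plain TIFF via :mod:`tifffile`), validates per-specimen annotation
documents (JSON, schema enforced with pydantic), and writes result tables
(CSV via pandas).

Conventions
-----------
* Pixel coordinates are 0-based ``(x, y)`` with y increasing downward.
* ROI rectangles are half-open: a rectangle covers pixels with
  ``x0 <= x < x0 + width`` and ``y0 <= y < y0 + height``.
* Physical pixel/voxel sizes are supplied by the caller or the annotation
  file, never parsed from TIFF tags (vendor tags are unreliable); a
  conflicting tag merely triggers a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, ValidationError as _PydanticValidationError

from .errors import AnnotationError, FormatError

__all__ = [
    "Image2D",
    "ImageStack3D",
    "RoiRect",
    "LandmarkSegment",
    "AnnotatedImagePair",
    "load_image",
    "load_stack",
    "write_image",
    "write_stack",
    "load_annotations",
    "load_annotated_pair",
    "write_results_table",
    "RESULT_COLUMNS",
]

#: Column order of the per-specimen results CSV.
RESULT_COLUMNS = [
    "specimen_id",
    "treatment",
    "c_brain",
    "c_ctrl",
    "t",
    "h_um",
    "h_max_um",
    "t_norm",
    "d_pre_um",
    "d_post_um",
    "retained_size",
]


@dataclass(frozen=True)
class Image2D:
    """A single grayscale photograph with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (arbitrary units).  Float
        arrays are accepted so that synthetic images with additive noise
        can be carried without premature quantization.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    bit_depth
        Nominal camera bit depth, 8 or 16; intensities must not exceed
        ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"image must be 2-D and non-empty, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        if px.size and float(px.min()) < 0:
            raise FormatError("image intensities must be non-negative")
        if px.size and float(px.max()) > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensity {float(px.max())} exceeds 2^{self.bit_depth}-1"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (height, width)


@dataclass(frozen=True)
class ImageStack3D:
    """A confocal z-series ordered ``(z, y, x)`` with voxel pitch in um."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]  # (dz, dy, dx)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise FormatError(f"stack must be 3-D and non-empty, got shape {v.shape}")
        if len(self.voxel_size_um) != 3 or any(s <= 0 for s in self.voxel_size_um):
            raise FormatError("voxel_size_um must be three positive lengths (dz, dy, dx)")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "voxel_size_um", tuple(float(s) for s in self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned half-open ROI rectangle with a contrast label a/b/c/d.

    Labels ``a``/``b`` are the light/dark grating bars beside the brain,
    ``c``/``d`` the light/dark bars seen through it.
    """

    x0: int
    y0: int
    width: int
    height: int
    label: Literal["a", "b", "c", "d"]

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise AnnotationError(
                f"ROI '{self.label}': width and height must be >= 1"
            )
        if self.label not in ("a", "b", "c", "d"):
            raise AnnotationError(f"ROI label must be one of a/b/c/d, got {self.label!r}")

    def check_inside(self, image: Image2D) -> None:
        h, w = image.shape
        if self.x0 < 0 or self.y0 < 0 or self.x0 + self.width > w or self.y0 + self.height > h:
            raise AnnotationError(
                f"ROI '{self.label}' [{self.x0},{self.y0},{self.width}x{self.height}] "
                f"extends outside the {w}x{h} image"
            )


@dataclass(frozen=True)
class LandmarkSegment:
    """A straight segment between two (sub-pixel) landmark coordinates."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise AnnotationError(f"landmark '{self.label}': p1 equals p2")
        object.__setattr__(self, "p1", (float(self.p1[0]), float(self.p1[1])))
        object.__setattr__(self, "p2", (float(self.p2[0]), float(self.p2[1])))


@dataclass
class AnnotatedImagePair:
    """All inputs for one specimen: pre/post images, ROIs and landmarks."""

    specimen_id: str
    treatment: str
    pre_image: Image2D
    post_image: Image2D
    rois_post: dict[str, RoiRect]
    brain_length_pre: LandmarkSegment
    brain_length_post: LandmarkSegment
    medulla_height_pre: LandmarkSegment | None = None

    def __post_init__(self) -> None:
        labels = sorted(self.rois_post)
        if labels != ["a", "b", "c", "d"]:
            raise AnnotationError(
                f"specimen {self.specimen_id}: ROI labels must be exactly a,b,c,d "
                f"(got {labels})"
            )
        for roi in self.rois_post.values():
            roi.check_inside(self.post_image)
        if self.brain_length_pre.label != self.brain_length_post.label:
            raise AnnotationError(
                f"specimen {self.specimen_id}: pre/post brain-length labels differ"
            )


# ---------------------------------------------------------------------------
# TIFF reading / writing
# ---------------------------------------------------------------------------

def _to_grayscale(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # unweighted channel mean; alpha (if any) is dropped
        return arr[..., :3].mean(axis=-1)
    raise FormatError(f"{path}: unsupported image layout with shape {arr.shape}")


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    # floats from RGB averaging keep 16-bit headroom
    return 16 if float(np.max(arr, initial=0)) > 255 else 8


def load_image(path: str | Path, pixel_size_um: float) -> Image2D:
    """Load a single-page grayscale (or RGB) TIFF as :class:`Image2D`.

    RGB input is converted to grayscale with the unweighted channel mean.
    A resolution tag that conflicts with ``pixel_size_um`` triggers a
    warning, never an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tag_size = _pixel_size_from_tags(page)
    if arr.dtype.kind not in "uif":
        raise FormatError(f"{path}: unsupported sample format {arr.dtype}")
    arr = _to_grayscale(np.asarray(arr), path)
    if tag_size is not None and not np.isclose(tag_size, pixel_size_um, rtol=0.05):
        warnings.warn(
            f"{path}: TIFF resolution tag implies {tag_size:.4g} um/px but "
            f"{pixel_size_um:.4g} um/px was supplied; using the supplied value",
            stacklevel=2,
        )
    return Image2D(pixels=arr, pixel_size_um=float(pixel_size_um), bit_depth=_bit_depth_of(arr))


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
    except (KeyError, AttributeError):
        return None
    try:
        num, den = xres
        if num == 0 or den == 0:
            return None
        per_unit = num / den
        unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", unit), None)
        if unit_um is None:
            return None
        return unit_um / per_unit
    except Exception:
        return None


def load_stack(path: str | Path, voxel_size_um: Sequence[float]) -> ImageStack3D:
    """Load a multi-page TIFF as a z-stack; pages become z-slices in order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pages = [np.asarray(p.asarray()) for p in tif.pages]
    if not pages:
        raise FormatError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"{path}: ragged page shapes {sorted(shapes)}")
    vox = np.stack(pages, axis=0)
    if vox.ndim == 4:  # single page already carried a z axis
        vox = vox.reshape(-1, *vox.shape[-2:])
    return ImageStack3D(voxels=vox, voxel_size_um=tuple(float(s) for s in voxel_size_um))


def write_image(image: Image2D, path: str | Path) -> None:
    """Write an :class:`Image2D` as an integer TIFF at its stated bit depth."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    data = np.round(np.asarray(image.pixels, dtype=float)).astype(dtype)
    tifffile.imwrite(Path(path), data)


def write_stack(stack: ImageStack3D, path: str | Path, dtype=np.uint16) -> None:
    data = np.round(np.asarray(stack.voxels, dtype=float)).clip(0, np.iinfo(dtype).max)
    tifffile.imwrite(Path(path), data.astype(dtype))


# ---------------------------------------------------------------------------
# Annotation JSON
# ---------------------------------------------------------------------------

class _RoiModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: Literal["a", "b", "c", "d"]
    x0: int
    y0: int
    width: int
    height: int


class _LandmarksModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    brain_length_pre: tuple[tuple[float, float], tuple[float, float]]
    brain_length_post: tuple[tuple[float, float], tuple[float, float]]
    medulla_height_pre: tuple[tuple[float, float], tuple[float, float]] | None = None


class AnnotationDocument(BaseModel):
    """Schema of one per-specimen annotation JSON document."""

    model_config = ConfigDict(extra="forbid")
    specimen_id: str
    treatment: str
    pre_image: str
    post_image: str
    pixel_size_um: float
    pixel_size_um_post: float | None = None  # optional per-image override
    rois: list[_RoiModel]
    landmarks: _LandmarksModel


def load_annotations(path: str | Path) -> AnnotationDocument:
    """Parse and schema-validate an annotation JSON document.

    Image files are not opened here; ROI bounds are checked when the images
    are loaded by :func:`load_annotated_pair`.
    """
    path = Path(path)
    try:
        doc = AnnotationDocument.model_validate(json.loads(path.read_text()))
    except _PydanticValidationError as exc:
        raise AnnotationError(f"{path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: invalid JSON ({exc})") from exc
    labels = [r.label for r in doc.rois]
    if sorted(labels) != ["a", "b", "c", "d"]:
        raise AnnotationError(
            f"{path}: ROI labels must be exactly a,b,c,d without duplicates, got {labels}"
        )
    if doc.pixel_size_um <= 0:
        raise AnnotationError(f"{path}: pixel_size_um must be positive")
    for name in ("brain_length_pre", "brain_length_post", "medulla_height_pre"):
        seg = getattr(doc.landmarks, name)
        if seg is not None and tuple(seg[0]) == tuple(seg[1]):
            raise AnnotationError(f"{path}: landmark '{name}' has p1 == p2")
    return doc


def load_annotated_pair(path: str | Path) -> AnnotatedImagePair:
    """Load an annotation document and its referenced images into memory."""
    path = Path(path)
    doc = load_annotations(path)
    base = path.parent
    pre = load_image(base / doc.pre_image, doc.pixel_size_um)
    post = load_image(base / doc.post_image, doc.pixel_size_um_post or doc.pixel_size_um)
    rois = {
        r.label: RoiRect(x0=r.x0, y0=r.y0, width=r.width, height=r.height, label=r.label)
        for r in doc.rois
    }
    lm = doc.landmarks
    medulla = None
    if lm.medulla_height_pre is not None:
        medulla = LandmarkSegment(*lm.medulla_height_pre, label="medulla_height")
    pair = AnnotatedImagePair(
        specimen_id=doc.specimen_id,
        treatment=doc.treatment,
        pre_image=pre,
        post_image=post,
        rois_post=rois,
        brain_length_pre=LandmarkSegment(*lm.brain_length_pre, label="brain_length"),
        brain_length_post=LandmarkSegment(*lm.brain_length_post, label="brain_length"),
        medulla_height_pre=medulla,
    )
    return pair


# ---------------------------------------------------------------------------
# Results CSV
# ---------------------------------------------------------------------------

def write_results_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write per-specimen results as CSV with the canonical column set.

    Floats are serialized with 8 significant digits, comfortably above the
    6 s.f. round-trip contract.
    """
    df = pd.DataFrame(list(rows), columns=RESULT_COLUMNS)
    df.to_csv(Path(path), index=False, float_format="%.8g")
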