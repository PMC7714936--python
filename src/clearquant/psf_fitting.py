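"""Point-spread-function estimation from fluorescent nanobead z-stacks.

Sub-resolution (200 nm) polystyrene beads are imaged as confocal z-series.
For each isolated bead the slice with the highest mean intensity is
selected, 1-D intensity profiles are extracted through the maximum-intensity
voxel along x, y (in-slice) and z, and each profile is fitted with a model
of the PSF: a Gaussian

    g(x) = a + b * exp(-(x - mu)^2 / (2 sigma^2))

whose peak shape is convolved with a unit top-hat of width equal to the
bead diameter (centred at a fitted position e), to account for the bead
being near-resolvable rather than a point source.  The convolved shape is
renormalized to unit peak before the intensity scaling is applied, so ``a``
remains the luminance offset and ``a + b`` the peak intensity.  The FWHM is
then taken from the Gaussian component alone:

    FWHM = 2 * sqrt(2 ln 2) * sigma,

i.e. the bead-size contribution is removed by the deconvolution implicit in
the fit.  Per condition, the lateral FWHM of a bead is the mean of its x-
and y-profile FWHMs and the axial FWHM is the z-profile FWHM; summaries are
means with standard errors across beads.

Note ``mu`` and ``e`` enter the convolved model only through their sum (the
peak sits at ``mu + e``), so they are not separately identifiable; ``e`` is
softly bounded near its initial value to keep the fit well-posed, and only
``sigma`` carries physical meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import BoundsError, EdgeBeadError, FormatError, NoBeadsError
from .image_io import ImageStack3D

__all__ = [
    "BeadDetection",
    "ProfileVector",
    "PsfModelFit",
    "FwhmSummary",
    "detect_beads",
    "best_slice",
    "extract_profile",
    "model_profile",
    "fit_psf_model",
    "fwhm_from_sigma",
    "summarize_fwhm",
    "analyze_bead_stack",
]

#: FWHM of a unit-sigma Gaussian.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class BeadDetection:
    """One connected bright component assumed to be a single bead."""

    centroid: tuple[float, float, float]  # (z, y, x) voxel coordinates
    peak_intensity: float
    #: half-open voxel ranges ((z0, z1), (y0, y1), (x0, x1))
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class ProfileVector:
    """A uniformly spaced 1-D intensity profile in physical units."""

    positions: np.ndarray  # um, centred on the extraction voxel
    intensities: np.ndarray
    axis: Literal["x", "y", "z"]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.size < 7:
            raise FormatError(f"profile needs >= 7 samples, got {pos.size}")
        if inten.shape != pos.shape:
            raise FormatError("positions and intensities must have equal length")
        steps = np.diff(pos)
        if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=0):
            raise FormatError("profile positions must be strictly increasing and uniform")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class PsfModelFit:
    """Fitted parameters of the Gaussian ⊗ top-hat profile model."""

    a: float
    b: float
    mu: float
    sigma: float
    e: float
    bead_diameter_um: float
    residual_rms: float
    converged: bool

    @property
    def fwhm_um(self) -> float:
        return fwhm_from_sigma(self.sigma)


@dataclass(frozen=True)
class FwhmSummary:
    """Per-condition FWHM summary across beads (mean and SEM)."""

    lateral_fwhm_um: float
    axial_fwhm_um: float
    n_beads: int
    sem_lateral_um: float
    sem_axial_um: float


# ---------------------------------------------------------------------------
# Detection and profile extraction
# ---------------------------------------------------------------------------

def detect_beads(
    stack: ImageStack3D,
    threshold_rel: float = 0.5,
    min_separation_um: float = 2.0,
) -> list[BeadDetection]:
    """Find isolated beads as connected components above a relative threshold.

    Components whose centroids lie closer than ``min_separation_um`` are
    discarded *pairwise* (both members removed): an overlapping neighbour
    contaminates the profile tails and biases sigma upward, so neither
    partner is trusted.
    """
    if not 0 < threshold_rel < 1:
        raise ValueError("threshold_rel must be in (0, 1)")
    vox = np.asarray(stack.voxels, dtype=float)
    vmax = float(vox.max(initial=0.0))
    if vmax <= 0:
        raise NoBeadsError("stack is empty or all-zero")
    mask = vox > threshold_rel * vmax
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoBeadsError("no voxel exceeds the detection threshold")
    idx = list(range(1, n + 1))
    coms = ndimage.center_of_mass(vox, labels, idx)
    peaks = ndimage.maximum(vox, labels, idx)
    slices = ndimage.find_objects(labels)
    dets = [
        BeadDetection(
            centroid=tuple(float(c) for c in com),
            peak_intensity=float(pk),
            bbox=tuple((s.start, s.stop) for s in sl),
        )
        for com, pk, sl in zip(coms, peaks, slices)
    ]
    pitch = np.asarray(stack.voxel_size_um)
    keep = np.ones(len(dets), dtype=bool)
    for i in range(len(dets)):
        for j in range(i + 1, len(dets)):
            d_um = np.linalg.norm(
                (np.asarray(dets[i].centroid) - np.asarray(dets[j].centroid)) * pitch
            )
            if d_um < min_separation_um:
                keep[i] = keep[j] = False
    return [d for d, k in zip(dets, keep) if k]


def best_slice(stack: ImageStack3D, detection: BeadDetection) -> int:
    """z index maximizing mean intensity over the bead's (y, x) footprint.

    Ties break to the lowest z.
    """
    (_, _), (y0, y1), (x0, x1) = detection.bbox
    means = np.asarray(stack.voxels, dtype=float)[:, y0:y1, x0:x1].mean(axis=(1, 2))
    return int(np.argmax(means))


def _max_voxel(vox: np.ndarray, bbox) -> tuple[int, int, int]:
    """Global max voxel inside bbox; ties first in (z, y, x) order."""
    (z0, z1), (y0, y1), (x0, x1) = bbox
    sub = vox[z0:z1, y0:y1, x0:x1]
    zi, yi, xi = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return z0 + zi, y0 + yi, x0 + xi


def extract_profile(
    stack: ImageStack3D,
    detection: BeadDetection,
    axis: Literal["x", "y", "z"],
    half_width_um: float,
) -> ProfileVector:
    """1-D intensity profile through the bead's maximum-intensity voxel.

    x/y profiles are taken in the best slice through the in-slice maximum;
    the z profile runs through the global maximum voxel of the detection.
    Positions are micrometres centred on that voxel.
    """
    vox = np.asarray(stack.voxels, dtype=float)
    dz, dy, dx = stack.voxel_size_um
    if axis in ("x", "y"):
        z = best_slice(stack, detection)
        (y0, y1), (x0, x1) = detection.bbox[1], detection.bbox[2]
        sub = vox[z, y0:y1, x0:x1]
        yi, xi = np.unravel_index(int(np.argmax(sub)), sub.shape)
        zc, yc, xc = z, y0 + yi, x0 + xi
    elif axis == "z":
        zc, yc, xc = _max_voxel(vox, detection.bbox)
    else:
        raise ValueError(f"axis must be x, y or z, got {axis!r}")

    pitch = {"x": dx, "y": dy, "z": dz}[axis]
    centre = {"x": xc, "y": yc, "z": zc}[axis]
    dim = {"x": vox.shape[2], "y": vox.shape[1], "z": vox.shape[0]}[axis]
    n = int(round(half_width_um / pitch))
    if centre - n < 0 or centre + n >= dim:
        raise EdgeBeadError(
            f"{axis}-profile window (±{n} voxels around {centre}) clipped by the "
            f"stack edge (axis extent {dim})"
        )
    if axis == "x":
        line = vox[zc, yc, centre - n : centre + n + 1]
    elif axis == "y":
        line = vox[zc, centre - n : centre + n + 1, xc]
    else:
        line = vox[centre - n : centre + n + 1, yc, xc]
    positions = (np.arange(-n, n + 1, dtype=float)) * pitch
    return ProfileVector(positions=positions, intensities=np.asarray(line), axis=axis)


# ---------------------------------------------------------------------------
# Profile model
# ---------------------------------------------------------------------------

def _tophat_midpoints(e: float, diameter: float, step: float) -> np.ndarray:
    m = max(1, int(round(diameter / step)))
    return e - diameter / 2.0 + step * (np.arange(m) + 0.5)


def model_profile(
    positions: np.ndarray,
    a: float,
    b: float,
    mu: float,
    sigma: float,
    e: float,
    bead_diameter_um: float,
    oversample: int = 10,
    literal: bool = False,
) -> np.ndarray:
    """Evaluate the Gaussian ⊗ top-hat profile model at ``positions``.

    Default (peak-shape) form: the unit-amplitude Gaussian centred at ``mu``
    is convolved with a unit top-hat of width ``bead_diameter_um`` centred
    at ``e`` (midpoint-rule sum on a grid ``oversample`` times finer than
    the sample spacing, since the bead can be narrower than a voxel), the
    convolved shape is normalized to unit maximum, and the intensity model
    ``a + b * shape`` is returned.  The peak therefore sits at ``mu + e``
    with value ``a + b``.  With ``bead_diameter_um`` below one fine-grid
    step the top-hat degenerates to a delta and the model reduces to the
    plain Gaussian ``a + b * exp(-(x - mu - e)^2 / (2 sigma^2))`` evaluated
    analytically.

    ``literal=True`` instead composes the operations in their raw order —
    convolve the *offset* Gaussian ``a + b*exp(...)`` with a ones-vector
    top-hat, then rescale by ``b / max`` — which distorts the offset; it is
    provided only for comparison with that composition.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if bead_diameter_um < 0:
        raise ValueError("bead_diameter_um must be non-negative")
    pos = np.asarray(positions, dtype=float)
    spacing = float(np.min(np.diff(np.sort(pos)))) if pos.size > 1 else sigma
    step = spacing / oversample

    def gauss(x: np.ndarray, centre_shift: float = 0.0) -> np.ndarray:
        return np.exp(-((x - mu - centre_shift) ** 2) / (2.0 * sigma**2))

    if not literal and bead_diameter_um < step:
        return a + b * gauss(pos, e)

    mids = _tophat_midpoints(e, max(bead_diameter_um, step), step)
    # normalization grid spans the data and the analytic peak location
    lo = min(pos.min(), mu + e) - max(bead_diameter_um, sigma)
    hi = max(pos.max(), mu + e) + max(bead_diameter_um, sigma)
    fine = np.arange(lo, hi + step / 2.0, step)
    fine = np.append(fine, mu + e)

    # direct midpoint-rule convolution sum, exact at the requested points
    def shape_plain(x: np.ndarray) -> np.ndarray:
        return np.exp(
            -((x[:, None] - mids[None, :] - mu) ** 2) / (2.0 * sigma**2)
        ).sum(axis=1) / len(mids)

    if literal:
        def y_un(x: np.ndarray) -> np.ndarray:
            return (
                a
                + b
                * np.exp(-((x[:, None] - mids[None, :] - mu) ** 2) / (2.0 * sigma**2))
            ).sum(axis=1)

        norm = float(y_un(fine).max())
        return b * y_un(pos) / norm

    norm = float(shape_plain(fine).max())
    return a + b * shape_plain(pos) / norm


def fwhm_from_sigma(sigma: float) -> float:
    """FWHM of a Gaussian with standard deviation ``sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return FWHM_FACTOR * sigma


def _naive_fwhm(pos: np.ndarray, inten: np.ndarray) -> float | None:
    """Half-max crossing width by linear interpolation, or None if undefined."""
    lo, hi = float(inten.min()), float(inten.max())
    if hi <= lo:
        return None
    half = (lo + hi) / 2.0
    above = inten >= half
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    left_i, right_i = idx[0], idx[-1]

    def crossing(i0: int, i1: int) -> float:
        y0, y1 = inten[i0], inten[i1]
        if y1 == y0:
            return float(pos[i1])
        frac = (half - y0) / (y1 - y0)
        return float(pos[i0] + frac * (pos[i1] - pos[i0]))

    left = crossing(left_i - 1, left_i) if left_i > 0 else float(pos[0])
    right = crossing(right_i + 1, right_i) if right_i < len(pos) - 1 else float(pos[-1])
    width = right - left
    return width if width > 0 else None


def fit_psf_model(profile: ProfileVector, bead_diameter_um: float) -> PsfModelFit:
    """Non-linear least-squares fit of the profile model.

    Initialization: offset from the profile minimum, amplitude from the
    range, centre at the maximum sample, sigma from the naive half-max
    width (floored at half the sample spacing); the top-hat centre starts
    at the Gaussian centre and is bounded within ±2 initial sigma of it.
    Non-convergence is reported through the ``converged`` flag, never as an
    exception.
    """
    pos = profile.positions
    inten = profile.intensities
    spacing = profile.spacing
    span = float(pos[-1] - pos[0])

    a0 = float(inten.min())
    ptp = float(inten.max() - inten.min())
    mu0 = float(pos[int(np.argmax(inten))])
    width = _naive_fwhm(pos, inten)
    sigma0 = max((width / FWHM_FACTOR) if width else spacing, spacing / 2.0)
    sigma0 = min(sigma0, span)
    e0 = mu0

    if ptp <= 0:  # flat profile: nothing to fit
        return PsfModelFit(
            a=a0, b=np.finfo(float).tiny, mu=mu0, sigma=sigma0, e=e0,
            bead_diameter_um=float(bead_diameter_um),
            residual_rms=0.0, converged=False,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, mu, sigma, e = theta
        return model_profile(pos, a, b, mu, sigma, e, bead_diameter_um) - inten

    lower = [-np.inf, 1e-12, float(pos[0]), 1e-6 * spacing, e0 - 2 * sigma0]
    upper = [np.inf, np.inf, float(pos[-1]), span, e0 + 2 * sigma0]
    x0 = np.clip([a0, ptp, mu0, sigma0, e0], lower, upper)
    try:
        res = optimize.least_squares(
            residuals, x0, bounds=(lower, upper), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        a, b, mu, sigma, e = (float(v) for v in res.x)
        rms = float(np.sqrt(np.mean(res.fun**2)))
        converged = bool(res.success) and b > 1e-6 * ptp
    except Exception:
        a, b, mu, sigma, e = a0, ptp, mu0, sigma0, e0
        rms = float(np.sqrt(np.mean(residuals(np.array(x0)) ** 2)))
        converged = False
    return PsfModelFit(
        a=a, b=b, mu=mu, sigma=sigma, e=e,
        bead_diameter_um=float(bead_diameter_um),
        residual_rms=rms, converged=converged,
    )


# ---------------------------------------------------------------------------
# Summaries and stack-level pipeline
# ---------------------------------------------------------------------------

def summarize_fwhm(bead_fits: Sequence[Mapping[str, PsfModelFit]]) -> FwhmSummary:
    """Mean and SEM of lateral and axial FWHM across beads.

    Each element maps axis names ``x``, ``y``, ``z`` to that bead's fits.
    Lateral FWHM of a bead is the mean of its x- and y-fit FWHMs; axial is
    the z-fit FWHM.  SEM uses the sample standard deviation (n-1); with a
    single bead it is reported as 0.
    """
    if len(bead_fits) == 0:
        raise NoBeadsError("no beads to summarize")
    lat = np.array(
        [(fits["x"].fwhm_um + fits["y"].fwhm_um) / 2.0 for fits in bead_fits]
    )
    ax = np.array([fits["z"].fwhm_um for fits in bead_fits])
    n = len(bead_fits)
    sem = lambda v: float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return FwhmSummary(
        lateral_fwhm_um=float(lat.mean()),
        axial_fwhm_um=float(ax.mean()),
        n_beads=n,
        sem_lateral_um=sem(lat),
        sem_axial_um=sem(ax),
    )


def analyze_bead_stack(
    stack: ImageStack3D,
    bead_diameter_um: float = 0.2,
    threshold_rel: float = 0.5,
    min_separation_um: float = 2.0,
    half_width_lat_um: float = 0.6,
    half_width_ax_um: float = 1.5,
) -> tuple[list[dict[str, PsfModelFit]], int]:
    """Detect beads and fit x/y/z profiles for each.

    Returns the per-bead fit triplets (edge-clipped beads skipped) and the
    number of beads excluded for clipping or non-convergence.
    """
    detections = detect_beads(stack, threshold_rel, min_separation_um)
    if not detections:
        raise NoBeadsError("all detections discarded as non-isolated")
    fits: list[dict[str, PsfModelFit]] = []
    excluded = 0
    for det in detections:
        try:
            triplet = {
                ax: fit_psf_model(
                    extract_profile(
                        stack, det, ax,
                        half_width_lat_um if ax in ("x", "y") else half_width_ax_um,
                    ),
                    bead_diameter_um,
                )
                for ax in ("x", "y", "z")
            }
        except (EdgeBeadError, BoundsError):
            excluded += 1
            continue
        if all(f.converged for f in triplet.values()):
            fits.append(triplet)
        else:
            excluded += 1
    if not fits:
        raise NoBeadsError("no bead produced a converged x/y/z fit triplet")
    return fits, excluded
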