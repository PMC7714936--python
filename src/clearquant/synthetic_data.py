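"""Synthetic scenes with exact ground truth for validating the pipeline.

Two generators emulate the study's measurement setups:

* :func:`generate_grating_scene` builds a pre/post photograph pair of a
  semi-transparent elliptical "brain" over a square-wave background grating
  (a resolution-test-target pattern).  Inside the brain the grating's AC
  component is multiplied by a known attenuation factor ``tau`` — pure
  contrast reduction, no blur — so the measured transparency equals ``tau``
  analytically.  The pre-clearing brain is rendered at ``1/scale`` times
  the post size, so the retained size equals ``scale`` exactly from the
  auto-generated landmarks.  Default geometry mimics a large fly brain:
  about 3000 x 1500 um at 5 um per pixel.

* :func:`generate_bead_stack` renders sub-resolution fluorescent beads
  blurred by an anisotropic Gaussian PSF into a confocal-like z-stack with
  Poisson-Gaussian noise at a stated peak SNR.  The default bead footprint
  is a separable box (a 200 nm rect along each axis), which makes the
  1-D Gaussian ⊗ top-hat profile model *exact* along each axis, so the full
  fitting pipeline can be validated against the known sigmas; a solid-
  sphere footprint is available for robustness experiments where the 1-D
  model is only approximate.

:func:`generate_cohort` writes a directory of TIFFs and annotation JSONs
consumable by the CLI unchanged, plus a ground-truth table.  All
randomness flows from the stated seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError
from .image_io import (
    AnnotatedImagePair,
    Image2D,
    ImageStack3D,
    LandmarkSegment,
    RoiRect,
    write_image,
)

__all__ = [
    "SceneGroundTruth",
    "BeadSceneGroundTruth",
    "GratingScene",
    "TreatmentSpec",
    "generate_grating_scene",
    "generate_bead_stack",
    "generate_cohort",
]


@dataclass(frozen=True)
class SceneGroundTruth:
    """Parameters of one synthetic grating scene.

    ``brain_ellipse`` is the *pre-clearing* ellipse (centre x, centre y,
    semi-axis x, semi-axis y, in pixels); the post-clearing ellipse is the
    same shape scaled by ``scale``.  The default 300 x 150 px semi-axes at
    5 um/px reproduce the ~3000 x 1500 um footprint of a fresh fly brain.
    """

    tau: float = 0.6
    scale: float = 0.85
    grating_period_px: int = 40
    grating_contrast: float = 0.5
    brain_ellipse: tuple[float, float, float, float] = (384.0, 224.0, 300.0, 150.0)
    noise_sigma: float = 0.0
    seed: int = 0
    image_shape: tuple[int, int] = (448, 768)  # (height, width)
    pixel_size_um: float = 5.0
    bit_depth: int = 8
    mean_level: float = 120.0
    landmark_jitter_px: float = 0.0
    pre_opacity_tau: float = 0.05  # residual grating contrast through the fresh brain

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise GeometryError("tau must be in (0, 1]")
        if self.scale <= 0:
            raise GeometryError("scale must be positive")
        if not 0 < self.grating_contrast <= 1:
            raise GeometryError("grating_contrast must be in (0, 1]")
        if self.grating_period_px < 4 or self.grating_period_px % 2:
            raise GeometryError("grating_period_px must be even and >= 4")
        if self.mean_level * (1 + self.grating_contrast) > 2**self.bit_depth - 1:
            raise GeometryError("light bars would exceed the bit depth")


@dataclass
class GratingScene:
    """A rendered scene plus the auto-annotations and its ground truth."""

    pre_image: Image2D
    post_image: Image2D
    rois_post: dict[str, RoiRect]
    brain_length_pre: LandmarkSegment
    brain_length_post: LandmarkSegment
    medulla_height_pre: LandmarkSegment
    truth: SceneGroundTruth

    def as_pair(self, specimen_id: str = "#00", treatment: str = "synthetic") -> AnnotatedImagePair:
        return AnnotatedImagePair(
            specimen_id=specimen_id,
            treatment=treatment,
            pre_image=self.pre_image,
            post_image=self.post_image,
            rois_post=self.rois_post,
            brain_length_pre=self.brain_length_pre,
            brain_length_post=self.brain_length_post,
            medulla_height_pre=self.medulla_height_pre,
        )


def _render(
    truth: SceneGroundTruth,
    ellipse: tuple[float, float, float, float],
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = truth.image_shape
    half = truth.grating_period_px // 2
    cols = np.arange(w)
    light = (cols // half) % 2 == 0
    amp = truth.mean_level * truth.grating_contrast
    row = np.where(light, amp, -amp)
    img = truth.mean_level + np.broadcast_to(row, (h, w)).copy()

    cx, cy, ax, by = ellipse
    X, Y = np.meshgrid(cols.astype(float), np.arange(h, dtype=float))
    inside = ((X - cx) / ax) ** 2 + ((Y - cy) / by) ** 2 <= 1.0
    img[inside] = truth.mean_level + tau * (img[inside] - truth.mean_level)

    img = np.round(img)  # quantize to the integer camera grid
    if truth.noise_sigma > 0:
        img = img + rng.normal(0.0, truth.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 2**truth.bit_depth - 1)


def _place_rois(truth: SceneGroundTruth, post_ellipse) -> dict[str, RoiRect]:
    h, w = truth.image_shape
    half = truth.grating_period_px // 2
    roi_w = max(2, half - 4)
    roi_h = 32
    cx, cy, ax, by = post_ellipse

    def bar_x0(bar_index: int) -> int:
        return bar_index * half + (half - roi_w) // 2

    def corners_status(x0: int, y0: int) -> tuple[bool, bool]:
        xs = np.array([x0, x0 + roi_w - 1], dtype=float)
        ys = np.array([y0, y0 + roi_h - 1], dtype=float)
        Xc, Yc = np.meshgrid(xs, ys)
        r2 = ((Xc - cx) / ax) ** 2 + ((Yc - cy) / by) ** 2
        return bool((r2 <= 0.95).all()), bool((r2 >= 1.05).all())

    # control pair (a light, b dark): first two bars, top-left corner
    y_out = 8
    a = RoiRect(x0=bar_x0(0), y0=y_out, width=roi_w, height=roi_h, label="a")
    b = RoiRect(x0=bar_x0(1), y0=y_out, width=roi_w, height=roi_h, label="b")
    for roi in (a, b):
        _, outside = corners_status(roi.x0, roi.y0)
        if not outside or roi.x0 + roi_w > w or y_out + roi_h > h:
            raise GeometryError("cannot place control ROIs outside the brain ellipse")

    # brain pair (c light, d dark): bar pair nearest the ellipse centre
    kc = int(cx // half)
    k_light = kc if kc % 2 == 0 else kc - 1
    y_in = int(round(cy - roi_h / 2))
    c = RoiRect(x0=bar_x0(k_light), y0=y_in, width=roi_w, height=roi_h, label="c")
    d = RoiRect(x0=bar_x0(k_light + 1), y0=y_in, width=roi_w, height=roi_h, label="d")
    for roi in (c, d):
        inside, _ = corners_status(roi.x0, roi.y0)
        if not inside:
            raise GeometryError(
                "brain ellipse too small to hold a full light/dark bar pair"
            )
    return {"a": a, "b": b, "c": c, "d": d}


def generate_grating_scene(truth: SceneGroundTruth) -> GratingScene:
    """Render a pre/post scene pair with auto-placed ROIs and landmarks.

    Contrast through the post-clearing brain equals ``tau`` times the
    control contrast by construction; when ``tau * mean_level *
    grating_contrast`` is an integer, quantization is exact and the
    measured transparency equals ``tau`` to machine precision at zero
    noise.  The landmark pre/post length ratio equals ``scale`` exactly
    (before optional jitter).
    """
    h, w = truth.image_shape
    cx, cy, ax_pre, by_pre = truth.brain_ellipse
    for a_, b_ in ((ax_pre, by_pre), (ax_pre * truth.scale, by_pre * truth.scale)):
        if cx - a_ < 0 or cx + a_ >= w or cy - b_ < 0 or cy + b_ >= h:
            raise GeometryError("brain ellipse does not fit inside the image")
    post_ellipse = (cx, cy, ax_pre * truth.scale, by_pre * truth.scale)

    rng = np.random.default_rng(truth.seed)
    pre_px = _render(truth, truth.brain_ellipse, truth.pre_opacity_tau, rng)
    post_px = _render(truth, post_ellipse, truth.tau, rng)
    rois = _place_rois(truth, post_ellipse)

    jit = truth.landmark_jitter_px

    def seg(p1, p2, label) -> LandmarkSegment:
        if jit > 0:
            p1 = tuple(np.asarray(p1) + rng.normal(0, jit, 2))
            p2 = tuple(np.asarray(p2) + rng.normal(0, jit, 2))
        return LandmarkSegment(p1=tuple(p1), p2=tuple(p2), label=label)

    mk = Image2D
    return GratingScene(
        pre_image=mk(pre_px, truth.pixel_size_um, truth.bit_depth),
        post_image=mk(post_px, truth.pixel_size_um, truth.bit_depth),
        rois_post=rois,
        brain_length_pre=seg((cx - ax_pre, cy), (cx + ax_pre, cy), "brain_length"),
        brain_length_post=seg(
            (cx - ax_pre * truth.scale, cy), (cx + ax_pre * truth.scale, cy), "brain_length"
        ),
        medulla_height_pre=seg((cx, cy - by_pre), (cx, cy + by_pre), "medulla_height"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Bead stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadSceneGroundTruth:
    """Parameters of one synthetic nanobead z-stack.

    Defaults reproduce the study conditions: 200 nm beads, five per stack,
    an anisotropic PSF (axial width about three times lateral) and 2x
    lateral oversampling relative to a ~0.1 um confocal pixel.
    """

    sigma_lat_um: float = 0.12
    sigma_ax_um: float = 0.35
    bead_diameter_um: float = 0.2
    voxel_pitch_um: tuple[float, float, float] = (0.1, 0.05, 0.05)  # (dz, dy, dx)
    n_beads: int = 5
    snr: float = 30.0  # peak signal over total noise s.d.; inf = noise-free
    seed: int = 0
    stack_shape: tuple[int, int, int] = (48, 192, 192)  # (nz, ny, nx)
    bead_shape: str = "box"  # "box" (separable rect, model-exact) or "sphere"
    min_separation_um: float = 3.0
    margin_um: tuple[float, float, float] = (1.6, 0.7, 0.7)

    def __post_init__(self) -> None:
        if self.sigma_lat_um <= 0 or self.sigma_ax_um <= 0:
            raise GeometryError("PSF sigmas must be positive")
        if self.bead_diameter_um < 0:
            raise GeometryError("bead_diameter_um must be non-negative")
        if self.n_beads < 1:
            raise GeometryError("n_beads must be >= 1")
        if self.bead_shape not in ("box", "sphere"):
            raise GeometryError("bead_shape must be 'box' or 'sphere'")


def _axis_profile(
    coords_um: np.ndarray, centre_um: float, sigma: float, bead_d: float, pitch: float
) -> np.ndarray:
    """Voxel-integrated 1-D bead profile: rect(bead) ⊗ Gaussian, box-averaged.

    Integration over each voxel uses a 9-point midpoint rule.
    """
    offsets = (np.arange(9) - 4.0) / 9.0 * pitch
    x = coords_um[:, None] + offsets[None, :] - centre_um
    if bead_d > 0:
        r = bead_d / 2.0
        from scipy.special import erf

        val = 0.5 * (
            erf((x + r) / (np.sqrt(2.0) * sigma)) - erf((x - r) / (np.sqrt(2.0) * sigma))
        )
    else:
        val = np.exp(-(x**2) / (2.0 * sigma**2))
    prof = val.mean(axis=1)
    peak = float(prof.max())
    return prof / peak if peak > 0 else prof


def _sphere_kernel(truth: BeadSceneGroundTruth, frac: tuple[float, float, float]):
    """Solid-sphere bead blurred by the anisotropic Gaussian, voxel-binned."""
    from scipy.ndimage import gaussian_filter

    dz, dy, dx = truth.voxel_pitch_um
    o = 5  # oversampling per voxel axis
    r = truth.bead_diameter_um / 2.0
    ext = (
        int(np.ceil((4 * truth.sigma_ax_um + r) / dz)) + 1,
        int(np.ceil((4 * truth.sigma_lat_um + r) / dy)) + 1,
        int(np.ceil((4 * truth.sigma_lat_um + r) / dx)) + 1,
    )
    grids = []
    for n, pitch, fr in zip(ext, (dz, dy, dx), frac):
        fine = (np.arange(2 * n * o) - n * o + 0.5) / o * pitch - fr * pitch
        grids.append(fine)
    Z, Y, X = np.meshgrid(*grids, indexing="ij")
    vol = (Z**2 + Y**2 + X**2 <= r**2).astype(float) if r > 0 else None
    if vol is None or not vol.any():
        vol = np.zeros_like(Z)
        vol[tuple(np.unravel_index(np.argmin(Z**2 + Y**2 + X**2), Z.shape))] = 1.0
    sig = (truth.sigma_ax_um / dz * o, truth.sigma_lat_um / dy * o, truth.sigma_lat_um / dx * o)
    blurred = gaussian_filter(vol, sigma=sig, mode="constant")
    nz, ny, nx = (2 * e for e in ext)
    binned = blurred.reshape(nz, o, ny, o, nx, o).mean(axis=(1, 3, 5))
    peak = binned.max()
    return binned / peak if peak > 0 else binned, ext


def _place_beads(truth: BeadSceneGroundTruth, rng: np.random.Generator) -> np.ndarray:
    dz, dy, dx = truth.voxel_pitch_um
    nz, ny, nx = truth.stack_shape
    mz, my, mx = truth.margin_um
    lo = np.array([mz / dz, my / dy, mx / dx])
    hi = np.array([nz - 1 - mz / dz, ny - 1 - my / dy, nx - 1 - mx / dx])
    if np.any(hi <= lo):
        raise GeometryError("stack too small for the requested margins")
    sep = max(truth.min_separation_um, 10.0 * truth.sigma_lat_um)
    pitch = np.array([dz, dy, dx])
    centres: list[np.ndarray] = []
    for _ in range(20000):
        cand = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm((cand - c) * pitch) >= sep for c in centres):
            centres.append(cand)
            if len(centres) == truth.n_beads:
                return np.asarray(centres)
    raise GeometryError(
        f"could not place {truth.n_beads} beads with {sep} um separation"
    )


def generate_bead_stack(
    truth: BeadSceneGroundTruth,
) -> tuple[ImageStack3D, np.ndarray]:
    """Render a bead z-stack; returns the stack and true centroids (z, y, x).

    Peak signal is ``snr**2`` photon counts so that shot noise at the peak
    gives the requested SNR; a small Gaussian read noise and a 5% constant
    background (the luminance offset of the profile model) are added.
    """
    rng = np.random.default_rng(truth.seed)
    centres = _place_beads(truth, rng)
    dz, dy, dx = truth.voxel_pitch_um
    nz, ny, nx = truth.stack_shape
    signal = np.zeros(truth.stack_shape, dtype=float)

    for cz, cy, cx in centres:
        if truth.bead_shape == "box":
            ez = int(np.ceil((4 * truth.sigma_ax_um + truth.bead_diameter_um) / dz)) + 1
            el = int(np.ceil((4 * truth.sigma_lat_um + truth.bead_diameter_um) / dy)) + 1
            z0, z1 = max(0, int(cz) - ez), min(nz, int(cz) + ez + 1)
            y0, y1 = max(0, int(cy) - el), min(ny, int(cy) + el + 1)
            x0, x1 = max(0, int(cx) - el), min(nx, int(cx) + el + 1)
            pz = _axis_profile(np.arange(z0, z1) * dz, cz * dz, truth.sigma_ax_um,
                               truth.bead_diameter_um, dz)
            py = _axis_profile(np.arange(y0, y1) * dy, cy * dy, truth.sigma_lat_um,
                               truth.bead_diameter_um, dy)
            px = _axis_profile(np.arange(x0, x1) * dx, cx * dx, truth.sigma_lat_um,
                               truth.bead_diameter_um, dx)
            signal[z0:z1, y0:y1, x0:x1] += (
                pz[:, None, None] * py[None, :, None] * px[None, None, :]
            )
        else:
            frac = (cz - int(cz), cy - int(cy), cx - int(cx))
            kern, ext = _sphere_kernel(truth, frac)
            z0 = int(cz) - ext[0]
            y0 = int(cy) - ext[1]
            x0 = int(cx) - ext[2]
            zs, ys, xs = kern.shape
            sl_src = []
            sl_dst = []
            for start, size, dim in ((z0, zs, nz), (y0, ys, ny), (x0, xs, nx)):
                d0, d1 = max(0, start), min(dim, start + size)
                sl_dst.append(slice(d0, d1))
                sl_src.append(slice(d0 - start, d1 - start))
            signal[tuple(sl_dst)] += kern[tuple(sl_src)]

    if np.isfinite(truth.snr):
        amplitude = truth.snr**2
        counts = signal * amplitude + 0.05 * amplitude
        noisy = rng.poisson(counts).astype(float)
        noisy += rng.normal(0.0, truth.snr / 10.0, size=noisy.shape)
        voxels = np.clip(noisy, 0.0, None)
    else:
        amplitude = 1000.0
        voxels = signal * amplitude + 0.05 * amplitude
    stack = ImageStack3D(voxels=voxels, voxel_size_um=(dz, dy, dx))
    return stack, centres


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentSpec:
    """Per-treatment sampling distributions for a synthetic cohort."""

    n: int
    tau_mean: float
    tau_sd: float = 0.03
    scale_mean: float = 0.95
    scale_sd: float = 0.02


def generate_cohort(
    treatments: Mapping[str, TreatmentSpec],
    out_dir: str | Path,
    seed: int = 0,
    base_truth: SceneGroundTruth | None = None,
) -> pd.DataFrame:
    """Write a synthetic annotated cohort to ``out_dir``.

    One TIFF pair and one annotation JSON per specimen, consumable by the
    clearing-analysis pipeline unchanged, plus ``ground_truth.csv``.  Per-
    specimen tau/scale are drawn from the treatment's (clipped) normal
    distributions and brain size varies uniformly by up to 20% so medulla
    heights differ across the cohort.  Deterministic for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_truth or SceneGroundTruth(noise_sigma=2.4, landmark_jitter_px=0.5)
    master = np.random.default_rng(seed)
    rows = []
    idx = 0
    for name in sorted(treatments):
        spec = treatments[name]
        for _ in range(spec.n):
            idx += 1
            sid = f"#{idx:03d}"
            tau = float(np.clip(master.normal(spec.tau_mean, spec.tau_sd), 0.02, 1.0))
            scale = float(np.clip(master.normal(spec.scale_mean, spec.scale_sd), 0.2, 1.3))
            size_f = float(master.uniform(0.8, 1.0))
            cx, cy, ax, by = base.brain_ellipse
            truth = replace(
                base,
                tau=tau,
                scale=scale,
                brain_ellipse=(cx, cy, ax * size_f, by * size_f),
                seed=int(master.integers(2**31)),
            )
            scene = generate_grating_scene(truth)
            pre_name = f"{idx:03d}_pre.tif"
            post_name = f"{idx:03d}_post.tif"
            write_image(scene.pre_image, out / pre_name)
            write_image(scene.post_image, out / post_name)
            doc = {
                "specimen_id": sid,
                "treatment": name,
                "pre_image": pre_name,
                "post_image": post_name,
                "pixel_size_um": truth.pixel_size_um,
                "rois": [
                    {
                        "label": lab,
                        "x0": roi.x0,
                        "y0": roi.y0,
                        "width": roi.width,
                        "height": roi.height,
                    }
                    for lab, roi in sorted(scene.rois_post.items())
                ],
                "landmarks": {
                    "brain_length_pre": [list(scene.brain_length_pre.p1),
                                         list(scene.brain_length_pre.p2)],
                    "brain_length_post": [list(scene.brain_length_post.p1),
                                          list(scene.brain_length_post.p2)],
                    "medulla_height_pre": [list(scene.medulla_height_pre.p1),
                                           list(scene.medulla_height_pre.p2)],
                },
            }
            (out / f"{idx:03d}_annotation.json").write_text(json.dumps(doc, indent=1))
            rows.append(
                {
                    "specimen_id": sid,
                    "treatment": name,
                    "tau": tau,
                    "scale": scale,
                    "h_true_um": 2.0 * by * size_f * truth.pixel_size_um,
                    "seed": truth.seed,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "ground_truth.csv", index=False, float_format="%.8g")
    return df
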