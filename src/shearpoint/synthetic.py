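"""Ground-truthed synthetic two-channel fluorescence images.

Emulates confocal fields of an endothelial monolayer in a gradient flow
chamber: channel 1 is a nuclear stain (elliptical nuclei), channel 2 a
transcription-factor stain partitioned between each nucleus and a
surrounding cytoplasmic annulus.  Both the orientation distribution of
the nuclei and the nuclear fraction of the channel-2 signal depend on the
local wall shear stress through a parameterized biphasic response model,
so that every downstream stage (segmentation, morphometry, response
curves, set-point estimation) can be validated against known truth.

Orientation model
-----------------
Per-cell signed nucleus orientation (degrees from the flow axis, in
(-90, 90]) is drawn from a wrapped normal distribution on the 180-degree
axial circle.  The dispersion is chosen, by numerical inversion of the
folded-mean function, so that the mean *folded* angle (acute angle to the
flow, in [0, 90]) equals the model's target at the local shear: the
aligned mean inside the optimal range, relaxing to the misaligned mean
(default 45 degrees, the uniform expectation) far outside it.  An
``angle_concentration`` of 0 yields exactly uniform orientations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .chamber import ChamberConfig, position_to_shear

__all__ = [
    "ResponseModel",
    "Scene",
    "NoiseModel",
    "SyntheticImage",
    "sample_scene",
    "sample_scene_at_shear",
    "render",
    "scene_label_masks",
    "suggested_image_shape",
    "HUVEC_MODEL",
    "HDLEC_MODEL",
]


# --------------------------------------------------------------------------
# response model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseModel:
    """Biphasic shear response generating the synthetic ground truth.

    ``optimum_shear_dyn_cm2`` centres the optimal range and
    ``optimum_halfwidth_dyn_cm2`` sets its half-width: within one
    half-width of the optimum the response is fully "aligned"; outside,
    it decays with a Gaussian shoulder of the same width toward the
    far-from-optimum level.
    """

    optimum_shear_dyn_cm2: float = 15.0
    optimum_halfwidth_dyn_cm2: float = 5.0
    aligned_mean_angle_deg: float = 20.0
    misaligned_mean_angle_deg: float = 45.0
    misaligned_mean_angle_high_deg: float | None = None  # >45 models perpendicular
    tf_nuclear_fraction_at_optimum: float = 0.7
    tf_nuclear_fraction_baseline: float = 0.3
    angle_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.optimum_halfwidth_dyn_cm2 <= 0:
            raise ValueError("optimum_halfwidth_dyn_cm2 must be > 0")
        for name in ("tf_nuclear_fraction_at_optimum", "tf_nuclear_fraction_baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("aligned_mean_angle_deg", "misaligned_mean_angle_deg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name} must lie in [0, 90], got {v}")
        if self.angle_concentration < 0:
            raise ValueError("angle_concentration must be >= 0")

    def optimum_weight(self, shear_dyn_cm2):
        """1 at/within the optimal range, → 0 far outside (Gaussian shoulder)."""
        tau = np.asarray(shear_dyn_cm2, dtype=float)
        d = np.maximum(0.0, np.abs(tau - self.optimum_shear_dyn_cm2) - self.optimum_halfwidth_dyn_cm2)
        return np.exp(-0.5 * (d / self.optimum_halfwidth_dyn_cm2) ** 2)

    def mean_folded_angle(self, shear_dyn_cm2):
        """Target mean acute angle (deg) between nucleus axis and flow."""
        tau = np.asarray(shear_dyn_cm2, dtype=float)
        w = self.optimum_weight(tau)
        far = np.full_like(tau, self.misaligned_mean_angle_deg, dtype=float)
        if self.misaligned_mean_angle_high_deg is not None:
            far = np.where(tau > self.optimum_shear_dyn_cm2, self.misaligned_mean_angle_high_deg, far)
        out = far + (self.aligned_mean_angle_deg - far) * w
        return float(out) if out.ndim == 0 else out

    def nuclear_fraction(self, shear_dyn_cm2):
        """True transcription-factor nuclear fraction at the given shear."""
        w = self.optimum_weight(shear_dyn_cm2)
        b, o = self.tf_nuclear_fraction_baseline, self.tf_nuclear_fraction_at_optimum
        out = b + (o - b) * np.asarray(w)
        return float(out) if out.ndim == 0 else out


#: venous-endothelium-like defaults: optimal alignment around 15 dyn/cm^2
HUVEC_MODEL = ResponseModel(optimum_shear_dyn_cm2=15.0, optimum_halfwidth_dyn_cm2=5.0)
#: lymphatic-endothelium-like defaults: optimum near 5 dyn/cm^2
HDLEC_MODEL = ResponseModel(optimum_shear_dyn_cm2=5.0, optimum_halfwidth_dyn_cm2=2.0)


# --------------------------------------------------------------------------
# folded wrapped-normal mean and its inverse
# --------------------------------------------------------------------------

_SIGMA_TABLE: np.ndarray | None = None
_MEAN_TABLE: np.ndarray | None = None


def folded_wrapped_normal_mean(sigma_deg: float) -> float:
    """E|X| for X ~ wrapped normal(0, sigma) on the axial circle (-90, 90]."""
    if sigma_deg <= 0:
        return 0.0
    if sigma_deg >= 150.0:
        # wrapped normal is uniform to < 1e-6 once sigma covers the period
        return 45.0
    t = np.linspace(0.0, 90.0, 1801)
    kmax = max(2, int(np.ceil(3 * sigma_deg / 180.0)) + 1)
    p = np.zeros_like(t)
    for k in range(-kmax, kmax + 1):
        p += norm.pdf(t + 180.0 * k, loc=0.0, scale=sigma_deg)
    # density is symmetric about 0; total mass on [0, 90] is 1/2
    return float(np.trapezoid(2.0 * t * p, t))


def _tables() -> tuple[np.ndarray, np.ndarray]:
    global _SIGMA_TABLE, _MEAN_TABLE
    if _SIGMA_TABLE is None:
        sig = np.concatenate([np.linspace(0.05, 60.0, 240), np.geomspace(61.0, 400.0, 60)])
        _MEAN_TABLE = np.array([folded_wrapped_normal_mean(s) for s in sig])
        _SIGMA_TABLE = sig
    return _SIGMA_TABLE, _MEAN_TABLE


def sigma_for_folded_mean(target_deg: float) -> float:
    """Wrapped-normal sigma whose folded mean equals ``target_deg`` (< 45).

    Returns ``inf`` for targets at (or numerically at) the uniform
    expectation of 45 degrees.
    """
    if not 0.0 <= target_deg <= 45.0:
        raise ValueError(f"folded-mean target must lie in [0, 45], got {target_deg}")
    if target_deg >= 44.99:
        return float("inf")
    sig, mean = _tables()
    if target_deg <= mean[0]:
        return float(sig[0])
    return float(np.interp(target_deg, mean, sig))


def _draw_signed_angles(rng: np.random.Generator, n: int, target_mean: float, concentration: float) -> np.ndarray:
    """Signed orientations in (-90, 90] whose folded mean is ``target_mean``."""
    if concentration <= 0:
        return rng.uniform(-90.0, 90.0, size=n)
    center = 0.0 if target_mean <= 45.0 else 90.0
    fold_target = target_mean if target_mean <= 45.0 else 90.0 - target_mean
    sigma = sigma_for_folded_mean(fold_target) / concentration
    if not np.isfinite(sigma) or sigma > 2000.0:
        return rng.uniform(-90.0, 90.0, size=n)
    theta = rng.normal(center, sigma, size=n)
    return (theta + 90.0) % 180.0 - 90.0


# --------------------------------------------------------------------------
# scene sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Scene:
    """A synthetic field of cells with full per-cell ground truth.

    ``cells`` columns: ``x_px, y_px`` (centroid), ``a_um, b_um`` (nucleus
    semi-axes), ``angle_deg`` (signed orientation from the flow axis,
    which is the image x-axis), ``true_tf`` (nuclear fraction in [0,1])
    and ``shear_dyn_cm2``.
    """

    shape_px: tuple[int, int]
    pixel_size_um: float
    x_position_cm: float
    shear_dyn_cm2: float
    cells: pd.DataFrame
    seed: int
    annulus_um: float = 6.0
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def folded_angles(self) -> np.ndarray:
        """Ground-truth acute angles to the flow axis, degrees in [0, 90]."""
        return np.abs(self.cells["angle_deg"].to_numpy())


def _grid_capacity(shape_px, pixel_size_um, pitch_um, margin_um):
    h_um = shape_px[0] * pixel_size_um
    w_um = shape_px[1] * pixel_size_um
    ny = int((h_um - 2 * margin_um) // pitch_um) + 1
    nx = int((w_um - 2 * margin_um) // pitch_um) + 1
    return max(0, ny), max(0, nx)


def suggested_image_shape(
    n_cells: int,
    pixel_size_um: float = 0.65,
    min_spacing_um: float = 25.0,
    jitter_um: float = 2.0,
    margin_um: float = 20.0,
) -> tuple[int, int]:
    """Smallest square image that can hold ``n_cells`` non-overlapping nuclei."""
    pitch = min_spacing_um + 2 * jitter_um
    side = int(np.ceil(np.sqrt(n_cells)))
    size_um = 2 * margin_um + side * pitch
    size_px = int(np.ceil(size_um / pixel_size_um))
    return (size_px, size_px)


def sample_scene_at_shear(
    model: ResponseModel,
    shear_dyn_cm2: float,
    n_cells: int,
    seed: int,
    *,
    x_position_cm: float = 0.0,
    image_shape_px: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 0.65,
    min_spacing_um: float = 25.0,
    jitter_um: float = 2.0,
    margin_um: float = 20.0,
    nucleus_semiaxes_um: tuple[float, float] = (8.0, 5.0),
    semiaxis_sd_um: tuple[float, float] = (0.5, 0.4),
    annulus_um: float = 6.0,
) -> Scene:
    """Sample a field of cells experiencing a single wall shear stress.

    Nuclei are placed on a jittered square grid so that the minimum
    centroid spacing is enforced by construction; an image too small for
    ``n_cells`` raises rather than silently truncating.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if shear_dyn_cm2 < 0:
        raise ValueError("shear must be >= 0")
    rng = np.random.default_rng(seed)
    pitch = min_spacing_um + 2 * jitter_um
    ny, nx = _grid_capacity(image_shape_px, pixel_size_um, pitch, margin_um)
    capacity = ny * nx
    if n_cells > capacity:
        raise ValueError(
            f"cannot place {n_cells} nuclei with {min_spacing_um} um spacing in a "
            f"{image_shape_px} image ({capacity} sites available); enlarge the image "
            f"(suggested_image_shape({n_cells}) -> {suggested_image_shape(n_cells, pixel_size_um, min_spacing_um, jitter_um, margin_um)})"
        )

    sites = rng.choice(capacity, size=n_cells, replace=False)
    gy, gx = np.divmod(sites, nx)
    cy_um = margin_um + gy * pitch + pitch / 2 + rng.uniform(-jitter_um, jitter_um, n_cells)
    cx_um = margin_um + gx * pitch + pitch / 2 + rng.uniform(-jitter_um, jitter_um, n_cells)

    a = np.clip(rng.normal(nucleus_semiaxes_um[0], semiaxis_sd_um[0], n_cells), 6.0, 10.0)
    b = np.clip(rng.normal(nucleus_semiaxes_um[1], semiaxis_sd_um[1], n_cells), 3.5, 6.5)
    b = np.minimum(b, a - 1.0)  # keep a clear major axis

    target = float(model.mean_folded_angle(shear_dyn_cm2))
    angles = _draw_signed_angles(rng, n_cells, target, model.angle_concentration)
    tf = float(model.nuclear_fraction(shear_dyn_cm2))

    cells = pd.DataFrame(
        {
            "x_px": cx_um / pixel_size_um,
            "y_px": cy_um / pixel_size_um,
            "a_um": a,
            "b_um": b,
            "angle_deg": angles,
            "true_tf": np.full(n_cells, tf),
            "shear_dyn_cm2": np.full(n_cells, float(shear_dyn_cm2)),
        }
    )
    return Scene(
        shape_px=tuple(image_shape_px),
        pixel_size_um=pixel_size_um,
        x_position_cm=x_position_cm,
        shear_dyn_cm2=float(shear_dyn_cm2),
        cells=cells,
        seed=seed,
        annulus_um=annulus_um,
        meta={"target_mean_folded_angle_deg": target},
    )


def sample_scene(
    config: ChamberConfig,
    model: ResponseModel,
    x_position_cm: float,
    n_cells: int,
    seed: int,
    **geometry,
) -> Scene:
    """Sample a field at axial position ``x`` of a gradient chamber."""
    tau = position_to_shear(config, x_position_cm)
    return sample_scene_at_shear(
        model, tau, n_cells, seed, x_position_cm=x_position_cm, **geometry
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Optics and camera model for rendering.

    Defaults keep the full dynamic range well below uint16 saturation.
    """

    psf_sigma_um: float = 0.8
    background: float = 100.0
    noise_sd: float = 5.0
    nucleus_amplitude: float = 2000.0
    cell_total_intensity: float = 60000.0
    dtype: str = "uint16"

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(psf_sigma_um=0.0, background=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class SyntheticImage:
    """Rendered two-channel image: ``data[0]`` nuclei, ``data[1]`` TF stain."""

    data: np.ndarray  # (2, H, W) integer
    pixel_size_um: float
    x_position_cm: float
    shear_dyn_cm2: float
    meta: dict = field(default_factory=dict)

    @property
    def nuclei(self) -> np.ndarray:
        return self.data[0]

    @property
    def tf_stain(self) -> np.ndarray:
        return self.data[1]


def _ellipse_mask_patch(shape, cx, cy, a_px, b_px, angle_deg):
    """Boolean patch + origin offset for one rotated ellipse."""
    r = int(np.ceil(max(a_px, b_px))) + 2
    x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
    y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x1, shape[1]), min(y1, shape[0])
    if x0c >= x1c or y0c >= y1c:
        return None, 0, 0
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    dx = xx - cx
    dy = yy - cy
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    u = (dx * c + dy * s) / a_px
    v = (-dx * s + dy * c) / b_px
    return (u * u + v * v) <= 1.0, y0c, x0c


def render(scene: Scene, noise: NoiseModel | None = None) -> SyntheticImage:
    """Render a scene to a two-channel integer image.

    Channel 1 holds uniformly filled nucleus ellipses; channel 2 splits a
    fixed per-cell total intensity between the nucleus and a cytoplasmic
    annulus (an ellipse grown by ``scene.annulus_um`` minus the nucleus)
    in proportion ``true_tf : (1 - true_tf)``.  A Gaussian PSF blur and
    additive Gaussian background noise follow; blur conserves the
    integrated per-cell signal away from the image border.
    """
    noise = noise or NoiseModel()
    h, w = scene.shape_px
    ch1 = np.zeros((h, w), dtype=float)
    ch2 = np.zeros((h, w), dtype=float)
    px = scene.pixel_size_um

    for row in scene.cells.itertuples(index=False):
        a_px, b_px = row.a_um / px, row.b_um / px
        nuc, y0, x0 = _ellipse_mask_patch((h, w), row.x_px, row.y_px, a_px, b_px, row.angle_deg)
        if nuc is None or not nuc.any():
            continue
        grow = scene.annulus_um / px
        outer, oy0, ox0 = _ellipse_mask_patch(
            (h, w), row.x_px, row.y_px, a_px + grow, b_px + grow, row.angle_deg
        )
        ch1[y0 : y0 + nuc.shape[0], x0 : x0 + nuc.shape[1]][nuc] += noise.nucleus_amplitude
        nuc_n = int(nuc.sum())
        ch2[y0 : y0 + nuc.shape[0], x0 : x0 + nuc.shape[1]][nuc] += (
            row.true_tf * noise.cell_total_intensity / nuc_n
        )
        if outer is not None and row.true_tf < 1.0:
            ann = outer.copy()
            # carve the nucleus out of the outer ellipse (align the patches)
            sy, sx = y0 - oy0, x0 - ox0
            ann[sy : sy + nuc.shape[0], sx : sx + nuc.shape[1]] &= ~nuc
            ann_n = int(ann.sum())
            if ann_n:
                ch2[oy0 : oy0 + ann.shape[0], ox0 : ox0 + ann.shape[1]][ann] += (
                    (1.0 - row.true_tf) * noise.cell_total_intensity / ann_n
                )

    sigma_px = noise.psf_sigma_um / px
    if sigma_px > 0:
        ch1 = gaussian_filter(ch1, sigma_px)
        ch2 = gaussian_filter(ch2, sigma_px)
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0x9E3779B9]))
    out = np.stack([ch1, ch2]) + noise.background
    if noise.noise_sd > 0:
        out = out + rng.normal(0.0, noise.noise_sd, size=out.shape)

    info = np.iinfo(np.dtype(noise.dtype))
    saturated = int(np.count_nonzero(out > info.max))
    if saturated:
        warnings.warn(
            f"render: {saturated} pixels saturated at {info.max}; lower the gain",
            RuntimeWarning,
            stacklevel=2,
        )
    data = np.clip(np.rint(out), 0, info.max).astype(noise.dtype)
    meta = {
        "saturated_px": saturated,
        "noise": noise,
        "seed": scene.seed,
        "n_cells": scene.n_cells,
    }
    return SyntheticImage(
        data=data,
        pixel_size_um=px,
        x_position_cm=scene.x_position_cm,
        shear_dyn_cm2=scene.shear_dyn_cm2,
        meta=meta,
    )


def scene_label_masks(scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the ground-truth nucleus and cytoplasm-annulus labels.

    Returns ``(nucleus_labels, annulus_labels)`` in the scene's own label
    order (row order of ``scene.cells``, 1-based); the annulus is the
    nucleus ellipse grown by ``scene.annulus_um`` minus the nucleus.
    """
    h, w = scene.shape_px
    nuc = np.zeros((h, w), dtype=np.int32)
    ann = np.zeros((h, w), dtype=np.int32)
    px = scene.pixel_size_um
    grow = scene.annulus_um / px
    for lab, row in enumerate(scene.cells.itertuples(index=False), start=1):
        a, b = row.a_um / px, row.b_um / px
        m, y0, x0 = _ellipse_mask_patch((h, w), row.x_px, row.y_px, a, b, row.angle_deg)
        o, oy0, ox0 = _ellipse_mask_patch(
            (h, w), row.x_px, row.y_px, a + grow, b + grow, row.angle_deg
        )
        if o is not None:
            ann[oy0 : oy0 + o.shape[0], ox0 : ox0 + o.shape[1]][o] = lab
        if m is not None:
            nuc[y0 : y0 + m.shape[0], x0 : x0 + m.shape[1]][m] = lab
    ann[nuc > 0] = 0
    return nuc, ann


def write_scene(image: SyntheticImage, scene: Scene, tiff_path, sidecar_path=None) -> None:
    """Write the rendered TIFF plus a CSV ground-truth sidecar."""
    import tifffile

    tifffile.imwrite(
        tiff_path,
        image.data,
        metadata={
            "axes": "CYX",
            "pixel_size_um": image.pixel_size_um,
            "x_position_cm": image.x_position_cm,
            "shear_dyn_cm2": image.shear_dyn_cm2,
        },
    )
    if sidecar_path is not None:
        scene.cells.assign(x_position_cm=scene.x_position_cm).to_csv(sidecar_path, index=False)
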