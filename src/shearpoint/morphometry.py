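"""Per-cell shape and intensity statistics.

Orientation is the acute angle between the major axis of the
second-moment ellipse of the nucleus mask and the flow direction (the
image x-axis), folded into [0, 90]: 0 means aligned with flow, 45 is the
expectation for random orientations, 90 is perpendicular.

The translocation factor TF of a transcription factor is the integrated
background-subtracted stain intensity inside the nucleus divided by that
of the whole cell; TF = 1 when the signal is entirely nuclear and 0 when
entirely cytoplasmic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .chamber import ChamberConfig, position_to_shear
from .segmentation import LabeledMasks

__all__ = [
    "orientation",
    "orientation_from_moments",
    "translocation_factor",
    "estimate_background",
    "measure_cells",
    "LineProfile",
    "profile_auc",
]

_DEGENERACY_RTOL = 1e-3


def orientation_from_moments(mu20: float, mu02: float, mu11: float) -> float:
    """Folded major-axis angle (deg, [0, 90]) from second central moments.

    Returns NaN when the moment ellipse is circular-degenerate (equal
    eigenvalues), where orientation is undefined.
    """
    scale = mu20 + mu02
    if scale <= 0:
        return float("nan")
    if abs(mu20 - mu02) < _DEGENERACY_RTOL * scale and abs(mu11) < _DEGENERACY_RTOL * scale:
        return float("nan")
    theta = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return float(abs(np.degrees(theta)))


def orientation(mask: np.ndarray, flow_axis: str = "x") -> float:
    """Acute angle between the mask's moment-ellipse major axis and flow.

    ``mask`` is a boolean (or label>0) region image; regions with fewer
    than 5 pixels or a degenerate moment ellipse return NaN, to be
    excluded from averages downstream.
    """
    ys, xs = np.nonzero(np.asarray(mask))
    if ys.size < 5:
        return float("nan")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = float(np.mean(x * x))
    mu02 = float(np.mean(y * y))
    mu11 = float(np.mean(x * y))
    if flow_axis == "y":
        mu20, mu02 = mu02, mu20
    elif flow_axis != "x":
        raise ValueError("flow_axis must be 'x' or 'y'")
    return orientation_from_moments(mu20, mu02, mu11)


def estimate_background(image: np.ndarray, cell_labels: np.ndarray) -> float:
    """Most frequent intensity outside every cell region (integer mode).

    Falls back to the median for float images or when everything is
    foreground.
    """
    outside = np.asarray(image)[np.asarray(cell_labels) == 0]
    if outside.size == 0:
        return 0.0
    if np.issubdtype(outside.dtype, np.integer):
        counts = np.bincount(outside.ravel())
        return float(np.argmax(counts))
    return float(np.median(outside))


def translocation_factor(
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    channel2: np.ndarray,
    background: float = 0.0,
) -> float:
    """TF = sum(I - bg over nucleus) / sum(I - bg over whole cell).

    Both sums clip negative (sub-background) pixels at zero.  Returns NaN
    (flagged, excluded downstream) when the whole-cell sum is not
    positive.
    """
    nuc = np.asarray(nucleus_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if np.any(nuc & ~cell):
        raise ValueError("nucleus mask must be contained in the cell mask")
    img = np.asarray(channel2, dtype=float) - background
    np.clip(img, 0.0, None, out=img)
    denom = float(img[cell].sum())
    if denom <= 0:
        return float("nan")
    return float(img[nuc].sum()) / denom


def measure_cells(
    channel2: np.ndarray,
    masks: LabeledMasks,
    x_position_cm: float | None = None,
    config: ChamberConfig | None = None,
    background: float | str | None = "auto",
    image_id: str | int = 0,
    flow_axis: str = "x",
) -> pd.DataFrame:
    """Per-cell orientation and translocation factor for one image.

    Returns a tidy frame (one row per label) with columns ``image``,
    ``label``, ``orientation_deg``, ``tf``, ``nucleus_area_um2``,
    ``cell_area_um2``, ``x_cm``, ``shear_dyn_cm2`` and ``flag`` (empty
    string, ``"degenerate_orientation"`` and/or ``"undefined_tf"``).

    ``background="auto"`` estimates the camera offset as the modal
    intensity outside all cell regions; pass 0 or ``None`` for literal
    un-subtracted ratios.
    """
    masks.validate()
    if masks.cells is None:
        raise ValueError("masks must include whole-cell regions (derive_cell_regions)")
    if background == "auto":
        bg = estimate_background(channel2, masks.cells)
    else:
        bg = float(background or 0.0)
    n = masks.n_labels
    px_area = masks.pixel_size_um**2
    shear = np.nan
    if config is not None and x_position_cm is not None:
        shear = position_to_shear(config, x_position_cm)

    nuc_slices = ndi.find_objects(masks.nuclei)
    cell_slices = ndi.find_objects(masks.cells)
    rows = []
    for lab in range(1, n + 1):
        nsl = nuc_slices[lab - 1]
        csl = cell_slices[lab - 1]
        nuc = masks.nuclei[nsl] == lab
        cell_local = masks.cells[csl] == lab
        theta = orientation(nuc, flow_axis=flow_axis)
        nuc_in_cell = (masks.nuclei[csl] == lab) & cell_local
        img = np.asarray(channel2, dtype=float)[csl] - bg
        np.clip(img, 0.0, None, out=img)
        denom = float(img[cell_local].sum())
        tf = float(img[nuc_in_cell].sum()) / denom if denom > 0 else float("nan")
        flags = []
        if np.isnan(theta):
            flags.append("degenerate_orientation")
        if np.isnan(tf):
            flags.append("undefined_tf")
        rows.append(
            {
                "image": image_id,
                "label": lab,
                "orientation_deg": theta,
                "tf": tf,
                "nucleus_area_um2": float(nuc.sum()) * px_area,
                "cell_area_um2": float(cell_local.sum()) * px_area,
                "x_cm": np.nan if x_position_cm is None else float(x_position_cm),
                "shear_dyn_cm2": float(shear),
                "flag": "+".join(flags),
            }
        )
    columns = [
        "image",
        "label",
        "orientation_deg",
        "tf",
        "nucleus_area_um2",
        "cell_area_um2",
        "x_cm",
        "shear_dyn_cm2",
        "flag",
    ]
    return pd.DataFrame(rows, columns=columns)


# --------------------------------------------------------------------------
# line profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LineProfile:
    """Fluorescence intensity sampled along a line (distances in um)."""

    distance_um: np.ndarray
    intensity: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_um, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if d.size != i.size:
            raise ValueError("distance and intensity must have equal length")
        if d.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        object.__setattr__(self, "distance_um", d)
        object.__setattr__(self, "intensity", i)

    @classmethod
    def from_csv(cls, path, background: float = 0.0) -> "LineProfile":
        """Read a 2-column CSV of (distance_um, intensity)."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("profile CSV needs two columns: distance, intensity")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), background)


def profile_auc(profile: LineProfile, per_um: bool = False) -> float:
    """Trapezoidal area under the background-subtracted profile.

    Negative excursions after background subtraction are clipped at zero.
    With ``per_um=True`` the area is divided by the profile span, giving a
    mean intensity rather than a total.
    """
    y = np.clip(profile.intensity - profile.background, 0.0, None)
    area = float(np.trapezoid(y, profile.distance_um))
    if per_um:
        span = profile.distance_um[-1] - profile.distance_um[0]
        return area / span
    return area
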