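"""End-to-end composition: images + positions → measurements → set point.

The pipeline mirrors the experimental workflow: fields of view are taken
at known axial positions of the gradient chamber, each is segmented and
measured per cell, the chamber model converts position to wall shear
stress, and the pooled measurements are binned, smoothed and reduced to
a set-point estimate.  Every parameter travels in a single
:class:`RunConfig` that is echoed into the outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import ChamberConfig, HUVEC_CHAMBER, chamber_from_dict, chamber_to_dict
from .morphometry import measure_cells
from .response import ResponseCurve, SetPointEstimate, bin_by_shear, estimate_set_point, lowess
from .segmentation import SegmentationParams, derive_cell_regions, segment_nuclei
from .synthetic import NoiseModel, ResponseModel, SyntheticImage, render, sample_scene, suggested_image_shape

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "simulate_dataset"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Complete parameterization of one pipeline run."""

    chamber: ChamberConfig = HUVEC_CHAMBER
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cell_strategy: str = "dilate"
    cell_radius_um: float = 6.0
    background: str | float | None = "auto"
    value: str = "orientation_deg"
    kind: str = "orientation"
    n_bins: int = 15
    lowess_frac: float = 0.5
    # estimation smoothing is non-robust: each bin is an average of many
    # cells, so bisquare reweighting would reject structurally informative
    # edge bins rather than outliers (use iterations=3 for display curves)
    lowess_iterations: int = 0
    criterion_fraction: float = 0.8
    per_image: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chamber"] = chamber_to_dict(self.chamber)
        d["segmentation"] = self.segmentation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        if "chamber" in d:
            d["chamber"] = chamber_from_dict(d["chamber"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    curve: ResponseCurve
    set_point: SetPointEstimate
    config: RunConfig
    per_image_counts: dict


def _load_image(item) -> tuple[np.ndarray, float]:
    """Accept a SyntheticImage or a TIFF path; return ((2,H,W) data, px size)."""
    if isinstance(item, SyntheticImage):
        return item.data, item.pixel_size_um
    import tifffile

    with tifffile.TiffFile(item) as tf:
        data = tf.asarray()
        px = 0.65
        meta = tf.shaped_metadata or tf.imagej_metadata
        if meta:
            m = meta[0] if isinstance(meta, (list, tuple)) else meta
            px = float(m.get("pixel_size_um", px))
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) two-channel TIFF, got shape {data.shape}")
    return data, px


def run_pipeline(
    images,
    positions_cm,
    config: RunConfig | None = None,
    outdir=None,
) -> PipelineResult:
    """Segment, measure and aggregate a set of fields of view.

    ``images`` is a sequence of TIFF paths or in-memory
    :class:`~shearpoint.synthetic.SyntheticImage` objects, matched
    one-to-one with axial ``positions_cm``.  Images where no cell is
    detected are excluded (logged) rather than aborting the run.  When
    ``outdir`` is given, the measurement table, the binned curve, the
    set-point report, the echoed config and a run report with sha256
    checksums are written there.
    """
    config = config or RunConfig()
    if len(images) != len(positions_cm):
        raise ValueError("images and positions must match one-to-one")
    frames = []
    counts = {}
    for i, (item, x) in enumerate(zip(images, positions_cm)):
        name = getattr(item, "name", None) or (str(item) if not isinstance(item, SyntheticImage) else f"image_{i}")
        try:
            data, px = _load_image(item)
            masks = segment_nuclei(data[0], px, config.segmentation)
            if masks.n_labels == 0:
                log.warning("run_pipeline: no cells detected in %s; skipping", name)
                counts[name] = 0
                continue
            masks = derive_cell_regions(
                masks, data[1], strategy=config.cell_strategy, radius_um=config.cell_radius_um
            )
            df = measure_cells(
                data[1],
                masks,
                x_position_cm=x,
                config=config.chamber,
                background=config.background,
                image_id=name,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline failed at image {name!r}: {exc}") from exc
        counts[name] = len(df)
        frames.append(df)
    if not frames:
        raise RuntimeError("pipeline: no image yielded any cells")
    measurements = pd.concat(frames, ignore_index=True)
    curve = bin_by_shear(
        measurements,
        config=config.chamber,
        n_bins=config.n_bins,
        value=config.value,
        kind=config.kind,
        per_image=config.per_image,
    )
    curve = lowess(curve, frac=config.lowess_frac, iterations=config.lowess_iterations)
    sp = estimate_set_point(curve, kind=config.kind, criterion_fraction=config.criterion_fraction)
    result = PipelineResult(measurements, curve, sp, config, counts)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mpath = outdir / "measurements.csv"
    cpath = outdir / "curve.csv"
    spath = outdir / "set_point.json"
    ypath = outdir / "run_config.yaml"
    result.measurements.to_csv(mpath, index=False)
    result.curve.to_frame().to_csv(cpath, index=False)
    spath.write_text(json.dumps(result.set_point.to_dict(), indent=2))
    result.config.to_yaml(ypath)
    report = {
        "cells_per_image": result.per_image_counts,
        "n_cells_total": int(len(result.measurements)),
        "n_bins": int(len(result.curve)),
        "checksums": {p.name: _sha256(p) for p in (mpath, cpath, spath, ypath)},
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))


def simulate_dataset(
    chamber: ChamberConfig,
    model: ResponseModel,
    n_positions: int = 16,
    n_cells: int = 100,
    seed: int = 0,
    noise: NoiseModel | None = None,
    margin_frac: float = 0.02,
    **geometry,
):
    """Render fields of view at evenly spaced chamber positions.

    Returns ``(images, positions_cm, scenes)``; per-image seeds are
    derived deterministically from the top-level seed.  Positions avoid
    the exact channel ends by ``margin_frac`` of the length.
    """
    length = chamber.channel_length_cm
    positions = np.linspace(margin_frac * length, (1 - margin_frac) * length, n_positions)
    geometry.setdefault("image_shape_px", suggested_image_shape(n_cells))
    images, scenes = [], []
    for i, x in enumerate(positions):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        scene = sample_scene(chamber, model, x, n_cells, sub, **geometry)
        images.append(render(scene, noise))
        scenes.append(scene)
    return images, positions, scenes
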