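"""Shear-binned response curves, smoothing and set-point estimation.

A "set point" is the wall shear stress magnitude at which an endothelial
stabilization response is extremal — where nuclei align best with flow
(minimum angle), inflammatory NF-kB nuclear translocation bottoms out
(minimum TF), or Smad nuclear translocation peaks (maximum TF).  The
optimal *range* around the optimum is the contiguous set of shear bins
whose smoothed response has covered at least a criterion fraction
(default 0.8) of the distance from baseline to optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .chamber import ChamberConfig, position_to_shear

__all__ = [
    "ResponseCurve",
    "SetPointEstimate",
    "bin_by_shear",
    "lowess",
    "lowess_fit",
    "estimate_set_point",
    "anova_shear_effect",
]

log = logging.getLogger(__name__)

#: extremum direction of each supported readout
READOUT_DIRECTION = {
    "orientation": "min",  # best alignment = smallest angle
    "nfkb": "min",  # laminar optimum suppresses NF-kB translocation
    "smad": "max",  # Smad translocation peaks at the optimum
}


@dataclass(frozen=True)
class ResponseCurve:
    """Shear-binned mean response with dispersion and optional smooth."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    kind: str = "orientation"
    smoothed: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.bin_centers, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        for name in ("mean", "sem", "n"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != c.shape:
                raise ValueError(f"{name} must match bin_centers in shape")
        if np.any(np.asarray(self.sem) < 0):
            raise ValueError("SEM must be non-negative")
        if np.any(np.asarray(self.n) < 1):
            raise ValueError("each retained bin needs n >= 1")

    def __len__(self) -> int:
        return len(self.bin_centers)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "shear_dyn_cm2": self.bin_centers,
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
            }
        )
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df


@dataclass(frozen=True)
class SetPointEstimate:
    """Estimated optimal shear and optimal range for one readout."""

    optimum_shear_dyn_cm2: float
    range_lo_dyn_cm2: float
    range_hi_dyn_cm2: float
    criterion_fraction: float
    baseline: float
    optimum_value: float
    kind: str
    at_boundary: bool

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "optimum_shear_dyn_cm2": self.optimum_shear_dyn_cm2,
            "range_lo_dyn_cm2": self.range_lo_dyn_cm2,
            "range_hi_dyn_cm2": self.range_hi_dyn_cm2,
            "criterion_fraction": self.criterion_fraction,
            "baseline": self.baseline,
            "optimum_value": self.optimum_value,
            "at_boundary": self.at_boundary,
        }


def bin_by_shear(
    measurements: pd.DataFrame,
    config: ChamberConfig | None = None,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 15,
    value: str = "orientation_deg",
    kind: str | None = None,
    per_image: bool = True,
) -> ResponseCurve:
    """Aggregate per-cell measurements into a shear-binned response curve.

    Shear is taken from the ``shear_dyn_cm2`` column or, failing that,
    computed from ``x_cm`` through the chamber model.  By default each
    image is averaged first and bins then summarise images (mean and SEM
    over image means, matching how fields of view are treated as the
    statistical unit); ``per_image=False`` pools cells.  Empty bins are
    dropped with a log notice; NaN-flagged cells are excluded.
    """
    df = measurements.copy()
    if "shear_dyn_cm2" not in df or df["shear_dyn_cm2"].isna().all():
        if config is None:
            raise ValueError("no shear column and no chamber config to derive it")
        df["shear_dyn_cm2"] = position_to_shear(config, df["x_cm"].to_numpy())
    df = df.dropna(subset=[value, "shear_dyn_cm2"])
    if df.empty:
        raise ValueError("no finite measurements to bin")
    if bin_edges is None:
        lo, hi = df["shear_dyn_cm2"].min(), df["shear_dyn_cm2"].max()
        if config is not None:
            lo, hi = config.shear_range()
        if hi <= lo:
            hi = lo + 1.0
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.digitize(df["shear_dyn_cm2"], bin_edges) - 1, 0, len(bin_edges) - 2)
    df = df.assign(_bin=idx)

    if per_image and "image" in df:
        unit = df.groupby(["_bin", "image"], sort=True)[value].mean().reset_index()
    else:
        unit = df.rename(columns={value: value})[["_bin", value]].copy()
        unit["image"] = np.arange(len(unit))
    g = unit.groupby("_bin", sort=True)[value]
    agg = g.agg(["mean", "sem", "count"])
    agg["sem"] = agg["sem"].fillna(0.0)

    all_bins = np.arange(len(bin_edges) - 1)
    empty = np.setdiff1d(all_bins, agg.index.to_numpy())
    if empty.size:
        log.info("bin_by_shear: dropping %d empty bins: %s", empty.size, empty.tolist())
    if agg.empty:
        raise ValueError("all shear bins are empty")
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])[agg.index.to_numpy()]
    return ResponseCurve(
        bin_centers=centers,
        mean=agg["mean"].to_numpy(),
        sem=agg["sem"].to_numpy(),
        n=agg["count"].to_numpy(),
        kind=kind or ("orientation" if value == "orientation_deg" else "tf"),
        meta={"per_image": per_image, "value": value, "bin_edges": bin_edges.tolist()},
    )


def lowess_fit(x, y, frac: float = 0.5, iterations: int = 3) -> np.ndarray:
    """LOWESS: locally weighted linear regression with robustness reweights.

    At each ``x[i]`` a line is fit by weighted least squares with
    tri-cube weights over the nearest ``ceil(frac * n)`` neighbours;
    ``iterations`` bisquare reweighting passes (Cleveland's robustness
    step) then downweight outlying residuals, including at the outlier's
    own abscissa.  Exactly linear data are reproduced to machine
    precision because a local linear fit is exact on a line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    k = min(n, max(2, int(np.ceil(frac * n))))
    delta = np.ones(n)
    out = y.copy()
    span = max(float(np.ptp(y)), 1.0)
    for iteration in range(iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            r = np.partition(d, k - 1)[k - 1]
            if r <= 0:
                r = max(float(d.max()), 1e-12)
            tric = np.clip(1.0 - (d / r) ** 3, 0.0, 1.0) ** 3
            w = tric * delta
            sw = w.sum()
            if sw <= 0:  # every in-window point robust-rejected: fall back
                w, sw = tric, tric.sum()
            xb = (w @ x) / sw
            yb = (w @ y) / sw
            sxx = w @ (x - xb) ** 2
            if sxx > 1e-12 * max(1.0, xb * xb):
                slope = (w @ ((x - xb) * (y - yb))) / sxx
            else:
                slope = 0.0
            out[i] = yb + slope * (x[i] - xb)
        if iteration == iterations:
            break
        resid = y - out
        s = float(np.median(np.abs(resid)))
        if s > 0:
            delta = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
        else:
            # majority of points fit exactly; reject the rest outright
            new = (np.abs(resid) <= 1e-9 * span).astype(float)
            if np.array_equal(new, delta) or not new.any():
                break
            delta = new
    return out


def lowess(curve: ResponseCurve, frac: float = 0.5, iterations: int = 3) -> ResponseCurve:
    """Smoothed copy of the curve (see :func:`lowess_fit`).

    Evaluated at each bin centre; a curve with fewer than 4 bins cannot
    be usefully smoothed — use the raw means instead.
    """
    if len(curve) < 4:
        raise ValueError("need at least 4 bins to smooth; use the raw curve")
    sm = lowess_fit(curve.bin_centers, curve.mean, frac=frac, iterations=iterations)
    return replace(curve, smoothed=np.asarray(sm, dtype=float))


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine an interior extremum by a 3-point parabola; falls back to x[i]."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return float(x1)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0:
        return float(x1)
    v = -b / (2 * a)
    return float(np.clip(v, x0, x2))


def estimate_set_point(
    curve: ResponseCurve,
    kind: str | None = None,
    criterion_fraction: float = 0.8,
    baseline: float | None = None,
) -> SetPointEstimate:
    """Locate the optimum and optimal range of a smoothed response curve.

    ``kind`` picks the extremum direction ("orientation" and "nfkb" →
    minimum, "smad" → maximum; "min"/"max" accepted directly).  The
    baseline defaults to a supplied no-flow value; otherwise the worst
    smoothed bin is used.  The optimal range is the maximal contiguous
    run of bins, containing the optimum, whose smoothed response lies at
    least ``criterion_fraction`` of the way from baseline to optimum.  A
    monotone curve puts the optimum on a boundary bin and sets
    ``at_boundary``.
    """
    if curve.smoothed is None:
        raise ValueError("smooth the curve first (lowess)")
    kind = kind or curve.kind
    direction = READOUT_DIRECTION.get(kind, kind)
    if direction not in ("min", "max"):
        raise ValueError(f"unknown readout kind {kind!r}")
    y = np.asarray(curve.smoothed, dtype=float)
    x = np.asarray(curve.bin_centers, dtype=float)
    i_opt = int(np.argmin(y) if direction == "min" else np.argmax(y))
    opt_val = float(y[i_opt])
    base = float(baseline) if baseline is not None else float(y.max() if direction == "min" else y.min())
    if not 0.0 < criterion_fraction <= 1.0:
        raise ValueError("criterion_fraction must lie in (0, 1]")
    threshold = base + criterion_fraction * (opt_val - base)
    good = y <= threshold if direction == "min" else y >= threshold
    # maximal contiguous run containing the optimum
    lo = i_opt
    while lo > 0 and good[lo - 1]:
        lo -= 1
    hi = i_opt
    while hi < len(y) - 1 and good[hi + 1]:
        hi += 1
    at_boundary = i_opt in (0, len(y) - 1)
    optimum = float(x[i_opt]) if at_boundary else _parabolic_vertex(x, y, i_opt)
    return SetPointEstimate(
        optimum_shear_dyn_cm2=optimum,
        range_lo_dyn_cm2=float(x[lo]),
        range_hi_dyn_cm2=float(x[hi]),
        criterion_fraction=criterion_fraction,
        baseline=base,
        optimum_value=opt_val,
        kind=kind,
        at_boundary=at_boundary,
    )


def anova_shear_effect(groups) -> tuple[float, float, int, int]:
    """One-way fixed-effects ANOVA across shear groups.

    ``groups`` is a sequence of 1-D arrays (one per shear bin) or a
    DataFrame with ``_bin``/``shear_dyn_cm2`` grouping and a value column.
    Returns ``(F, p, df_between, df_within)``.  Zero within-group
    variance with equal means leaves F undefined (NaN, flagged by the
    caller).
    """
    if isinstance(groups, pd.DataFrame):
        key = "_bin" if "_bin" in groups else "shear_dyn_cm2"
        value = [c for c in groups.columns if c not in (key, "image")][0]
        groups = [g[value].dropna().to_numpy() for _, g in groups.groupby(key)]
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    if k < 2 or n_total - k < 1:
        raise ValueError("need >= 2 groups and residual degrees of freedom")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            return float("nan"), float("nan"), k - 1, n_total - k
    f, p = stats.f_oneway(*groups)
    return float(f), float(p), k - 1, n_total - k
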