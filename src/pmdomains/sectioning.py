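"""Cluster sectioning: high-pass difference imaging plus Rényi entropy
thresholding.

The procedure detects bright, immobile microdomains ("clusters") on a dimmer
membrane background in TIRF footprints: the background-corrected frame is
median-filtered at a physical radius (default 0.9 µm) and subtracted from
itself, leaving clusters as positive excursions in the difference image.
A Rényi entropy threshold computed on the within-cell histogram of the
difference image binarizes it; connected components above a minimum size
become cluster ROIs. Whole-cell metrics (coverage fraction, density per µm²,
mean cluster area) are aggregated over the first frames of a time series
(default 10), and a bulk-membrane mask excludes everything within a physical
distance of any cluster (default 1.8 µm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import CalibratedImage, CellMask, ImageStack, median_filter_physical

__all__ = [
    "SectioningParams",
    "ClusterMap",
    "ClusterMetrics",
    "AggregatedMetrics",
    "renyi_entropy_threshold",
    "detect_clusters",
    "cluster_metrics",
    "aggregate_timeseries",
    "bulk_membrane_mask",
]

N_BINS = 256


@dataclass(frozen=True)
class SectioningParams:
    """Tunable parameters of the sectioning algorithm.

    median_radius_um : high-pass median filter radius (µm).
    renyi_method : "sahoo_combined" (three-order combination) or
        "single_alpha" with the order given by ``alpha`` (``alpha=1`` is the
        Shannon maximum-entropy criterion).
    min_cluster_px : components smaller than this are discarded.
    connectivity : 4 or 8 pixel connectivity for component labeling.
    frames_to_aggregate : number of leading frames entering time-series
        aggregation.
    bulk_exclusion_um : distance from clusters defining bulk membrane.
    """

    median_radius_um: float = 0.9
    renyi_method: str = "sahoo_combined"
    alpha: float = 1.0
    min_cluster_px: int = 4
    connectivity: int = 8
    frames_to_aggregate: int = 10
    bulk_exclusion_um: float = 1.8

    def __post_init__(self):
        if self.median_radius_um <= 0:
            raise ValueError("median_radius_um must be > 0")
        if self.min_cluster_px < 1:
            raise ValueError("min_cluster_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.frames_to_aggregate < 1:
            raise ValueError("frames_to_aggregate must be >= 1")
        if self.renyi_method not in ("sahoo_combined", "single_alpha"):
            raise ValueError(f"unknown renyi_method {self.renyi_method!r}")


@dataclass(frozen=True)
class ClusterMap:
    """Labeled cluster image plus the cell footprint it lives in."""

    labels: np.ndarray
    cell: CellMask
    threshold_used: float
    pixel_size_um: float

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.shape != self.cell.mask.shape:
            raise ValueError("labels and cell mask shape mismatch")
        object.__setattr__(self, "labels", lab)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    @property
    def cluster_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class ClusterMetrics:
    """Whole-cell cluster statistics."""

    coverage_fraction: float
    density_per_um2: float
    mean_cluster_area_um2: float
    n_clusters: int


@dataclass(frozen=True)
class AggregatedMetrics:
    """Per-frame metrics with across-frame mean and s.e.m."""

    per_frame: tuple
    mean: ClusterMetrics
    sem: ClusterMetrics


# ---------------------------------------------------------------------------
# Rényi entropy thresholding
# ---------------------------------------------------------------------------

def _class_entropies(p: np.ndarray, alpha: float) -> np.ndarray:
    """Background+foreground Rényi entropy objective for all 256 candidate
    thresholds; -inf where a class is empty.

    For alpha != 1, H of a class with probabilities p_i and mass P is
    (1/(1-alpha)) * ln( sum (p_i/P)^alpha ); alpha -> 1 recovers the Shannon
    entropy, giving the maximum-entropy criterion.
    """
    def _suffix(x):
        # sum over bins strictly above t, computed without cancellation
        s = np.zeros(N_BINS)
        s[:-1] = np.cumsum(x[::-1])[::-1][1:]
        return s

    P1 = np.cumsum(p)
    P2 = _suffix(p)
    valid = (P1 > 0) & (P2 > 0)
    obj = np.full(N_BINS, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(alpha - 1.0) < 1e-12:
            plogp = np.where(p > 0, p * np.log(p), 0.0)
            c1 = np.cumsum(plogp)
            c2 = _suffix(plogp)
            hb = np.log(P1) - c1 / P1
            hf = np.log(P2) - c2 / P2
        else:
            pa = p**alpha
            s1 = np.cumsum(pa)
            s2 = _suffix(pa)
            hb = (np.log(s1) - alpha * np.log(P1)) / (1.0 - alpha)
            hf = (np.log(s2) - alpha * np.log(P2)) / (1.0 - alpha)
    total = hb + hf
    obj[valid] = np.where(np.isfinite(total[valid]), total[valid], -np.inf)
    return obj


def _argmax_lowest(obj: np.ndarray) -> int:
    # deterministic tie-break: lowest maximizing bin
    return int(np.argmax(obj))


def _single_alpha_threshold(p: np.ndarray, alpha: float) -> int:
    return _argmax_lowest(_class_entropies(p, alpha))


def renyi_entropy_threshold(hist: np.ndarray, method: str = "sahoo_combined", alpha: float = 1.0) -> int:
    """Select a threshold bin from a 256-bin histogram by Rényi entropy.

    ``single_alpha`` maximizes the summed background/foreground Rényi
    entropies of the given order. ``sahoo_combined`` computes thresholds at
    orders 1/2, 1 and 2, sorts them, and merges them with the
    cumulative-probability β-weight rule of Sahoo, Wilkins & Yeager (1997),
    where the β triple depends on whether adjacent sorted thresholds differ
    by at most 5 gray levels. Returns the threshold bin index; pixels in
    strictly higher bins are foreground.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (N_BINS,):
        raise ValueError(f"expected a {N_BINS}-bin histogram")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")
    p = hist / hist.sum()

    if method == "single_alpha":
        return _single_alpha_threshold(p, alpha)
    if method != "sahoo_combined":
        raise ValueError(f"unknown method {method!r}")

    t_shannon = _single_alpha_threshold(p, 1.0)
    t_half = _single_alpha_threshold(p, 0.5)
    t_two = _single_alpha_threshold(p, 2.0)
    t1, t2, t3 = sorted((t_shannon, t_half, t_two))

    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 1, 2, 1
        else:
            b1, b2, b3 = 0, 1, 3
    else:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 3, 1, 0
        else:
            b1, b2, b3 = 1, 2, 1

    P1 = np.cumsum(p)
    omega = P1[t3] - P1[t1]
    t = (
        t1 * (P1[t1] + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * (1.0 - P1[t3] + 0.25 * omega * b3)
    )
    return int(t)


# ---------------------------------------------------------------------------
# Cluster detection and metrics
# ---------------------------------------------------------------------------

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def detect_clusters(
    frame: CalibratedImage,
    cell: CellMask,
    params: SectioningParams = SectioningParams(),
) -> ClusterMap:
    """Detect clusters in one background-corrected frame.

    Difference image D = max(frame - median_filter(frame, r), 0); D within
    the cell footprint is histogrammed into 256 bins and thresholded by
    Rényi entropy; components below ``min_cluster_px`` are discarded.
    A flat difference image (no structure) yields an empty map with a
    warning rather than an error.
    """
    if frame.shape != cell.mask.shape:
        raise ValueError("frame and cell mask shape mismatch")
    if not cell.mask.any():
        raise ValueError("empty cell mask")
    # fill extracellular pixels with the within-cell median before the
    # low-pass so the dark surround does not drag the local median down at
    # the cell edge and leave a spurious bright rim in the difference image
    fill = float(np.median(frame.pixels[cell.mask]))
    filled = frame.with_pixels(np.where(cell.mask, frame.pixels, fill))
    lowpass = median_filter_physical(filled, params.median_radius_um)
    diff = np.clip(frame.pixels - lowpass.pixels, 0.0, None)
    diff[~cell.mask] = 0.0
    inside = diff[cell.mask]

    empty = ClusterMap(
        np.zeros(frame.shape, dtype=np.int32), cell, float("nan"), frame.pixel_size_um
    )
    dmax = inside.max() if inside.size else 0.0
    if dmax <= 0:
        warnings.warn("flat difference image inside cell: no clusters detected", stacklevel=2)
        return empty

    # map [0, dmax] onto 256 bins; threshold bin -> intensity at its upper edge
    bin_width = dmax / N_BINS
    idx = np.minimum((inside / bin_width).astype(int), N_BINS - 1)
    hist = np.bincount(idx, minlength=N_BINS).astype(float)
    try:
        tbin = renyi_entropy_threshold(hist, params.renyi_method, params.alpha)
    except ValueError:
        warnings.warn("degenerate difference histogram: no clusters detected", stacklevel=2)
        return empty
    threshold = (tbin + 1) * bin_width

    binary = (diff > threshold) & cell.mask
    labels, n = ndimage.label(binary, structure=_STRUCTURES[params.connectivity])
    if n and params.min_cluster_px > 1:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= params.min_cluster_px)
        keep = keep[keep > 0]
        relabel = np.zeros(sizes.size, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
    return ClusterMap(labels.astype(np.int32), cell, float(threshold), frame.pixel_size_um)


def cluster_metrics(cm: ClusterMap) -> ClusterMetrics:
    """Coverage, density and size statistics for one cluster map."""
    cell_px = cm.cell.n_pixels
    if cell_px == 0:
        raise ValueError("empty cell mask")
    px_area = cm.pixel_size_um**2
    n = cm.n_clusters
    cluster_px = int(np.count_nonzero(cm.labels))
    coverage = cluster_px / cell_px
    cell_area = cell_px * px_area
    density = n / cell_area
    mean_area = (cluster_px / n) * px_area if n else 0.0
    return ClusterMetrics(coverage, density, mean_area, n)


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return m, s


def aggregate_timeseries(
    stack: ImageStack,
    cell: CellMask,
    params: SectioningParams = SectioningParams(),
) -> AggregatedMetrics:
    """Detect clusters per frame and aggregate metrics over the leading
    ``frames_to_aggregate`` frames (mean and s.e.m. per metric).

    The per-cell mean is the unit meant to enter any cross-cell statistics;
    the s.e.m. across frames only reports within-cell stability.
    """
    n_frames = params.frames_to_aggregate
    if len(stack) < n_frames:
        warnings.warn(
            f"stack has {len(stack)} frames, fewer than the {n_frames} requested; using all",
            stacklevel=2,
        )
        n_frames = len(stack)
    per_frame = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frame in stack.frames[:n_frames]:
            per_frame.append(cluster_metrics(detect_clusters(frame, cell, params)))
    fields = ["coverage_fraction", "density_per_um2", "mean_cluster_area_um2", "n_clusters"]
    means, sems = {}, {}
    for f in fields:
        vals = np.array([getattr(m, f) for m in per_frame], dtype=float)
        means[f], sems[f] = _mean_sem(vals)
    return AggregatedMetrics(
        per_frame=tuple(per_frame),
        mean=ClusterMetrics(**means),
        sem=ClusterMetrics(**sems),
    )


def bulk_membrane_mask(cm: ClusterMap, exclusion_um: float | None = None) -> CellMask:
    """Bulk (non-clustered) membrane: cell pixels at least ``exclusion_um``
    from any cluster pixel (Euclidean distance transform in µm)."""
    if exclusion_um is None:
        exclusion_um = SectioningParams().bulk_exclusion_um
    if exclusion_um < 0:
        raise ValueError("exclusion_um must be >= 0")
    cluster = cm.cluster_mask
    if not cluster.any():
        return CellMask(cm.cell.mask.copy(), cm.pixel_size_um)
    dist_px = ndimage.distance_transform_edt(~cluster)
    bulk = cm.cell.mask & (dist_px * cm.pixel_size_um >= exclusion_um) & ~cluster
    if not bulk.any():
        raise ValueError("no bulk membrane at this exclusion distance")
    return CellMask(bulk, cm.pixel_size_um)
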