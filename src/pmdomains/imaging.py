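"""Calibrated image primitives shared by all imaging stages.

A :class:`CalibratedImage` couples a 2-D intensity array (arbitrary camera
units) with its physical pixel size in µm, which is the single source of
truth for every spatial conversion downstream (median-filter radii, cluster
areas, exclusion distances). Operations here cover background correction,
physical-radius median filtering, cell-footprint segmentation and
line-profile extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "CalibratedImage",
    "ImageStack",
    "CellMask",
    "Profile",
    "background_correct",
    "background_correct_stack",
    "median_filter_physical",
    "segment_cell_footprint",
    "extract_line_profile",
    "physical_radius_px",
]

MIN_IMAGE_EDGE = 8


@dataclass(frozen=True)
class CalibratedImage:
    """2-D intensity image with physical calibration.

    Parameters
    ----------
    pixels
        Non-negative intensity array in camera units, shape (H, W).
    pixel_size_um
        Physical edge length of one pixel in µm (> 0).
    """

    pixels: np.ndarray
    pixel_size_um: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D image, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_EDGE or px.shape[1] < MIN_IMAGE_EDGE:
            raise ValueError(f"image must be at least {MIN_IMAGE_EDGE}x{MIN_IMAGE_EDGE}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **meta) -> "CalibratedImage":
        """Return a copy carrying new pixel data and updated metadata."""
        return CalibratedImage(pixels, self.pixel_size_um, {**self.meta, **meta})


@dataclass(frozen=True)
class ImageStack:
    """Ordered time series of identically calibrated frames."""

    frames: tuple
    frame_interval_s: float

    def __post_init__(self):
        frames = tuple(self.frames)
        if len(frames) < 1:
            raise ValueError("stack needs at least one frame")
        shape = frames[0].shape
        px = frames[0].pixel_size_um
        for f in frames:
            if f.shape != shape or f.pixel_size_um != px:
                raise ValueError("all frames must share shape and pixel size")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.frame_interval_s

    def as_array(self) -> np.ndarray:
        """(T, H, W) float array view of the stack."""
        return np.stack([f.pixels for f in self.frames])


@dataclass(frozen=True)
class CellMask:
    """Boolean cell footprint with its physical area."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size_um**2


@dataclass(frozen=True)
class Profile:
    """Intensity samples along a line, with arc-length positions in µm."""

    positions_um: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions_um, dtype=float)
        vals = np.asarray(self.intensities, dtype=float)
        if pos.shape != vals.shape or pos.ndim != 1:
            raise ValueError("positions and intensities must be 1-D and equal length")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.normalized and vals.size and abs(vals.mean() - 1.0) > 1e-9:
            raise ValueError("normalized profile must have mean 1")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "intensities", vals)


def physical_radius_px(radius_um: float, pixel_size_um: float) -> int:
    """Convert a physical radius to integer pixels, round-half-up, minimum 1.

    Round-half-up (not banker's rounding) so metrics are reproducible across
    platforms for a given calibration.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    r = int(np.floor(radius_um / pixel_size_um + 0.5))
    if r < 1:
        warnings.warn(
            f"radius {radius_um} µm is below one pixel at {pixel_size_um} µm/px; using 1 px",
            stacklevel=2,
        )
        r = 1
    return r


def background_correct(
    img: CalibratedImage,
    mode: str = "percentile",
    *,
    constant: float | None = None,
    percentile: float | None = None,
    cell: CellMask | None = None,
) -> CalibratedImage:
    """Subtract a scalar background offset and clip at zero.

    In ``constant`` mode the supplied offset is subtracted directly. In
    ``percentile`` mode the offset is a percentile of the extracellular
    pixels when a cell mask is supplied (default: median, which is unbiased
    under symmetric read noise and robust to hot pixels), or of the full
    frame otherwise (default: 1st percentile, approximating the dark level
    when no mask separates cell from background). Negative results are
    clipped to 0 because downstream entropy thresholding assumes
    non-negative intensities. The offset used is recorded in
    ``meta['background_offset']``.
    """
    if mode == "constant":
        if constant is None:
            raise ValueError("constant mode requires the 'constant' offset")
        offset = float(constant)
    elif mode == "percentile":
        if cell is not None:
            outside = img.pixels[~cell.mask]
            if outside.size == 0:
                raise ValueError("no extracellular pixels available for background estimation")
            if percentile is None:
                percentile = 50.0
        else:
            outside = img.pixels.ravel()
            if percentile is None:
                percentile = 1.0
        offset = float(np.percentile(outside, percentile))
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    corrected = np.clip(img.pixels - offset, 0.0, None)
    return img.with_pixels(corrected, background_offset=offset)


def background_correct_stack(
    stack: ImageStack,
    cell: CellMask | None = None,
    mode: str = "percentile",
    *,
    constant: float | None = None,
    percentile: float | None = None,
) -> ImageStack:
    """Background-correct every frame of a stack (see background_correct)."""
    frames = tuple(
        background_correct(f, mode, constant=constant, percentile=percentile, cell=cell)
        for f in stack.frames
    )
    return ImageStack(frames, stack.frame_interval_s)


def median_filter_physical(img: CalibratedImage, radius_um: float) -> CalibratedImage:
    """Median filter with a disk structuring element of physical radius.

    The pixel radius is ``round(radius_um / pixel_size_um)`` (half-up,
    min 1). Borders are handled by edge replication, which avoids the dark
    rim a zero pad would leave in the high-pass difference image at cell
    edges.
    """
    r = physical_radius_px(radius_um, img.pixel_size_um)
    footprint = disk(r)
    filtered = ndimage.median_filter(img.pixels, footprint=footprint, mode="nearest")
    return img.with_pixels(filtered, median_radius_px=r)


def segment_cell_footprint(
    img: CalibratedImage,
    method: str = "otsu",
    *,
    polygon: np.ndarray | None = None,
    smooth_sigma_px: float = 2.0,
) -> CellMask:
    """Segment the cell footprint as a single filled connected component.

    ``otsu`` thresholds a lightly Gaussian-smoothed copy; ``manual`` rasterizes
    a user polygon given as (row, col) vertices. In either case only the
    largest connected component is kept and interior holes are filled.
    """
    if method == "otsu":
        if np.ptp(img.pixels) == 0:
            raise ValueError("no cell detected: image has zero dynamic range")
        smoothed = ndimage.gaussian_filter(img.pixels, smooth_sigma_px)
        if np.ptp(smoothed) == 0:
            raise ValueError("no cell detected: image has zero dynamic range")
        binary = smoothed > threshold_otsu(smoothed)
    elif method == "manual":
        if polygon is None:
            raise ValueError("manual method requires a polygon")
        from skimage.draw import polygon2mask

        binary = polygon2mask(img.shape, np.asarray(polygon, dtype=float))
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no cell detected")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return CellMask(mask, img.pixel_size_um)


def extract_line_profile(
    img: CalibratedImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    normalize: bool = False,
) -> Profile:
    """Sample intensities along the segment p0→p1 at ~1 px spacing.

    Endpoints are (row, col) pixel coordinates inside the image. Sampling
    uses bilinear interpolation; positions are arc length in µm from p0.
    If ``normalize``, intensities are divided by their mean.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h, w = img.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"endpoint {tuple(p)} outside image of shape {img.shape}")
    length_px = float(np.hypot(*(p1 - p0)))
    if length_px == 0:
        raise ValueError("zero-length profile segment")
    n = int(np.ceil(length_px)) + 1
    t = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] + (p1 - p0)[:, None] * t[None, :]
    vals = ndimage.map_coordinates(img.pixels, coords, order=1, mode="nearest")
    positions = t * length_px * img.pixel_size_um
    if normalize:
        m = vals.mean()
        if m == 0:
            raise ValueError("cannot normalize profile with zero mean")
        vals = vals / m
    return Profile(positions, vals, normalized=normalize)
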