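"""Pixel-wise colocalization and line-profile comparison.

Pearson's correlation coefficient over a cell mask quantifies how well two
fluorescence channels co-vary pixel by pixel; it is invariant to gain and
offset in either channel, which makes it the standard readout for
colocalization of membrane markers. No intensity thresholding is applied:
the plain whole-mask coefficient is reported. The membrane index quantifies
wide-field membrane-versus-cytosol localization from a line profile crossing
the cell: mean reporter intensity at the two membrane-marker peaks divided
by mean cytosolic intensity between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .imaging import CalibratedImage, CellMask, Profile, extract_line_profile

__all__ = [
    "ColocResult",
    "MembraneIndex",
    "pearson_coefficient",
    "profile_pair",
    "membrane_index",
]

MIN_MASK_PIXELS = 16


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    n_pixels: int
    mask_area_um2: float


@dataclass(frozen=True)
class MembraneIndex:
    peak_mean: float
    cytosol_mean: float

    @property
    def index(self) -> float:
        return self.peak_mean / self.cytosol_mean


def pearson_coefficient(
    img_a: CalibratedImage, img_b: CalibratedImage, mask: CellMask
) -> ColocResult:
    """Pearson correlation of two channels over the masked pixels."""
    if img_a.shape != img_b.shape or img_a.shape != mask.mask.shape:
        raise ValueError("images and mask must share a shape")
    a = img_a.pixels[mask.mask]
    b = img_b.pixels[mask.mask]
    if a.size < MIN_MASK_PIXELS:
        raise ValueError(f"mask must contain at least {MIN_MASK_PIXELS} pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined correlation: constant channel within mask")
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocResult(pearson_r=r, n_pixels=a.size, mask_area_um2=mask.area_um2)


def profile_pair(
    img_a: CalibratedImage,
    img_b: CalibratedImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
) -> tuple[Profile, Profile]:
    """Extract the same line profile from both channels, each normalized to
    its own mean so that gain differences drop out."""
    pa = extract_line_profile(img_a, p0, p1, normalize=True)
    pb = extract_line_profile(img_b, p0, p1, normalize=True)
    return pa, pb


def membrane_index(
    gfp_profile: Profile,
    marker_profile: Profile,
    *,
    min_separation_fraction: float = 0.25,
    prominence_fraction: float = 0.2,
) -> MembraneIndex:
    """Membrane-to-cytosol localization index from a cross-cell profile.

    The two highest local maxima of the membrane-marker profile separated by
    at least ``min_separation_fraction`` of the profile length locate the two
    plasma-membrane crossings; the reporter (GFP) intensity at those peaks
    (±1 sample) is averaged and divided by its mean over the central 50% of
    the inter-peak interval (the cytosol).
    """
    marker = marker_profile.intensities
    gfp = gfp_profile.intensities
    if marker.shape != gfp.shape:
        raise ValueError("profiles must be sampled at identical positions")
    n = marker.size
    prominence = prominence_fraction * np.ptp(marker)
    peaks, props = find_peaks(marker, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("profile does not cross membrane twice")
    # pick the two highest peaks subject to the separation constraint
    order = peaks[np.argsort(marker[peaks])[::-1]]
    min_sep = min_separation_fraction * n
    i = int(order[0])
    j = None
    for cand in order[1:]:
        if abs(int(cand) - i) >= min_sep:
            j = int(cand)
            break
    if j is None:
        raise ValueError("profile does not cross membrane twice")
    lo, hi = sorted((i, j))

    def peak_window_mean(k: int) -> float:
        return float(gfp[max(k - 1, 0) : min(k + 2, n)].mean())

    peak_mean = 0.5 * (peak_window_mean(lo) + peak_window_mean(hi))
    span = hi - lo
    c0 = lo + int(round(0.25 * span))
    c1 = lo + int(round(0.75 * span))
    cytosol = gfp[c0 : c1 + 1]
    cytosol_mean = float(cytosol.mean())
    if cytosol_mean <= 0:
        raise ValueError("non-positive cytosolic intensity")
    return MembraneIndex(peak_mean=peak_mean, cytosol_mean=cytosol_mean)
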