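"""Seeded synthetic-data generators with exact ground truth.

Every analysis stage in this package is validated against data generated
here: TIRF-like footprints of adherent cells carrying bright immobile
clusters on a dimmer membrane background, correlated two-channel image
pairs with a tunable true Pearson coefficient, monoexponential FRAP
recovery traces with an immobile fraction, lipid-depletion image series
with distinct cluster/bulk residuals, and two-state (bound/unbound)
membrane-distance trajectories. Each generator is a pure function of its
parameters and seed, and returns the exact realized truth (masks, coverage,
density, ρ, τ, bound fraction) alongside the data.

Camera model: photon signal is Poisson-distributed (scaled by
``poisson_scale``), the electronic offset is noise-free, and Gaussian read
noise is added everywhere — the standard sCMOS/CCD model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .imaging import CalibratedImage, CellMask, ImageStack
from .kinetics import FrapTrace
from .mdbinding import DistanceTrajectory

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "radius_for_coverage",
    "synth_tirf_scene",
    "synth_coloc_pair",
    "synth_frap_trace",
    "synth_depletion_stack",
    "synth_distance_traj",
    "child_seeds",
]

MAX_PLACEMENT_ATTEMPTS = 10_000


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Fan a single seed out into ``n`` independent child seeds (< 2**31)."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def radius_for_coverage(coverage: float, density_per_um2: float) -> float:
    """Cluster radius (µm) that realizes a target coverage at a given
    density: coverage = density * pi * r**2, hence r = sqrt(c / (pi * d))."""
    if not (0 < coverage < 1) or density_per_um2 <= 0:
        raise ValueError("coverage in (0,1) and density > 0 required")
    return float(np.sqrt(coverage / (np.pi * density_per_um2)))


@dataclass(frozen=True)
class SceneSpec:
    """Parameterization of a synthetic TIRF footprint.

    Defaults emulate a CHO-cell footprint with clusters at the density and
    coverage typical of tubbyCT microdomains (0.66 clusters/µm² covering
    ~10.5% of the cell). ``cluster_radius_um`` is the root-mean-square
    cluster radius, so that expected coverage = density * pi * radius**2
    regardless of ``cluster_radius_spread`` (lognormal sigma in log space).
    ``enrichment_factor`` is the cluster/bulk intensity ratio.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    cell_axes_um: tuple[float, float] = (18.0, 13.0)  # semi-axes
    cell_center_px: tuple[float, float] | None = None
    camera_offset: float = 100.0
    bulk_intensity: float = 250.0
    cluster_density_per_um2: float = 0.66
    cluster_radius_um: float = radius_for_coverage(0.105, 0.66)
    cluster_radius_spread: float = 0.15
    enrichment_factor: float = 2.0
    poisson_scale: float = 1.0
    gaussian_sigma: float = 2.0
    background_gradient: float = 0.1
    n_frames: int = 10
    frame_interval_s: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.cluster_density_per_um2 < 0:
            raise ValueError("cluster density must be >= 0")
        if self.cluster_radius_um <= 0:
            raise ValueError("cluster radius must be > 0")

    @property
    def target_coverage(self) -> float:
        return self.cluster_density_per_um2 * np.pi * self.cluster_radius_um**2


@dataclass(frozen=True)
class GroundTruth:
    """Exact realized truth of a generated scene."""

    cluster_mask: np.ndarray
    coverage_fraction: float
    density_per_um2: float
    n_clusters: int
    centers_px: np.ndarray = field(compare=False, default=None)
    radii_px: np.ndarray = field(compare=False, default=None)


def _ellipse_mask(shape, center, semi_axes_px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ay, ax = semi_axes_px
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _place_clusters(rng, spec: SceneSpec, cell_mask: np.ndarray):
    """Place non-overlapping disks uniformly inside the cell by rejection
    sampling. Disk edges keep a >=2 px gap so rasterized components never
    touch at 8-connectivity."""
    px = spec.pixel_size_um
    cell_area_um2 = cell_mask.sum() * px**2
    n_target = int(round(spec.cluster_density_per_um2 * cell_area_um2))
    h, w = spec.image_shape
    cy, cx = spec.cell_center_px if spec.cell_center_px is not None else (h / 2, w / 2)
    ay, ax = spec.cell_axes_um[0] / px, spec.cell_axes_um[1] / px

    sigma = spec.cluster_radius_spread
    mu = np.log(spec.cluster_radius_um / px) - sigma**2  # E[r^2] = rms^2
    radii = np.exp(rng.normal(mu, sigma, size=n_target)) if sigma > 0 else np.full(
        n_target, spec.cluster_radius_um / px
    )

    centers = np.empty((n_target, 2))
    gap = 2.0
    for i in range(n_target):
        r = radii[i]
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            # uniform in the ellipse shrunk so the disk stays inside the cell
            u, v = rng.uniform(-1, 1, 2)
            if u * u + v * v > 1:
                continue
            y = cy + u * max(ay - r - 1, 1)
            x = cx + v * max(ax - r - 1, 1)
            if i and np.any(
                np.hypot(centers[:i, 0] - y, centers[:i, 1] - x) < radii[:i] + r + gap
            ):
                continue
            centers[i] = (y, x)
            break
        else:
            raise ValueError(
                f"cannot place clusters: density/radius combination infeasible "
                f"(stuck after {i} of {n_target})"
            )

    mask = np.zeros(spec.image_shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for (y, x), r in zip(centers, radii):
        y0, y1 = int(max(y - r - 1, 0)), int(min(y + r + 2, h))
        x0, x1 = int(max(x - r - 1, 0)), int(min(x + r + 2, w))
        sub = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2 <= r * r
        mask[y0:y1, x0:x1] |= sub
    return mask, centers, radii, n_target, cell_area_um2


def _noisy_frame(rng, signal, spec: SceneSpec):
    counts = signal
    if spec.poisson_scale > 0:
        counts = rng.poisson(signal * spec.poisson_scale) / spec.poisson_scale
    frame = spec.camera_offset + counts
    if spec.gaussian_sigma > 0:
        frame = frame + rng.normal(0.0, spec.gaussian_sigma, size=signal.shape)
    return np.clip(frame, 0.0, None)


def _scene_signal(spec: SceneSpec, cell_mask: np.ndarray, cluster_mask: np.ndarray):
    h, w = spec.image_shape
    tilt = 1.0 + spec.background_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
    signal = np.zeros(spec.image_shape)
    signal[cell_mask] = spec.bulk_intensity
    signal[cluster_mask & cell_mask] = spec.bulk_intensity * spec.enrichment_factor
    return signal * tilt[None, :]


def synth_tirf_scene(spec: SceneSpec) -> tuple[ImageStack, CellMask, GroundTruth]:
    """Generate an immobile-cluster TIRF time series with exact truth.

    Clusters are non-overlapping disks placed uniformly inside an elliptical
    cell; they are identical across frames (immobile on the imaging time
    scale) while the noise is redrawn per frame. The returned GroundTruth
    records the realized rasterized mask and the metrics computed from it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.image_shape
    center = spec.cell_center_px if spec.cell_center_px is not None else (h / 2, w / 2)
    px = spec.pixel_size_um
    cell_mask = _ellipse_mask(
        spec.image_shape, center, (spec.cell_axes_um[0] / px, spec.cell_axes_um[1] / px)
    )
    cluster_mask, centers, radii, n_clusters, cell_area_um2 = _place_clusters(
        rng, spec, cell_mask
    )
    signal = _scene_signal(spec, cell_mask, cluster_mask)
    frames = tuple(
        CalibratedImage(_noisy_frame(rng, signal, spec), px)
        for _ in range(spec.n_frames)
    )
    stack = ImageStack(frames, spec.frame_interval_s)
    truth = GroundTruth(
        cluster_mask=cluster_mask,
        coverage_fraction=float(cluster_mask[cell_mask].mean()),
        density_per_um2=n_clusters / cell_area_um2,
        n_clusters=n_clusters,
        centers_px=centers,
        radii_px=radii,
    )
    return stack, CellMask(cell_mask, px), truth


def synth_coloc_pair(
    shape: tuple[int, int] = (512, 512),
    rho: float = 0.3,
    seed: int = 0,
    pixel_size_um: float = 0.1,
    mean: float = 200.0,
    amplitude: float = 25.0,
) -> tuple[CalibratedImage, CalibratedImage, CellMask]:
    """Two-channel image pair with true pixel-wise Pearson coefficient rho.

    Built by Gaussian mixing: A from a standardized field z1, B from
    rho*z1 + sqrt(1-rho^2)*z2, each affinely mapped to a positive intensity
    range (no clipping at the chosen amplitude), so the expected sample
    Pearson equals rho exactly.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z1 = rng.standard_normal(shape)
    z2 = rng.standard_normal(shape)
    zb = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    img_a = CalibratedImage(mean + amplitude * z1, pixel_size_um)
    img_b = CalibratedImage(mean + amplitude * zb, pixel_size_um)
    mask = _ellipse_mask(shape, (shape[0] / 2, shape[1] / 2), (shape[0] / 2.2, shape[1] / 2.2))
    return img_a, img_b, CellMask(mask, pixel_size_um)


def synth_frap_trace(
    tau_s: float = 2.0,
    mobile_fraction: float = 0.8,
    f0: float = 0.2,
    dt_s: float = 0.1,
    duration_s: float = 20.0,
    sigma: float = 0.0,
    seed: int = 0,
    pre_bleach_s: float = 1.0,
) -> FrapTrace:
    """Monoexponential FRAP recovery with an immobile fraction.

    Pre-bleach samples sit at 1; after the bleach,
    F(t) = f0 + mobile*(1 - f0)*(1 - exp(-t/tau)) + Gaussian noise sigma.
    Default cadence 0.1 s emulates typical FRAP acquisition.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_pre = max(3, int(round(pre_bleach_s / dt_s)))
    n_post = int(round(duration_s / dt_s)) + 1
    times = np.arange(n_pre + n_post) * dt_s
    t_post = np.arange(n_post) * dt_s
    y = np.ones(n_pre + n_post)
    y[n_pre:] = f0 + mobile_fraction * (1.0 - f0) * (1.0 - np.exp(-t_post / tau_s))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=y.shape)
    return FrapTrace(times_s=times, intensities=y, bleach_index=n_pre)


@dataclass(frozen=True)
class DepletionTruth:
    residual_cluster: float
    residual_bulk: float
    tau_dep_s: float
    t_on_s: float


def synth_depletion_stack(
    spec: SceneSpec | None = None,
    residual_cluster: float = 0.2,
    residual_bulk: float = 0.1,
    tau_dep_s: float = 6.0,
    t_on_s: float = 20.0,
    activation_s: float = 60.0,
    noise_sigma_frac: float = 0.0,
    seed: int = 0,
):
    """Image series in which cluster and bulk intensities decay to distinct
    residuals after lipid-depletion onset at ``t_on_s``.

    Emulates acute PI(4,5)P2 depletion during a depolarization step: frames
    every 4 s (from the spec's frame interval), decay time constant
    ``tau_dep_s``, residuals as fractions of baseline. Returns
    (ImageStack, ClusterMap-ready truth mask, CellMask, DepletionTruth).

    The default scene is sparser than the cluster-detection default
    (0.08 clusters/µm², radius 0.4 µm) so that a bulk-membrane region at
    the standard 1.8 µm exclusion distance actually exists.
    """
    for r in (residual_cluster, residual_bulk):
        if not 0 <= r <= 1:
            raise ValueError("residuals must be in [0, 1]")
    if spec is None:
        spec = SceneSpec(
            cluster_density_per_um2=0.08, cluster_radius_um=0.4, seed=seed
        )
    else:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed + 1))
    h, w = spec.image_shape
    px = spec.pixel_size_um
    center = spec.cell_center_px if spec.cell_center_px is not None else (h / 2, w / 2)
    cell_mask = _ellipse_mask(
        spec.image_shape, center, (spec.cell_axes_um[0] / px, spec.cell_axes_um[1] / px)
    )
    cluster_mask, *_ = _place_clusters(
        np.random.default_rng(np.random.SeedSequence(spec.seed)), spec, cell_mask
    )
    bulk_mask = cell_mask & ~cluster_mask

    n_frames = int(round((t_on_s + activation_s) / spec.frame_interval_s)) + 1
    times = np.arange(n_frames) * spec.frame_interval_s
    frames = []
    base = np.zeros(spec.image_shape)
    base[bulk_mask] = spec.bulk_intensity
    base[cluster_mask] = spec.bulk_intensity * spec.enrichment_factor
    for t in times:
        if t < t_on_s:
            scale_cl = scale_bk = 1.0
        else:
            decay = np.exp(-(t - t_on_s) / tau_dep_s)
            scale_cl = residual_cluster + (1 - residual_cluster) * decay
            scale_bk = residual_bulk + (1 - residual_bulk) * decay
        img = spec.camera_offset + np.where(cluster_mask, base * scale_cl, base * scale_bk)
        if noise_sigma_frac > 0:
            img = img + rng.normal(0.0, noise_sigma_frac * spec.bulk_intensity, size=img.shape)
        frames.append(CalibratedImage(np.clip(img, 0, None), px))
    stack = ImageStack(tuple(frames), spec.frame_interval_s)
    truth = DepletionTruth(residual_cluster, residual_bulk, tau_dep_s, t_on_s)
    return stack, cluster_mask, CellMask(cell_mask, px), truth


def synth_distance_traj(
    p_unbound_to_bound: float = 0.1,
    p_bound_to_unbound: float = 0.1,
    bound_mu_nm: float = 1.5,
    bound_sigma_nm: float = 0.15,
    unbound_range_nm: tuple[float, float] = (3.0, 6.0),
    n_frames: int = 10_000,
    seed: int = 0,
    dt_us: float = 0.01,
    compartment: str = "B",
    replica_id: int = 0,
    pip2_molpercent: float | None = None,
) -> DistanceTrajectory:
    """Two-state (bound/unbound) Markov-chain distance trajectory.

    Bound frames draw the pocket-PO4 distance from a normal distribution
    truncated to positive values; unbound frames from a uniform range above
    the binding cutoff. The initial state is drawn from the stationary
    distribution p_bound = p_ub / (p_ub + p_bu), so the expected bound
    fraction equals the stationary probability at every trajectory length.
    """
    p_ub, p_bu = p_unbound_to_bound, p_bound_to_unbound
    for p in (p_ub, p_bu):
        if not 0 <= p <= 1:
            raise ValueError("switch probabilities must be in [0, 1]")
    if p_ub + p_bu == 0:
        raise ValueError("at least one switch probability must be positive")
    if bound_mu_nm >= unbound_range_nm[0]:
        raise ValueError("bound_mu_nm must lie below the unbound range")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p_stat = p_ub / (p_ub + p_bu)
    bound = np.empty(n_frames, dtype=bool)
    bound[0] = rng.random() < p_stat
    u = rng.random(n_frames)
    for i in range(1, n_frames):
        bound[i] = (u[i] < p_ub) if not bound[i - 1] else (u[i] >= p_bu)
    d = np.empty(n_frames)
    n_b = int(bound.sum())
    db = rng.normal(bound_mu_nm, bound_sigma_nm, size=n_b)
    while np.any(db <= 0):  # truncate at 0
        bad = db <= 0
        db[bad] = rng.normal(bound_mu_nm, bound_sigma_nm, size=int(bad.sum()))
    d[bound] = db
    d[~bound] = rng.uniform(*unbound_range_nm, size=n_frames - n_b)
    times = np.arange(n_frames) * dt_us + dt_us
    return DistanceTrajectory(
        times_us=times,
        distances_nm=d,
        compartment=compartment,
        pip2_molpercent=pip2_molpercent,
        replica_id=replica_id,
    )
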