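"""Membrane-binding statistics from coarse-grained trajectory distances.

The raw observable is the distance (nm) between a protein's lipid-binding
pocket and the phosphate (PO4) plane of one membrane leaflet, sampled along
a simulation trajectory. Binding is scored by integrating the distance
population up to a cutoff, implemented as direct frame counting (equivalent
to integrating the normalized histogram, without binning artifacts):
default cutoffs 2.25 nm for tubbyCT and 2.0 nm for the PLCδ1 PH domain.
When the protein can bind either of two competing leaflets (compartments A
and B carrying different lipid concentrations), the compartment-B population
P_B = bound_B / (bound_A + bound_B) over frames bound to either leaflet
summarizes the preference; replicas are aggregated as mean ± s.e.m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DistanceTrajectory",
    "BindingSummary",
    "CompartmentPopulation",
    "CUTOFF_NM",
    "distance_histogram",
    "bound_fraction",
    "compartment_population",
]

# default PO4-pocket distance cutoffs by protein tag
CUTOFF_NM = {"tubbyCT": 2.25, "PLCd1-PH": 2.0}

MIN_HISTOGRAM_FRAMES = 100


@dataclass(frozen=True)
class DistanceTrajectory:
    """Pocket-to-PO4-plane distance time series for one compartment."""

    times_us: np.ndarray
    distances_nm: np.ndarray
    compartment: str = "B"
    pip2_molpercent: float | None = None
    replica_id: int = 0

    def __post_init__(self):
        t = np.asarray(self.times_us, dtype=float)
        d = np.asarray(self.distances_nm, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and distances must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("distances must be finite and positive")
        if self.compartment not in ("A", "B"):
            raise ValueError("compartment must be 'A' or 'B'")
        object.__setattr__(self, "times_us", t)
        object.__setattr__(self, "distances_nm", d)

    @property
    def n_frames(self) -> int:
        return self.times_us.size


@dataclass(frozen=True)
class BindingSummary:
    bound_fraction: float
    cutoff_nm: float
    n_frames: int
    replica_id: int = 0

    @property
    def n_bound(self) -> int:
        return int(round(self.bound_fraction * self.n_frames))


@dataclass(frozen=True)
class CompartmentPopulation:
    """Replica-aggregated population bound to compartment B."""

    per_replica: tuple
    mean: float
    sem: float
    n_replicas: int


def distance_histogram(
    traj: DistanceTrajectory, bin_width_nm: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of the distance trajectory over [0, max distance].

    Returns ``(bin_edges, density)`` with ``sum(density) * bin_width = 1``.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if traj.n_frames < MIN_HISTOGRAM_FRAMES:
        import warnings

        warnings.warn(
            f"histogram from only {traj.n_frames} frames (< {MIN_HISTOGRAM_FRAMES}) "
            "will be poorly sampled",
            stacklevel=2,
        )
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be > 0")
    dmax = traj.distances_nm.max()
    # one bin past the maximum so every bin is right-open, [k*w, (k+1)*w)
    n_bins = int(np.floor(dmax / bin_width_nm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_nm
    density, edges = np.histogram(traj.distances_nm, bins=edges, density=True)
    return edges, density


def bound_fraction(
    traj: DistanceTrajectory,
    cutoff_nm: float | None = None,
    protein: str = "tubbyCT",
) -> BindingSummary:
    """Fraction of frames with pocket-PO4 distance at or below the cutoff.

    ``cutoff_nm`` overrides the per-protein default (tubbyCT: 2.25 nm,
    PLCd1-PH: 2.0 nm).
    """
    if cutoff_nm is None:
        try:
            cutoff_nm = CUTOFF_NM[protein]
        except KeyError:
            raise ValueError(f"no default cutoff for protein {protein!r}") from None
    frac = float(np.mean(traj.distances_nm <= cutoff_nm)) if traj.n_frames else 0.0
    return BindingSummary(bound_fraction=frac, cutoff_nm=float(cutoff_nm), n_frames=traj.n_frames)


def compartment_population(
    frac_a: Sequence[BindingSummary],
    frac_b: Sequence[BindingSummary],
    symmetric_control: bool = False,
) -> CompartmentPopulation:
    """Population bound to compartment B, aggregated over replicas.

    ``frac_a`` and ``frac_b`` are paired bound-fraction summaries from the
    same replica set (one pair per replica). Per replica
    P_B = bound_B / (bound_A + bound_B) over frames bound to either
    compartment; frames bound to neither are excluded (binding to both
    leaflets at once is sterically excluded, so the counts are disjoint).
    With ``symmetric_control`` (both leaflets carrying the same lipid
    concentration) each replica's value is replaced by the average of the
    two leaflet populations, (P_B + P_A)/2, mirroring the leaflet averaging
    applied to a symmetric setup. Replicas where the protein never binds
    either compartment are excluded with a warning.
    """
    import warnings

    if len(frac_a) != len(frac_b):
        raise ValueError("need paired A/B summaries per replica")
    values = []
    for sa, sb in zip(frac_a, frac_b):
        n_a, n_b = sa.n_bound, sb.n_bound
        if n_a + n_b == 0:
            warnings.warn(
                f"replica {sa.replica_id}: never bound to either compartment; excluded",
                stacklevel=2,
            )
            continue
        p_b = n_b / (n_a + n_b)
        if symmetric_control:
            p_b = 0.5 * ((1.0 - p_b) + p_b)
        values.append(p_b)
    if not values:
        raise ValueError("no replica with bound frames")
    vals = np.asarray(values)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return CompartmentPopulation(
        per_replica=tuple(values), mean=mean, sem=sem, n_replicas=vals.size
    )


def bound_series(traj: DistanceTrajectory, cutoff_nm: float) -> np.ndarray:
    """Boolean per-frame bound indicator (distance <= cutoff)."""
    return traj.distances_nm <= cutoff_nm
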