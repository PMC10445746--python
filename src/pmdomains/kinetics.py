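"""FRAP and lipid-depletion kinetics.

FRAP recovery is modeled as a single exponential
``F(t) = f_inf - (f_inf - f0) * exp(-(t - t_bleach)/tau)`` after
normalization to the pre-bleach mean. ``tau`` reports mobility of the
fluorescent species and the unrecovered plateau the immobile fraction:
``mobile = (f_inf - f0) / (1 - f0)``.

Depletion analysis quantifies biosensor dissociation after acute lipid
depletion (e.g. voltage-activated Ci-VSP phosphatase): per-frame mean
intensity inside the cluster and bulk-membrane masks, each normalized to its
pre-activation baseline; the residual is the mean of the normalized trace
over a plateau window at the end of the activation period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .imaging import CellMask, ImageStack
from .sectioning import ClusterMap

__all__ = [
    "FrapTrace",
    "FrapFit",
    "DepletionResult",
    "fit_frap",
    "depletion_response",
]

MIN_PRE_BLEACH = 3
MIN_POST_BLEACH = 10


@dataclass(frozen=True)
class FrapTrace:
    """Time-intensity record of one bleach/recovery experiment.

    ``bleach_index`` is the index of the first post-bleach sample.
    Intensities are background-corrected ROI means in camera units; they are
    normalized internally, so absolute gain is irrelevant.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    bleach_index: int

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("times must start at 0")
        if self.bleach_index < MIN_PRE_BLEACH:
            raise ValueError(f"need at least {MIN_PRE_BLEACH} pre-bleach samples")
        if t.size - self.bleach_index < MIN_POST_BLEACH:
            raise ValueError(f"need at least {MIN_POST_BLEACH} post-bleach samples")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class FrapFit:
    """Monoexponential parameterization of a recovery trace."""

    tau_s: float
    f0: float
    f_inf: float
    mobile_fraction: float
    rmse: float
    tau_identifiable: bool = True
    meta: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class DepletionResult:
    residual_cluster: float
    residual_bulk: float
    n_frames_plateau: int
    trace_cluster: np.ndarray = field(compare=False, default=None)
    trace_bulk: np.ndarray = field(compare=False, default=None)


def _recovery_model(t, f0, f_inf, tau):
    return f_inf - (f_inf - f0) * np.exp(-t / tau)


def fit_frap(trace: FrapTrace, reference: np.ndarray | None = None) -> FrapFit:
    """Fit the monoexponential recovery model to a FRAP trace.

    The trace is normalized to its pre-bleach mean; an optional unbleached
    ``reference`` trace (same length) corrects for acquisition bleaching by
    division after its own baseline normalization. Initialization: f0 from
    the first post-bleach sample, f_inf from the last 10% of samples, tau
    from the time to half recovery divided by ln 2.
    """
    y = trace.intensities.astype(float)
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != y.shape:
            raise ValueError("reference trace length mismatch")
        ref_base = ref[: trace.bleach_index].mean()
        if ref_base <= 0 or np.any(ref <= 0):
            raise ValueError("reference trace must be positive")
        y = y / (ref / ref_base)
    pre = y[: trace.bleach_index].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach baseline")
    y = y / pre
    t_post = trace.times_s[trace.bleach_index :] - trace.times_s[trace.bleach_index]
    y_post = y[trace.bleach_index :]

    f0_init = float(y_post[0])
    n_tail = max(1, int(round(0.1 * y_post.size)))
    f_inf_init = float(y_post[-n_tail:].mean())
    dt = float(np.median(np.diff(trace.times_s)))
    duration = float(t_post[-1])

    # flat trace: no recovery to fit
    span = f_inf_init - f0_init
    if abs(span) < 1e-12 or np.ptp(y_post) < 1e-12:
        mobile = 0.0
        return FrapFit(
            tau_s=float("nan"), f0=f0_init, f_inf=f_inf_init,
            mobile_fraction=mobile, rmse=float(np.std(y_post)),
            tau_identifiable=False, meta={"raw_mobile_fraction": mobile},
        )

    half = f0_init + 0.5 * span
    above = np.nonzero(y_post >= half)[0] if span > 0 else np.nonzero(y_post <= half)[0]
    t_half = t_post[above[0]] if above.size else duration / 2
    tau_init = max(t_half / np.log(2), dt)

    try:
        popt, _ = curve_fit(
            _recovery_model, t_post, y_post,
            p0=[f0_init, f_inf_init, tau_init],
            bounds=([0.0, 0.0, dt / 100], [2.0, 2.0, 1000 * duration]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(f"unidentifiable kinetics: fit did not converge ({exc})") from exc
    f0, f_inf, tau = (float(v) for v in popt)
    if not (dt / 10 < tau < 100 * duration):
        raise ValueError(
            f"unidentifiable kinetics: tau={tau:.3g} s outside ({dt / 10:.3g}, {100 * duration:.3g})"
        )
    resid = y_post - _recovery_model(t_post, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    raw_mobile = (f_inf - f0) / (1.0 - f0) if f0 < 1.0 else float("nan")
    mobile = float(np.clip(raw_mobile, 0.0, 1.0))
    return FrapFit(
        tau_s=tau, f0=f0, f_inf=f_inf, mobile_fraction=mobile, rmse=rmse,
        tau_identifiable=True, meta={"raw_mobile_fraction": raw_mobile},
    )


def depletion_response(
    stack: ImageStack,
    clusters: ClusterMap,
    bulk: CellMask,
    t_on_s: float,
    t_window_s: float | None = None,
) -> DepletionResult:
    """Residual membrane association in cluster vs bulk regions.

    Per-frame mean intensity inside the cluster mask and the bulk mask, each
    normalized to its pre-activation (t < ``t_on_s``) baseline mean. The
    residual is the mean of the normalized trace over the final
    ``t_window_s`` seconds (default: the last 3 frames).
    """
    cl_mask = clusters.cluster_mask
    if not cl_mask.any():
        raise ValueError("empty cluster mask")
    if not bulk.mask.any():
        raise ValueError("empty bulk mask")
    arr = stack.as_array()
    times = stack.times_s
    baseline = times < t_on_s
    if baseline.sum() < 3:
        raise ValueError("need at least 3 baseline frames before activation")

    trace_cl = arr[:, cl_mask].mean(axis=1)
    trace_bk = arr[:, bulk.mask].mean(axis=1)
    for name, tr in (("cluster", trace_cl), ("bulk", trace_bk)):
        if tr[baseline].mean() <= 0:
            raise ValueError(f"non-positive {name} baseline")
    trace_cl = trace_cl / trace_cl[baseline].mean()
    trace_bk = trace_bk / trace_bk[baseline].mean()

    if t_window_s is None:
        n_plateau = 3
    else:
        n_plateau = max(1, int(round(t_window_s / stack.frame_interval_s)))
    n_plateau = min(n_plateau, len(stack))
    return DepletionResult(
        residual_cluster=float(trace_cl[-n_plateau:].mean()),
        residual_bulk=float(trace_bk[-n_plateau:].mean()),
        n_frames_plateau=n_plateau,
        trace_cluster=trace_cl,
        trace_bulk=trace_bk,
    )
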