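"""End-to-end convenience pipelines.

These wire the stages together the way a full analysis run does: generate or
load a stack, segment the cell footprint from the image, background-correct,
then run the stage-specific measurement. They are also the entry points the
validation studies use to measure how well the pipeline recovers generator
ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .coloc import pearson_coefficient
from .imaging import background_correct, segment_cell_footprint
from .sectioning import AggregatedMetrics, SectioningParams, aggregate_timeseries
from .synth import SceneSpec, child_seeds, synth_coloc_pair, synth_tirf_scene

__all__ = ["measure_scene", "cluster_recovery_study", "pearson_recovery_study"]


def measure_scene(
    spec: SceneSpec, params: SectioningParams = SectioningParams()
) -> tuple[AggregatedMetrics, "np.ndarray"]:
    """Full sectioning pipeline on one generated scene.

    Segments the cell footprint from the first frame, background-corrects
    every frame against the extracellular region, and aggregates cluster
    metrics over the leading frames. Returns the aggregate and the truth
    (coverage, density) pair.
    """
    stack, _, truth = synth_tirf_scene(spec)
    cell = segment_cell_footprint(stack.frames[0])
    corrected = dataclasses.replace(
        stack,
        frames=tuple(background_correct(f, cell=cell) for f in stack.frames),
    )
    agg = aggregate_timeseries(corrected, cell, params)
    return agg, np.array([truth.coverage_fraction, truth.density_per_um2])


def cluster_recovery_study(
    seed: int,
    n_scenes: int = 20,
    spec: SceneSpec = SceneSpec(),
    params: SectioningParams = SectioningParams(),
) -> dict:
    """Detected vs truth coverage and density over seeded scenes.

    Returns across-scene means of the per-scene (10-frame-aggregated)
    detected coverage fraction and density, alongside the realized truth
    means.
    """
    cov_det, den_det, truths = [], [], []
    for s in child_seeds(seed, n_scenes):
        agg, truth = measure_scene(dataclasses.replace(spec, seed=int(s)), params)
        cov_det.append(agg.mean.coverage_fraction)
        den_det.append(agg.mean.density_per_um2)
        truths.append(truth)
    truths = np.asarray(truths)
    return {
        "coverage_detected": float(np.mean(cov_det)),
        "density_detected": float(np.mean(den_det)),
        "coverage_truth": float(truths[:, 0].mean()),
        "density_truth": float(truths[:, 1].mean()),
        "n_scenes": n_scenes,
    }


def pearson_recovery_study(
    seed: int, rho: float = 0.3, n_pairs: int = 10, shape=(512, 512)
) -> dict:
    """Measured Pearson coefficient on generated pairs with true mixing
    coefficient rho; returns the across-pair mean."""
    rs = []
    for s in child_seeds(seed, n_pairs):
        a, b, mask = synth_coloc_pair(shape=shape, rho=rho, seed=int(s))
        rs.append(pearson_coefficient(a, b, mask).pearson_r)
    return {"pearson_mean": float(np.mean(rs)), "rho": rho, "n_pixels": int(mask.n_pixels),
            "n_pairs": n_pairs}
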