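"""Spatially scaled averaging: step 2 of the motion-correction algorithm.

The observed magnitude of repetition i is modelled as a spatially varying
attenuation of a motion-free image, ``I_i(x, y) = w_i(x, y) * Ihat(x, y) + n``.
Because motion during diffusion encoding predominantly *loses* signal, the
maximum intensity projection (MIP) across repetitions approximates the
motion-free image, and the per-repetition scaling factor is estimated as
the ratio of the low-pass-filtered repetition to the filtered MIP.  The
combined image divides the repetition sum by the aggregate weight
``W = Σ_i w_i`` instead of N, undoing the attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AveragedVolume, DwiStack, standard_average
from .rejection import AlgorithmConfig, RejectionResult, reject_outliers

__all__ = [
    "WeightSet",
    "PipelineResult",
    "compute_weights",
    "scaled_average",
    "run_pipeline",
    "run_pipeline_per_direction",
]


@dataclass
class WeightSet:
    """Per-repetition weight maps and their aggregate.

    w : (z, i, y, x) float in [0, 1]; 0 exactly on rejected voxels.
    aggregate : (z, y, x) float in [0, N]; ``W = Σ_i w``.
    fallback_mask : (z, y, x) bool; voxels with ``W == 0`` where the
        scaled average is undefined.
    """

    w: np.ndarray
    aggregate: np.ndarray
    fallback_mask: np.ndarray


def compute_weights(
    filtered: DwiStack,
    rejection: RejectionResult,
    cfg: AlgorithmConfig | None = None,
) -> WeightSet:
    """Estimate per-repetition scaling factors against the MIP reference.

    At each voxel the MIP is taken over the repetitions that survived
    rejection at that voxel; surviving repetitions get
    ``w = filtered / MIP`` and rejected ones ``w = 0``.  Factors strictly
    above ``cfg.weight_clip`` are set to 1 (noise guard: near-unity
    ratios reflect noise, not motion).  Where the MIP is zero the weight
    is undefined; such voxels get ``w = 0`` and are marked for fallback.
    """
    cfg = cfg or AlgorithmConfig()
    vals = filtered.data
    keep = ~rejection.voxel_rejected
    if keep.shape != vals.shape:
        raise ValueError("rejection masks do not match the filtered stack")
    # vals >= 0, so masking rejected entries with 0 leaves the max over
    # the kept entries (or 0 when nothing usable remains).
    mip = np.where(keep, vals, 0.0).max(axis=1)
    usable = keep & (mip[:, None] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(usable, vals / np.where(mip[:, None] > 0, mip[:, None], 1.0), 0.0)
    w[w > cfg.weight_clip] = 1.0
    aggregate = w.sum(axis=1)
    return WeightSet(w=w, aggregate=aggregate, fallback_mask=aggregate == 0)


def scaled_average(
    raw: DwiStack,
    weights: WeightSet,
    rejection: RejectionResult,
) -> AveragedVolume:
    """Combine raw magnitudes into the scaled average DW image.

    Per voxel: the sum of raw magnitudes over non-rejected repetitions,
    divided by the aggregate weight W.  Where W is zero (no usable
    signal) the plain arithmetic mean over all N repetitions is used and
    the voxel is flagged in the fallback mask.
    """
    if weights.w.shape != raw.data.shape:
        raise ValueError("weight maps do not match the raw stack")
    keep = ~rejection.voxel_rejected
    numerator = (raw.data * keep).sum(axis=1)
    agg = weights.aggregate
    fallback = weights.fallback_mask
    data = np.where(fallback, raw.data.mean(axis=1), numerator / np.where(agg > 0, agg, 1.0))
    return AveragedVolume(
        data=data,
        b_value=raw.b_value,
        method="proposed",
        fallback=fallback,
        voxel_size=raw.voxel_size,
    )


@dataclass
class PipelineResult:
    """All stages of one pipeline run, kept for inspection and export."""

    proposed: AveragedVolume
    standard: AveragedVolume
    weights: WeightSet
    rejection: RejectionResult
    config: AlgorithmConfig


def run_pipeline(stack: DwiStack, cfg: AlgorithmConfig | None = None) -> PipelineResult:
    """Full deterministic two-step combination of one stack.

    Composition: repetition rejection → low-pass filtering → voxel
    rejection → weight estimation → scaled averaging.  The standard
    arithmetic average is computed alongside for comparison.
    """
    cfg = cfg or AlgorithmConfig()
    rejection, filtered = reject_outliers(stack, cfg)
    weights = compute_weights(filtered, rejection, cfg)
    proposed = scaled_average(stack, weights, rejection)
    return PipelineResult(
        proposed=proposed,
        standard=standard_average(stack),
        weights=weights,
        rejection=rejection,
        config=cfg,
    )


def run_pipeline_per_direction(
    stack: DwiStack, cfg: AlgorithmConfig | None = None
) -> tuple[AveragedVolume, dict[int, PipelineResult]]:
    """Run the pipeline independently per diffusion-encoding direction.

    For anisotropic tissue (e.g. paraspinal muscle) the directions cannot
    be pooled as extra repetitions: each direction group is processed on
    its own and the per-direction scaled averages are then averaged.
    Returns the direction-averaged volume and the per-direction results.
    """
    cfg = cfg or AlgorithmConfig()
    results: dict[int, PipelineResult] = {}
    for d in stack.direction_ids():
        results[d] = run_pipeline(stack.select_direction(d), cfg)
    combined = np.mean([r.proposed.data for r in results.values()], axis=0)
    fallback = np.any([r.proposed.fallback for r in results.values()], axis=0)
    volume = AveragedVolume(
        data=combined,
        b_value=stack.b_value,
        method="proposed",
        fallback=fallback,
        voxel_size=stack.voxel_size,
    )
    return volume, results
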