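"""Outlier rejection: step 1 of the motion-correction algorithm.

Two sequential rejection stages, both driven by robust statistics
(median and raw median absolute deviation) of the repetitions of a slice:

1. *Repetition rejection* discards whole repetitions whose slice-wise
   intensity sum ζ falls more than ``lambda_rep`` MADs below the median ζ
   of that slice — these carry global, near-total signal loss.
2. *Voxel rejection* works on low-pass-filtered repetitions (motion
   dropout affects patches, not isolated voxels) and discards, per voxel,
   repetitions whose filtered magnitude falls more than ``lambda_vxl``
   MADs below the across-repetition median at that voxel.  The resulting
   threshold map is spatially dependent.

The MAD here is deliberately unscaled (no 1.4826 normal-consistency
factor); the thresholds are calibrated against the raw statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DwiStack

__all__ = [
    "AlgorithmConfig",
    "RejectionResult",
    "mad",
    "slice_sums",
    "reject_repetitions",
    "lowpass",
    "reject_voxels",
    "reject_outliers",
]


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the two-step algorithm.

    lambda_rep : float
        Repetition-rejection threshold distance in MADs below the median
        slice sum (default 5, a conservative choice that only removes
        near-total global dropout).
    lambda_vxl : float
        Voxel-rejection threshold distance in MADs (default 3).
    lowpass_sigma : float
        Isotropic in-plane Gaussian smoothing, in voxels, applied before
        voxel rejection and weight computation (default 2.0).  0 disables
        filtering.
    weight_clip : float
        Scaling factors strictly greater than this value are set to 1 to
        avoid noise-driven overestimation of the combined image
        (default 0.8).
    """

    lambda_rep: float = 5.0
    lambda_vxl: float = 3.0
    lowpass_sigma: float = 2.0
    weight_clip: float = 0.8

    def __post_init__(self) -> None:
        if self.lambda_rep <= 0:
            raise ValueError("lambda_rep must be > 0")
        if self.lambda_vxl <= 0:
            raise ValueError("lambda_vxl must be > 0")
        if self.lowpass_sigma < 0:
            raise ValueError("lowpass_sigma must be >= 0")
        if not 0 < self.weight_clip <= 1:
            raise ValueError("weight_clip must be in (0, 1]")


@dataclass
class RejectionResult:
    """Outcome of both rejection stages for one stack.

    rep_rejected : (z, i) bool — repetition globally rejected on slice z.
    voxel_rejected : (z, i, y, x) bool — per-voxel rejection; true for
        every voxel of a globally rejected repetition.
    zeta : (z, i) float — slice intensity sums.
    rep_threshold : (z,) float — repetition-rejection threshold per slice.
    voxel_threshold : (z, y, x) float — spatially dependent voxel
        threshold map.
    """

    rep_rejected: np.ndarray
    voxel_rejected: np.ndarray
    zeta: np.ndarray
    rep_threshold: np.ndarray
    voxel_threshold: np.ndarray

    def rejected_counts(self) -> np.ndarray:
        """Number of globally rejected repetitions per slice."""
        return self.rep_rejected.sum(axis=1)

    def voxel_rejected_fraction(self) -> np.ndarray:
        """Fraction of voxel-level rejections per slice, over all (i, y, x)."""
        return self.voxel_rejected.mean(axis=(1, 2, 3))


def mad(values) -> float:
    """Raw median absolute deviation: median of |x - median(x)|.

    No consistency scaling is applied.  Even-length medians are the mean
    of the two central order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty set is undefined")
    return float(np.median(np.abs(values - np.median(values))))


def slice_sums(stack: DwiStack) -> np.ndarray:
    """ζ matrix: sum of all voxel magnitudes per (slice, repetition)."""
    return stack.data.sum(axis=(2, 3))


def reject_repetitions(
    stack: DwiStack, cfg: AlgorithmConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag globally corrupted repetitions per slice.

    Repetition i of slice z is rejected iff
    ``zeta[z, i] < median_i(zeta[z]) - lambda_rep * mad_i(zeta[z])``
    (strict inequality; a value exactly at threshold is kept).

    Returns ``(rep_rejected, rep_threshold, zeta)``.  Because the
    threshold sits below the median for any positive ``lambda_rep``, at
    most ⌊N/2⌋ repetitions of a slice can be rejected.
    """
    cfg = cfg or AlgorithmConfig()
    zeta = slice_sums(stack)
    med = np.median(zeta, axis=1)
    mad_z = np.median(np.abs(zeta - med[:, None]), axis=1)
    threshold = med - cfg.lambda_rep * mad_z
    rejected = zeta < threshold[:, None]
    return rejected, threshold, zeta


def lowpass(stack: DwiStack, sigma: float) -> DwiStack:
    """In-plane 2D Gaussian smoothing of every repetition of every slice.

    ``sigma`` is in voxels; 0 returns the stack unchanged.  Mirror
    boundary handling preserves flat regions up to the image edge.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return stack
    filtered = ndimage.gaussian_filter(
        stack.data, sigma=(0, 0, sigma, sigma), mode="mirror"
    )
    # Gaussian smoothing of non-negative data is non-negative; guard the
    # occasional -1e-17 from floating-point round-off.
    np.maximum(filtered, 0.0, out=filtered)
    return stack.with_data(filtered)


def reject_voxels(
    filtered: DwiStack,
    rep_rejected: np.ndarray,
    cfg: AlgorithmConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag locally corrupted voxels on the low-pass-filtered stack.

    Statistics (median, MAD across repetitions) are formed at each voxel
    from the repetitions that survived the global rejection, so a dead
    repetition cannot drag the local median down.  A surviving
    repetition's voxel is rejected iff its filtered magnitude is strictly
    below ``median - lambda_vxl * MAD``.  All voxels of globally rejected
    repetitions are flagged wholesale.

    Returns ``(voxel_rejected, voxel_threshold)`` with shapes
    ``(z, i, y, x)`` and ``(z, y, x)``.
    """
    cfg = cfg or AlgorithmConfig()
    rep_rejected = np.asarray(rep_rejected, dtype=bool)
    if rep_rejected.shape != filtered.data.shape[:2]:
        raise ValueError("rep_rejected shape must be (n_slices, n_reps)")
    n_z, n_i, n_y, n_x = filtered.data.shape
    voxel_rejected = np.zeros((n_z, n_i, n_y, n_x), dtype=bool)
    threshold = np.full((n_z, n_y, n_x), np.nan)
    for z in range(n_z):
        keep = ~rep_rejected[z]
        if not keep.any():  # cannot occur for lambda_rep > 0
            voxel_rejected[z] = True
            continue
        vals = filtered.data[z, keep]
        med = np.median(vals, axis=0)
        mad_v = np.median(np.abs(vals - med), axis=0)
        t = med - cfg.lambda_vxl * mad_v
        threshold[z] = t
        voxel_rejected[z, keep] = vals < t
        voxel_rejected[z, ~keep] = True
    return voxel_rejected, threshold


def reject_outliers(
    stack: DwiStack, cfg: AlgorithmConfig | None = None
) -> tuple[RejectionResult, DwiStack]:
    """Run both rejection stages; returns the result and the filtered stack.

    The filtered stack is returned because the downstream weight
    computation reuses exactly the same low-pass-filtered images.
    """
    cfg = cfg or AlgorithmConfig()
    rep_rejected, rep_threshold, zeta = reject_repetitions(stack, cfg)
    filtered = lowpass(stack, cfg.lowpass_sigma)
    voxel_rejected, voxel_threshold = reject_voxels(filtered, rep_rejected, cfg)
    result = RejectionResult(
        rep_rejected=rep_rejected,
        voxel_rejected=voxel_rejected,
        zeta=zeta,
        rep_threshold=rep_threshold,
        voxel_threshold=voxel_threshold,
    )
    return result, filtered
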