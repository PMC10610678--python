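"""ADC quantification and ROI-level evaluation statistics.

The apparent diffusion coefficient is obtained from a mono-exponential
signal model, ``S(b) = S0 · exp(-b · ADC)``, fitted voxel-wise by
log-linear least squares over the supplied b-values (by convention the
b=0 image is excluded to avoid perfusion contamination).  ROI statistics,
the left/right liver-lobe ADC ratio (ALR), paired t-tests and left-right
regression mirror the standard evaluation of liver DWI post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AveragedVolume

__all__ = [
    "AdcVolume",
    "RoiReport",
    "HEALTHY_LIVER_ADC_RANGE",
    "fit_adc",
    "roi_stats",
    "alr",
    "paired_ttest",
    "line_fit",
    "evaluate",
]

#: Literature range of healthy liver-parenchyma ADC, mm²/s, used to
#: annotate reports.
HEALTHY_LIVER_ADC_RANGE: tuple[float, float] = (0.9e-3, 1.6e-3)


@dataclass
class AdcVolume:
    """Voxel-wise ADC map in mm²/s with fitted intercept and validity mask.

    Voxels with any non-positive input signal, or where the fit returns a
    negative diffusivity, are invalid and carry NaN.
    """

    adc: np.ndarray
    s0: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.adc.shape == self.s0.shape == self.valid.shape):
            raise ValueError("adc, s0 and valid must share a shape")


def fit_adc(
    volumes: Sequence[AveragedVolume | np.ndarray],
    b_values: Sequence[float] | None = None,
) -> AdcVolume:
    """Log-linear least-squares mono-exponential fit across b-values.

    Parameters
    ----------
    volumes:
        Combined DW images (one per b-value), co-registered by
        construction; arrays or :class:`AveragedVolume`.
    b_values:
        Diffusion weightings in s/mm²; taken from the volumes when omitted.

    Per voxel the model ``ln S(b) = ln S0 - b·ADC`` is solved in closed
    form.  Any voxel with a non-positive signal at some b-value, or with
    a negative fitted ADC, is marked invalid (NaN).
    """
    if b_values is None:
        b_values = [v.b_value for v in volumes]  # type: ignore[union-attr]
    b = np.asarray(b_values, dtype=float)
    if len(np.unique(b)) < 2:
        raise ValueError("ADC fitting needs at least 2 distinct b-values")
    if len(volumes) != b.size:
        raise ValueError("one volume per b-value required")
    arrays = [v.data if isinstance(v, AveragedVolume) else np.asarray(v, float) for v in volumes]
    signal = np.stack(arrays, axis=0)  # (n_b, z, y, x)

    valid = np.all(signal > 0, axis=0) & np.all(np.isfinite(signal), axis=0)
    safe = np.where(signal > 0, signal, 1.0)
    log_s = np.log(safe)
    b_mean = b.mean()
    b_c = b - b_mean
    denom = float((b_c**2).sum())
    slope = np.tensordot(b_c, log_s, axes=(0, 0)) / denom
    adc = -slope
    s0 = np.exp(log_s.mean(axis=0) + adc * b_mean)

    valid &= np.isfinite(adc) & (adc >= 0)
    adc = np.where(valid, adc, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return AdcVolume(adc=adc, s0=s0, valid=valid)


def roi_stats(adc: AdcVolume, rois: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Mean and sample standard deviation of ADC per ROI over valid voxels.

    Raises if an ROI is empty or contains no valid voxel, naming the ROI.
    """
    rows = {}
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != adc.adc.shape:
            raise ValueError(f"ROI {name!r} shape does not match the ADC volume")
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty")
        sel = mask & adc.valid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"ROI {name!r} contains no valid voxels")
        vals = adc.adc[sel]
        rows[name] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)) if n > 1 else 0.0,
            "n_valid": n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def alr(
    adc: AdcVolume,
    left_rois: Mapping[str, np.ndarray],
    right_rois: Mapping[str, np.ndarray],
    mode: str = "segment_mean",
) -> float:
    """ADC liver-lobe ratio: left-lobe mean over right-lobe mean.

    ``mode="segment_mean"`` averages the per-ROI means of each side
    (every segment counts equally); ``mode="pooled"`` pools all voxels of
    a side before averaging.
    """
    if mode not in ("segment_mean", "pooled"):
        raise ValueError(f"unknown ALR mode {mode!r}")
    if not left_rois or not right_rois:
        raise ValueError("both ROI sides must be non-empty")

    def side_mean(rois: Mapping[str, np.ndarray]) -> float:
        if mode == "segment_mean":
            return float(roi_stats(adc, rois)["mean"].mean())
        pooled = np.zeros_like(adc.valid)
        for mask in rois.values():
            pooled |= np.asarray(mask, dtype=bool)
        return float(roi_stats(adc, {"pooled": pooled}).loc["pooled", "mean"])

    right = side_mean(right_rois)
    if right == 0:
        raise ValueError("right-side mean ADC is zero; ALR undefined")
    return side_mean(left_rois) / right


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p).

    Identical samples (all differences zero) are reported as t=0, p=1
    rather than the 0/0 indeterminate form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired observations")
    if np.allclose(a - b, 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def line_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares line y = a·x + b with Pearson r; returns (a, b, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points for a line fit")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass
class RoiReport:
    """Side-by-side ROI evaluation of the two averaging methods."""

    per_roi: pd.DataFrame
    alr_standard: float
    alr_proposed: float
    ttest_t: float
    ttest_p: float
    n_pairs: int
    left_right_fit: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    healthy_range: tuple[float, float] = HEALTHY_LIVER_ADC_RANGE

    def to_dict(self) -> dict:
        return {
            "per_roi": {
                method: self.per_roi.xs(method, level="method").to_dict(orient="index")
                for method in ("standard", "proposed")
            },
            "alr": {"standard": self.alr_standard, "proposed": self.alr_proposed},
            "paired_ttest": {"t": self.ttest_t, "p": self.ttest_p, "n": self.n_pairs},
            "left_right_fit": {
                m: {"slope": f[0], "intercept": f[1], "pearson_r": f[2]}
                for m, f in self.left_right_fit.items()
            },
            "healthy_liver_adc_range_mm2_per_s": list(self.healthy_range),
        }


def evaluate(
    adc_standard: AdcVolume,
    adc_proposed: AdcVolume,
    left_rois: Mapping[str, np.ndarray],
    right_rois: Mapping[str, np.ndarray],
) -> RoiReport:
    """Paired comparison of the two methods over a common ROI set.

    Computes per-ROI mean/std for both methods, a two-sided paired t-test
    on the per-ROI means, the ALR of each method, and — treating each
    slice as an independent pairing of left and right means — a
    least-squares left-vs-right line fit with Pearson r per method.
    """
    rois = {**left_rois, **right_rois}
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs for a paired evaluation")
    frames = []
    for method, vol in (("standard", adc_standard), ("proposed", adc_proposed)):
        df = roi_stats(vol, rois)
        df.index = pd.MultiIndex.from_product([[method], df.index], names=["method", "roi"])
        frames.append(df)
    per_roi = pd.concat(frames)

    means_std = per_roi.xs("standard", level="method")["mean"].reindex(rois.keys())
    means_prop = per_roi.xs("proposed", level="method")["mean"].reindex(rois.keys())
    t, p = paired_ttest(means_std.to_numpy(), means_prop.to_numpy())

    def _lobe_union(side: Mapping[str, np.ndarray]) -> np.ndarray:
        out = np.zeros_like(adc_standard.valid)
        for mask in side.values():
            out |= np.asarray(mask, dtype=bool)
        return out

    left_mask, right_mask = _lobe_union(left_rois), _lobe_union(right_rois)
    fits: dict[str, tuple[float, float, float]] = {}
    for method, vol in (("standard", adc_standard), ("proposed", adc_proposed)):
        lefts, rights = [], []
        for z in range(vol.adc.shape[0]):
            lsel = left_mask[z] & vol.valid[z]
            rsel = right_mask[z] & vol.valid[z]
            if lsel.any() and rsel.any():
                lefts.append(vol.adc[z][lsel].mean())
                rights.append(vol.adc[z][rsel].mean())
        if len(lefts) >= 2 and np.ptp(rights) > 0:
            fits[method] = line_fit(rights, lefts)

    return RoiReport(
        per_roi=per_roi,
        alr_standard=alr(adc_standard, left_rois, right_rois),
        alr_proposed=alr(adc_proposed, left_rois, right_rois),
        ttest_t=t,
        ttest_p=p,
        n_pairs=len(rois),
        left_right_fit=fits,
    )
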