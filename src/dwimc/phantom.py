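"""Synthetic motion-corrupted liver DWI phantom with known ground truth.

Simulates the multiplicative signal-loss model that the correction
algorithm assumes: every observed repetition is a spatially varying
attenuation ``w_i(x, y) ∈ [0, 1]`` of a motion-free image, plus magnitude
(Rician) noise.  The phantom geometry is a deliberately simple abdominal
cartoon — two elliptical liver lobes and two paraspinal-muscle discs on
an empty background — acquired with the clinical multi-b protocol
(b = 0/50/300/600 s/mm² with 2/1/2/6 repetitions and 3 encoding
directions for b > 0, so up to 18 effective repetitions after pooling).

Two dropout mechanisms emulate the clinical phenomenology:

* *global dropout*: with small probability the entire liver of a
  repetition collapses to a few percent of its magnitude (the kind of
  repetition the slice-level rejection must catch).  Static structures —
  paraspinal muscle, background — keep their signal: intravoxel
  dephasing requires tissue motion, which is why muscle serves as the
  motion-free control region;
* *patch dropout*: with larger probability a smooth, compact patch
  centred at a random location inside the left liver lobe is attenuated
  (cardiac-pulsation-like local loss).  Patch shapes are clipped,
  peak-normalised smoothed Gaussian random fields under a Gaussian
  envelope, truncated at 2% of peak so each patch has compact support.

Motion events (cardiac systole during encoding) occur at a rate that does
not depend on b, but the intravoxel dephasing they cause grows with the
diffusion gradient area: dropout *depth* therefore scales linearly with
b/b_max while the event probabilities stay fixed (and no dropout occurs
at b = 0, where no diffusion gradients are played).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import AveragedVolume, DwiStack

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "score_recovery",
    "no_dropout_spec",
]

REGION_NAMES = {0: "background", 1: "right_lobe", 2: "left_lobe", 3: "muscle"}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of the simulated acquisition.

    Signal levels are in arbitrary magnitude units; ADCs in mm²/s; all
    spatial scales in voxels.  ``noise_sigma`` is the per-channel
    standard deviation of the complex Gaussian noise whose modulus forms
    the magnitude (Rician) noise; the default corresponds to a b=0
    liver SNR of 25.
    """

    shape: tuple[int, int, int] = (5, 96, 96)  # (slices, rows, cols)
    b_values: tuple[float, ...] = (0.0, 50.0, 300.0, 600.0)
    reps_per_b: tuple[int, ...] = (2, 1, 2, 6)
    n_directions: int = 3  # for b > 0; b = 0 has a single direction
    s0_liver: float = 1000.0
    s0_muscle: float = 800.0
    adc_liver: float = 1.2e-3
    adc_muscle: float = 1.5e-3
    p_global: float = 0.05
    global_weight: float = 0.05
    p_patch: float = 0.4
    patch_weight_range: tuple[float, float] = (0.3, 0.7)
    patch_radius_range: tuple[float, float] = (8.0, 16.0)
    dropout_smoothness: float = 8.0
    b_scaled_dropout: bool = True
    noise_sigma: float = 40.0
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.b_values) != len(self.reps_per_b):
            raise ValueError("one repetition count per b-value required")
        if any(n < 1 for n in self.reps_per_b) or self.n_directions < 1:
            raise ValueError("repetition and direction counts must be >= 1")
        for p in (self.p_global, self.p_patch):
            if not 0 <= p <= 1:
                raise ValueError("dropout probabilities must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def n_effective_reps(self, b: float) -> int:
        i = self.b_values.index(b)
        return self.reps_per_b[i] * (self.n_directions if b > 0 else 1)


@dataclass
class PhantomTruth:
    """Ground truth of a simulated acquisition.

    ihat : per b-value, the motion-free magnitude (z, y, x).
    true_weights : per b-value, the imposed attenuation fields (z, i, y, x).
    true_adc : (z, y, x) ADC map in mm²/s (NaN on background).
    labels : (z, y, x) integer region labels (see ``label_names``).
    """

    ihat: dict[float, np.ndarray]
    true_weights: dict[float, np.ndarray]
    true_adc: np.ndarray
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))
    noise_sigma: float = 0.0

    def region_mask(self, region: str) -> np.ndarray:
        for code, name in self.label_names.items():
            if name == region:
                return self.labels == code
        raise ValueError(f"unknown region {region!r}")

    def region_rois(self, erode: int = 0) -> dict[str, np.ndarray]:
        """Boolean mask per named tissue region, optionally eroded in-plane.

        Erosion keeps ROI statistics away from partial-volume edges, the
        way circular ROIs are placed inside segments in practice.
        """
        rois = {}
        for code, name in self.label_names.items():
            if name == "background":
                continue
            mask = self.labels == code
            if erode > 0:
                structure = np.ones((1, 2 * erode + 1, 2 * erode + 1), dtype=bool)
                mask = ndimage.binary_erosion(mask, structure=structure)
            rois[name] = mask
        return rois


def _geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Region labels, S0 map and ADC map on one slice plane."""
    _, ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    labels = np.zeros((ny, nx), dtype=np.int16)
    labels[ellipse(0.48 * ny, 0.31 * nx, 0.27 * ny, 0.21 * nx)] = 1  # right lobe
    labels[ellipse(0.42 * ny, 0.67 * nx, 0.15 * ny, 0.125 * nx)] = 2  # left lobe
    labels[ellipse(0.85 * ny, 0.40 * nx, 0.065 * ny, 0.065 * nx)] = 3  # muscle L
    labels[ellipse(0.85 * ny, 0.60 * nx, 0.065 * ny, 0.065 * nx)] = 3  # muscle R

    s0 = np.zeros((ny, nx))
    s0[(labels == 1) | (labels == 2)] = spec.s0_liver
    s0[labels == 3] = spec.s0_muscle
    adc = np.full((ny, nx), np.nan)
    adc[(labels == 1) | (labels == 2)] = spec.adc_liver
    adc[labels == 3] = spec.adc_muscle
    return labels, s0, adc


def _patch_field(
    rng: np.random.Generator,
    spec: PhantomSpec,
    lobe_idx: tuple[np.ndarray, np.ndarray],
    liver: np.ndarray,
    depth_scale: float,
) -> np.ndarray:
    """One smooth, compact attenuation field with its core in the left lobe.

    Returns a weight field in [min_weight, 1]: a clipped smoothed Gaussian
    random field shaped by a Gaussian envelope around a random left-lobe
    centre, renormalised to peak 1 and truncated below 2% of peak.
    """
    _, ny, nx = spec.shape
    k = rng.integers(len(lobe_idx[0]))
    cy, cx = float(lobe_idx[0][k]), float(lobe_idx[1][k])
    radius = rng.uniform(*spec.patch_radius_range)
    min_weight = rng.uniform(*spec.patch_weight_range)

    g = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), spec.dropout_smoothness)
    g = np.clip(g, 0.0, None)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    envelope = np.exp(-4.0 * (((yy - cy) ** 2 + (xx - cx) ** 2) / radius**2))
    shape = g * envelope
    peak = shape.max()
    if peak <= 0:  # degenerate GRF draw; fall back to the bare envelope
        shape = envelope
        peak = shape.max()
    shape = shape / peak
    shape[shape < 0.02] = 0.0
    # Attenuation only affects moving tissue; static structures keep
    # their signal even under the patch footprint.  The dephasing depth
    # grows with the diffusion weighting (depth_scale = b / b_max).
    return 1.0 - (1.0 - min_weight) * depth_scale * shape * liver


def make_phantom(
    spec: PhantomSpec | None = None, seed: int | None = None
) -> tuple[dict[float, DwiStack], PhantomTruth]:
    """Simulate one acquisition; returns per-b-value stacks and the truth.

    Deterministic for a fixed ``seed`` (falls back to ``spec.seed``).
    Dropout fields are sampled independently per b-value, repetition and
    slice; magnitude noise is the modulus of complex Gaussian noise.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_z, ny, nx = spec.shape
    plane_labels, s0, adc_plane = _geometry(spec)
    labels = np.broadcast_to(plane_labels, (n_z, ny, nx)).copy()
    true_adc = np.broadcast_to(adc_plane, (n_z, ny, nx)).copy()
    lobe_idx = np.nonzero(plane_labels == 2)
    liver = (plane_labels == 1) | (plane_labels == 2)
    # Residual weight field of a liver-wide ("global") dropout event:
    # moving tissue is attenuated, static tissue keeps its signal.
    global_field = np.where(liver, spec.global_weight, 1.0)

    b_max = max(spec.b_values)
    stacks: dict[float, DwiStack] = {}
    ihat: dict[float, np.ndarray] = {}
    true_weights: dict[float, np.ndarray] = {}
    for b, n_rep in zip(spec.b_values, spec.reps_per_b):
        decay = np.where(np.isnan(adc_plane), 1.0, np.exp(-b * np.nan_to_num(adc_plane)))
        plane = s0 * decay
        ihat_b = np.broadcast_to(plane, (n_z, ny, nx)).copy()

        n_dir = spec.n_directions if b > 0 else 1
        n_eff = n_rep * n_dir
        scale = (b / b_max) if (spec.b_scaled_dropout and b_max > 0) else 1.0
        global_field_b = 1.0 - (1.0 - global_field) * scale

        w = np.ones((n_z, n_eff, ny, nx))
        for i in range(n_eff):
            for z in range(n_z):
                if b > 0 and rng.random() < spec.p_global:
                    w[z, i] *= global_field_b
                if b > 0 and rng.random() < spec.p_patch:
                    w[z, i] *= _patch_field(rng, spec, lobe_idx, liver, scale)

        clean = w * ihat_b[:, None]
        if spec.noise_sigma > 0:
            n1 = rng.normal(0.0, spec.noise_sigma, clean.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, clean.shape)
            data = np.sqrt((clean + n1) ** 2 + n2**2)
        else:
            data = clean

        rep_labels = [(d, r) for d in range(n_dir) for r in range(n_rep)]
        stacks[b] = DwiStack(
            data=data, b_value=b, rep_labels=rep_labels, voxel_size=spec.voxel_size
        )
        ihat[b] = ihat_b
        true_weights[b] = w

    truth = PhantomTruth(
        ihat=ihat,
        true_weights=true_weights,
        true_adc=true_adc,
        labels=labels,
        noise_sigma=spec.noise_sigma,
    )
    return stacks, truth


def score_recovery(
    output: AveragedVolume, truth: PhantomTruth, region: str
) -> dict[str, float]:
    """Region-restricted RMSE and bias of a combined image against truth.

    Compares ``output`` with the motion-free image at the matching
    b-value; ``region`` is one of the named tissue regions.
    """
    if output.b_value not in truth.ihat:
        raise ValueError(f"no truth stored for b={output.b_value}")
    mask = truth.region_mask(region)
    diff = output.data[mask] - truth.ihat[output.b_value][mask]
    return {
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "bias": float(np.mean(diff)),
        "n": int(mask.sum()),
    }


def no_dropout_spec(**overrides) -> PhantomSpec:
    """Convenience spec with dropout and noise switched off."""
    base = dict(p_global=0.0, p_patch=0.0, noise_sigma=0.0)
    base.update(overrides)
    return replace(PhantomSpec(), **base)
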