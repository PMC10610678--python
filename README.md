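# dwimc — motion-artifact reduction for multi-repetition liver DWI

Respiratory-triggered diffusion-weighted MRI (DWI) of the liver acquires
many repetitions of every slice and b-value and averages them for SNR.
Cardiac motion during diffusion encoding causes intravoxel dephasing and
unpredictable, non-diffusion signal loss — worst in the left liver lobe —
so the plain magnitude average is biased low and the apparent diffusion
coefficient (ADC) fitted from it is biased high. Radiologists often have
to disregard the left lobe entirely.

`dwimc` implements a retrospective, data-driven correction for this
signal loss, plus the ADC quantification and evaluation statistics
around it, and a synthetic motion-corrupted phantom so the whole chain
can be validated against a known ground truth. It is aimed at MRI
physicists and image-analysis researchers working on quantitative body
DWI.

## The model and the algorithm

Each acquired magnitude repetition *i* of slice *z* is modelled as an
attenuated view of a motion-free image Î:

    I_{z,i}(x,y) = w_{z,i}(x,y) · Î_z(x,y) + n_z(x,y),   0 ≤ w ≤ 1

Standard averaging computes μ = (1/N) Σᵢ I_{z,i}, which underestimates Î
whenever Σᵢ w_{z,i} < N. The correction works in two steps, per slice
and b-value (diffusion directions are pooled as extra repetitions under
the isotropic-liver assumption):

1. **Outlier rejection.**
   *Repetition level*: repetition *i* is discarded when its intensity
   sum ζ_{z,i} falls below med(ζ_z) − λ⁽ʳᵉᵖ⁾·mad(ζ_z), with λ⁽ʳᵉᵖ⁾ = 5
   and the MAD taken raw (no consistency factor). *Voxel level*: after
   in-plane Gaussian low-pass filtering (σ = 2 voxels; motion dropout is
   patch-like), a voxel of repetition *i* is discarded when its filtered
   magnitude falls below med − λ⁽ᵛˣˡ⁾·mad across the surviving
   repetitions, with λ⁽ᵛˣˡ⁾ = 3. Both thresholds sit below the median,
   so at most ⌊N/2⌋ repetitions of a slice can ever be rejected.
2. **Spatially scaled averaging.** Because motion predominantly *loses*
   signal, the maximum intensity projection (MIP) over the surviving
   filtered repetitions approximates Î. Weights are estimated as
   w = I_lr / MIP (0 on rejected voxels; values above 0.8 snapped to 1
   as a noise guard) and the combined image is

       DWI_z(x,y) = Σᵢ I_{z,i}(x,y) / W_z(x,y),   W_z = Σᵢ w_{z,i}

   with the numerator restricted to surviving voxels. Where W = 0 the
   voxel falls back to the plain mean and is flagged.

ADC maps are fitted voxel-wise by log-linear least squares of the
mono-exponential model S(b) = S₀·exp(−b·ADC) over the diffusion-weighted
b-values (b = 50/300/600 s/mm² under the default protocol; b = 0 is
excluded). ROI statistics include the ADC liver-lobe ratio
ALR = mean ADC(left lobe) / mean ADC(right lobe), paired t-tests,
left-vs-right regression with Pearson r, and annotation against the
healthy-parenchyma range (0.9–1.6)×10⁻³ mm²/s.

## Worked example

Simulate one motion-corrupted acquisition (five 96×96 slices, the
default 0/50/300/600 s/mm² protocol with up to 18 effective repetitions,
left-lobe patch dropout, liver SNR 25), run both averaging methods, fit
ADC maps, and compare against the known truth:

```python
from dwimc import phantom_study

result = phantom_study(seed=42)
m = result.metrics
print(f"true liver ADC        : {m['adc_true_liver']*1e3:.2f} x 10^-3 mm^2/s")
print(f"left lobe  (standard) : {m['adc_left_lobe_standard']*1e3:.2f}")
print(f"left lobe  (proposed) : {m['adc_left_lobe_proposed']*1e3:.2f}")
print(f"ALR standard/proposed : {m['alr_standard']:.3f} / {m['alr_proposed']:.3f}")
print(f"muscle change         : {m['muscle_rel_change']*100:.2f} %")
print(f"left-lobe RMSE b600   : {m['rmse_left_b_top_standard']:.1f} -> {m['rmse_left_b_top_proposed']:.1f}")
```

prints

```
true liver ADC        : 1.20 x 10^-3 mm^2/s
left lobe  (standard) : 1.32
left lobe  (proposed) : 1.19
ALR standard/proposed : 1.027 / 0.997
muscle change         : 0.10 %
left-lobe RMSE b600   : 36.8 -> 10.6
```

Standard averaging overestimates the left-lobe ADC by ~10% and leaves
the lobes unbalanced (ALR > 1); the scaled average recovers the true
ADC to within half a percent, equalises the lobes, and cuts the
left-lobe image error at b = 600 s/mm² by ~3.5×. The motion-free muscle
region is essentially untouched (0.1% change) — the correction does not
introduce bias where there is no artifact.

The same chain is available from the shell:

```sh
dwimc simulate --out sim --seed 42
dwimc run --in sim/dwi.nii.gz --out out --save-intermediates
dwimc report --adc-standard out/adc_standard.nii.gz \
             --adc-proposed out/adc_proposed.nii.gz \
             --labels sim/truth/labels.nii.gz \
             --label-map sim/truth/labels.json --out report
```

`run` writes combined DW images, ADC maps, weight maps and rejection
masks as NIfTI plus a JSON manifest with the per-slice rejection
summary; `report` writes the ROI evaluation as CSV + JSON.

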