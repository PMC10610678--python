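# Methods

## Signal model and scope

The package treats motion corruption in multi-repetition magnitude DWI
as multiplicative, spatially varying attenuation: repetition *i* of
slice *z* observes `I_{z,i} = w_{z,i} · Î_z + n_z` with weights
`w ∈ [0, 1]`, a repetition-independent motion-free image `Î_z`, and a
noise term. Everything else that can differ between repetitions —
misregistration, phase variation, eddy-current or EPI distortion — is
outside the model and outside the package's scope; if such effects are
present they must be corrected before this algorithm is applied.

## The two-step correction

**Repetition rejection.** For each slice, the intensity sum
`ζ_{z,i} = Σ_{x,y} I_{z,i}(x,y)` over the full field of view (no body
mask) is thresholded at `med(ζ_z) − λ_rep · mad(ζ_z)`. The MAD is raw
(median of absolute deviations, no 1.4826 normal-consistency factor);
the thresholds are calibrated against this raw statistic. Even-length
medians are the mean of the two central order statistics; the
comparison is strict (`<`), so a value exactly at threshold is kept and
a constant ζ-vector (MAD = 0) rejects nothing. Since the threshold lies
below the median whenever `λ_rep > 0`, at most `⌊N/2⌋` repetitions per
slice can be rejected. Default `λ_rep = 5`, a deliberately conservative
setting that only removes near-total global dropout: under-rejection
can be compensated by the scaling step, over-rejection cannot.

**Voxel rejection.** Local dropout affects patches, not single voxels,
so rejection operates on low-pass-filtered repetitions: an isotropic
2D Gaussian, `σ = 2` voxels, mirror boundary (the filter type and
boundary handling are implementation choices; a smooth patch-scale
kernel is what matters). Per voxel, the across-repetition median and
raw MAD are computed **excluding repetitions already rejected at slice
level** — otherwise a dead repetition would drag the local median
down — and repetition *i*'s voxel is rejected when its filtered value
falls below `med − λ_vxl · mad` (default `λ_vxl = 3`). All voxels of a
slice-rejected repetition are flagged wholesale.

On pure noise (no dropout), this rule rejects a small fraction of
entries by construction: Monte Carlo with Gaussian fluctuation gives
≈3.5% at N = 18 and ≈4.9% at N = 6 (the asymptotic normal rate is
`P(Z < −3·0.6745) ≈ 2.2%`; small samples inflate it). The resulting
bias on the combined image is negligible at the SNR of filtered data,
but the rate is worth knowing when interpreting rejection-fraction
logs.

**Weights and scaled averaging.** The maximum intensity projection
(MIP) across the surviving filtered repetitions serves as the
motion-free reference; the MIP is taken over non-rejected entries only,
which keeps the `W = 0` bookkeeping consistent (for non-negative data
the max over survivors is what the reference means anyway). Weights are
`w = I_lr / MIP` for surviving entries and 0 for rejected ones; weights
strictly above 0.8 are set to 1 (a value of exactly 0.8 is kept). The
clip is applied per entry *before* summation into `W = Σ_i w_i`, the
only ordering under which `W ∈ [0, N]`. The combined image divides the
raw-magnitude sum over surviving entries by `W`; weights are estimated
on filtered data but applied to raw magnitudes. Where `W = 0` — every
repetition rejected at that voxel, or all surviving values zero — the
method cannot do better than standard averaging: the voxel reverts to
the plain mean over all N repetitions and is flagged in the fallback
mask.

Two consequences worth stating: the scaled average never falls below
the arithmetic mean of the surviving repetitions (all `w ≤ 1`), and the
whole pipeline is equivariant under a common positive rescaling and
invariant under permutation of the repetition axis. No processing stage
consumes randomness; only the simulator is seeded.

**Per-direction mode.** Pooling diffusion directions as extra
repetitions assumes isotropic diffusion, valid for liver parenchyma but
not for skeletal muscle. `run_pipeline_per_direction` (CLI
`--per-direction`) processes each encoding direction as its own
repetition set and averages the per-direction outputs.

## ADC quantification

Voxel-wise log-linear least squares of `ln S(b) = ln S₀ − b·ADC`,
unweighted, closed form — deterministic and exact on noiseless
mono-exponential input, adequate at the SNR of averaged images.
By default b = 0 is excluded (perfusion contamination); the default
protocol fits b = 50/300/600 s/mm². Voxels with a non-positive signal
at any fitted b-value, or with a negative fitted diffusivity, are
marked invalid and carry NaN. ROI statistics use the sample (n−1)
standard deviation and only valid voxels. The ADC liver-lobe ratio
(ALR) divides the left-lobe mean by the right-lobe mean; with several
ROIs per side it averages segment means by default (each segment counts
equally), with voxel pooling as an alternative mode. Couinaud
segmentation is an *input* (an integer label volume), never computed:
left = {I, II, III, IVa, IVb}, right = {V, VI, VII, VIII}.

## The synthetic phantom

The generator exists to make every stage and the end-to-end bias claims
testable without clinical data. It emulates the clinical acquisition:
b = 0/50/300/600 s/mm² with 2/1/2/6 repetitions and 3 encoding
directions for b > 0 (18 effective repetitions at b = 600), five 96×96
slices of 3×3×4 mm voxels. Geometry is a deliberate cartoon — a large
right-lobe ellipse, a smaller left-lobe ellipse, two paraspinal-muscle
discs, empty background — with S₀ = 1000 (liver) / 800 (muscle)
arbitrary units and true ADC 1.2×10⁻³ (liver) / 1.5×10⁻³ mm²/s
(muscle).

Dropout follows the multiplicative model exactly, with two mechanisms:

* **Global events** (probability 0.05 per repetition and slice):
  the liver signal of that repetition collapses to a residual weight of
  0.05. Attenuation is confined to moving tissue — static structures
  (muscle, background) keep their signal, which is exactly why the
  paraspinal muscle works as a motion-free control region.
* **Patch events** (probability 0.4): a smooth compact patch centred at
  a random left-lobe voxel, built as a clipped, peak-normalised
  smoothed Gaussian random field (smoothness 8 voxels) under a Gaussian
  envelope of random radius 8–16 voxels, truncated below 2% of peak so
  the patch has compact support. The core residual weight is drawn
  uniformly from 0.3–0.7.

Motion events occur at a b-independent rate, but the dephasing they
cause grows with the diffusion gradient area: dropout *depth* scales
linearly with b/b_max (full depth at b = 600, about 1/12 of it at
b = 50, none at b = 0 where no diffusion gradients are played). A
b-independent dropout depth would partially cancel out of the
log-linear fit and misrepresent the high-b-dominated artifact this
method targets. The quantitative dropout statistics (probabilities,
depths, scales) are plausibility choices — no quantitative dropout
statistics exist for the clinical phenomenology — and are all exposed
on `PhantomSpec`.

Noise is Rician: the modulus of complex Gaussian noise added to the
attenuated signal, per-channel σ = 40 by default (b = 0 liver
SNR 25). The generator is bit-deterministic under a fixed seed.

What the phantom does **not** emulate: inter-repetition
misregistration, EPI distortion and ghosting, cardiac-phase timing
structure, perfusion (IVIM) signal at low b, anisotropic muscle
diffusion, anatomical realism of the liver outline. Passing tests
therefore demonstrate correctness of the algorithm under its own signal
model and robustness to Rician noise — not performance on clinical data
with registration errors or artifacts outside the model.

## Exact-recovery condition

With zero noise, the pipeline recovers `Î` *to machine precision* at
every voxel where a strict majority of repetitions is dropout-free over
the voxel's whole filter neighbourhood: the across-repetition median of
the filtered stack then equals the clean value, the MAD vanishes, every
affected repetition falls strictly below the threshold and is rejected,
and the survivors are bitwise-identical clean copies with weight 1.
Merely having one repetition above the clip threshold is *not*
sufficient: a partially attenuated repetition that survives rejection
contributes a blurred weight that differs from its true attenuation.
The exactness test asserts the majority precondition from the imposed
truth before asserting recovery.

## Numerical and evaluation choices

* Phantom-study ROIs are the tissue regions eroded in-plane by
  2 voxels, keeping statistics away from partial-volume edges — the
  analogue of placing circular ROIs inside segments.
* The paired t-test returns (t = 0, p = 1) for identical samples
  instead of the 0/0 indeterminate form.
* Left-vs-right regression in single-acquisition reports treats each
  slice as one pairing of lobe means; with one subject there is no
  across-patient axis.
* The 100-seed bias study (acceptance script and test) uses the default
  `PhantomSpec`; one study runs in ~0.2 s, the full set in ~25 s on one
  CPU. Problem sizes (5 slices, 96×96) are chosen so patch statistics
  are meaningful while the whole validation stays interactive.
* Intensities are never normalised across repetitions: the rejection
  statistics rely on raw magnitude fluctuation, and scanner scaling is
  assumed consistent across repetitions of one series.

## Known limitations

Thresholds (λ = 5, 3) and the 0.8 clip are fixed empirical values, not
adaptive; the method cannot restore a slice in which *all* repetitions
are corrupted (it then falls back to standard averaging); the MIP
reference is itself noisy, mitigated but not eliminated by filtering
and clipping; and the correction assumes motion-induced signal *loss* —
signal-increasing artifacts (e.g. bright-vessel pulsation) are outside
the model.
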