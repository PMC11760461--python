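# angiovis

Visibility enhancement for X-ray coronary angiograms.

Contrast-injected coronary vessels appear as dark tubes on a brighter,
noisy, unevenly illuminated background. Clinically important detail — small
vessels, wires, stent markers, the interior of large vessels — sits near the
noise floor, especially under low radiation or after dye clearance.
`angiovis` implements a visual-cortex-inspired enhancement pipeline for such
frames and validates it entirely on synthetic vessel phantoms with ground
truth.

## Method

For an input frame *I(x, y)* on [0, 1] the pipeline runs four stages:

1. **Multiscale oriented edges.** *I* is decomposed into a Gaussian pyramid
   *I_j* (Lanczos resampling, 8 scales) and each level is correlated with a
   bank of cosine-phase Gabor kernels *G_θ* (σ = 8 px, λ = 12 px, 8
   orientations on [0°, 180°)). Per pixel the strongest signed response
   S = s(x, y, j, θ*) is kept, split into polarity channels
   c_P = max(S, 0), c_N = max(−S, 0), gated at the 5th percentile of the
   nonzero magnitudes, and passed through Naka–Rushton gain control
   R = cⁿ/(cⁿ + σ_NRⁿ) with n = 2, σ_NR = 0.1.
2. **Lateral-facilitation line completion.** Every response projects a
   sub-threshold additive signal along its preferred orientation — a
   Gaussian mask with its classical-receptive-field disk (radius r_RF)
   zeroed. Summing each orientation channel with the additive spill of its
   neighbours gives LF(x, y, θ, j); a per-scale percentile soft threshold
   (γ_j from the packaged parameter table) keeps only facilitated responses.
   Channels recombine over polarity (LF_P − LF_N), orientation (signed
   power-sum, exponent m₁ = 1) and scale (Lanczos upsampling, weighted
   power-sum with m₂ = 2, inverse root, gain γ = 1/8) into the compound
   texture image TE.
3. **Blood-vessel ROI.** Each per-scale compound image is Otsu-binarised,
   morphologically closed with a per-scale disk (radii 0…6 px), reduced to
   its largest connected component, upsampled, fused by a width-3 sliding
   median across scales (8 scales → 6 fused masks), and vote-thresholded
   into the binary vessel ROI.
4. **Dynamic-range-balanced integration.**
   IE = clip(I + α·[T_P/(1 + β·I) − T_N/(1 + β − β·I)], 0, 1) with α = 0.4,
   β = 4: the ROI-masked texture darkens vessel interiors and brightens
   their flanks, with divisive protection of the ends of the display range.

The synthetic phantom generator renders seeded branching trees of dark
Gaussian-profile tubes with multiplicative illumination drift, broad bony
absorbers, tool-like curves and Poisson photon noise
(counts = Poisson(photon_scale · I)/photon_scale), plus ground-truth masks.
Visibility is scored as the contrast-to-noise ratio
CNR = |μ_bg − μ_vessel| / σ_bg.

## Worked example

```python
from angiovis import PhantomSpec, generate_phantom, cnr, cnr_improvement
from angiovis.enhance import enhance_frame

frame, truth = generate_phantom(PhantomSpec(seed=1))   # 256 px, 5000 photons
result, diag = enhance_frame(frame)

print(f"CNR raw      {cnr(frame, truth):.3f}")
print(f"CNR enhanced {cnr(result.output, truth):.3f}")
print(f"improvement  {cnr_improvement(frame, result.output, truth):.2f}%")
print(f"ROI covers   {100 * (diag.masks.roi & truth.vessel_mask).sum() / truth.vessel_mask.sum():.1f}% of vessels")
```

```
CNR raw      6.378
CNR enhanced 6.822
improvement  6.96%
ROI covers   100.0% of vessels
```

The raw CNR of 6.4 means the vessel–background intensity gap is 6.4
background noise standard deviations; enhancement deepens the vessel
interior inside the detected ROI, raising it by ~7% while leaving every
pixel outside the ROI untouched. `diag` exposes all intermediates (pyramid,
per-scale responses, TE, per-scale and fused masks) for QC.

The same pipeline is available from the shell:

```sh
angiovis phantom --seed 1 --out phantom_out/      # frame + ground truth
angiovis enhance phantom_out/frame.png -o enhanced.png --debug
angiovis evaluate --seeds 5 -o cnr_report.csv     # CSV: raw vs enhanced CNR
```

## Layout

- `src/angiovis/gabor.py` — pyramid, Gabor bank, polarity/noise/gain stages
- `src/angiovis/facilitation.py` — additive signals, collinear summation,
  thresholding, recombination into TE
- `src/angiovis/roi.py` — per-scale Otsu/morphology/CCL and multiscale fusion
- `src/angiovis/enhance.py` — integration rule and pipeline orchestration
- `src/angiovis/phantom.py` — synthetic angiograms, CNR metrics, bar fixtures
- `src/angiovis/io.py`, `src/angiovis/cli.py` — PNG/TIFF/DICOM I/O and CLI
- `docs/methods.md` — model description, parameter table, design notes
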