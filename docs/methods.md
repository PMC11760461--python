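# Methods

This note documents the model implemented by `angiovis`, the parameters
that matter, what the synthetic phantoms do and do not emulate, and the
numerical and design choices made where the design was genuinely open.

## Model

The pipeline treats vessel enhancement as perceptual line completion. Early
visual cortex responds to oriented contrast through receptive fields well
modelled by Gabor filters; collinear flanking stimuli facilitate each other
through lateral interactions, so interrupted contours are perceived as
complete. The pipeline transplants that mechanism: oriented edge responses
project sub-threshold "additive signals" along their preferred orientation,
collinear responses reinforce each other above a percentile threshold, and
the resulting texture — strong along vessel walls, completed across weak or
interrupted segments, incoherent over noise — is blended back into the
frame only where a multiscale region-of-interest stage detects vessels.

### Oriented multiscale decomposition

- Gaussian pyramid with factor-2 Lanczos-3 downsampling after a σ = 1 px
  Gaussian anti-alias blur; level 1 is the input. A fixed kernel size with a
  shrinking image realises multi-size receptive fields.
- Gabor kernels `exp(-(x² + y²)/σ²)·cos(2π/λ·(x·cosθ + y·sinθ))` with
  σ = 8 px, λ = 12 px, support 33 px, 8 orientations evenly spaced on
  [0°, 180°) — cosine-phase kernels are 180°-periodic, so 8 angles is the
  full distinct set. Kernels are DC-corrected and scaled to unit L2 norm so
  responses are comparable across orientations.
- Pyramid levels smaller than the kernel support are skipped with a logged
  warning (their responses are zero). Consequently a 256 px frame has three
  active scales; the full 8 require a 1024 px frame.
- Per pixel and scale the orientation maximising |s| wins (ties to the
  lowest index); the signed winner is split into nonnegative polarity
  channels that are processed independently until the recombination stage.
- Noise gate: within each (scale, polarity) channel the threshold is the
  5th-percentile (lower order statistic) of the *nonzero* magnitudes;
  entries strictly below it are zeroed, survivors pass unchanged. A
  `noise.use_max_fraction` variant gates at 0.95·max instead.
- Naka–Rushton gain control R = cⁿ/(cⁿ + σ_NRⁿ), n = 2, σ_NR = 0.1. The
  alternative reading σ_NRⁿ = 0.1 is available (`nr.sigma_is_power`).

### Lateral facilitation

- The additive signal at orientation θ is an anisotropic Gaussian in the
  rotated frame x′ = x·cosθ + y·sinθ, y′ = y·cosθ − x·sinθ, with decays
  σx, σy given per scale as *fractions of the scale image's linear
  dimension* (pixel conversion: level width by default). The central disk
  of radius r_RF (default 8 px, the Gabor envelope σ) is zeroed — a
  response does not facilitate its own classical receptive field — and the
  mask is normalised to unit sum.
- The summation over all neighbouring same-orientation responses is
  realised as a dense correlation of the orientation-restricted gain-control
  output with the mask (mathematically the same superposition, O(N log N)).
  LF(θ) is that additive field plus the channel's own response.
- Percentile threshold: thr_j is the γ_j-th percentile of LF pooled over
  pixels and orientations within one (scale, polarity); polarity channels
  are computed independently throughout, so pooling across them would
  couple them. The soft step H is logistic with slope 10/thr_j (H(0) = ½);
  slope ∞ recovers the hard gate LF·[LF > thr_j], used whenever exact
  zeros matter.
- Recombination: polarity difference; orientation signed power-sum with
  m₁ = 1 followed by the 1/m₁ root; scale fusion of the Lanczos-upsampled
  per-scale images with weights 1/τ_j (τ_j = 1 — no per-scale weights are
  published, and a neutral default adds no invented numbers), exponent
  m₂ = 2, inverse root, gain γ = 1/8. The inverse root keeps TE on the
  intensity scale of its inputs; the literal power variant is available
  (`lf.literal_te_power`).

### Per-scale parameter table (packaged defaults)

| scale j | σx = σy | γ_j (%) | closing radius r_j (px) |
|--------:|--------:|--------:|------------------------:|
| 1 | 0.05 | 99 | 0 |
| 2 | 0.05 | 80 | 2 |
| 3 | 0.06 | 97 | 3 |
| 4 | 0.07 | 97 | 4 |
| 5 | 0.07 | 96 | 5 |
| 6 | 0.07 | 96 | 5 |
| 7 | 0.10 | 96 | 5 |
| 8 | 0.10 | 96 | 6 |

With σx = σy the additive mask is isotropic apart from the excluded
central disk; orientation selectivity of the facilitation then comes from
the per-orientation channel restriction and the percentile threshold, not
from mask anisotropy. The mask supports σx ≠ σy when configured.

### Blood-vessel ROI

Per scale: Otsu binarisation of the compound image (on |T′_j| by default —
dark vessels produce strongly *negative* texture, so thresholding the
signed values selects the background side and the ROI misses the vessels;
the signed variant remains selectable via `roi.use_magnitude: false`),
closing with a disk of radius r_j (computed on a zero-padded grid so it
never removes foreground), largest 8-connected component, Lanczos
upsampling to full resolution re-binarised at 0.5. Across scales: width-3
sliding median (stride 1; 8 scales → 6 fused masks), per-pixel vote count,
ROI where the count strictly exceeds τ = 0 (union — maximises small-vessel
retention; stricter votes are configurable). Constant compound images
(e.g. skipped scales) contribute empty masks with a logged warning.

### Integration

IE = clip(I + α·[T_P/(1 + β·I) − T_N/(1 + β − β·I)], 0, 1), α = 0.4,
β = 4. The divisors suppress positive texture where the frame is already
bright and negative texture where it is already dark; the structure is
symmetric under (I, T_P, T_N) → (1−I, T_N, T_P). The formula can leave
[0, 1]; the output is clipped and the clipped fraction logged (min–max
renormalisation was considered and rejected: it would couple the output
range to frame content and break the locality guarantee that pixels
outside the ROI are untouched). Frames of a cine sequence are processed
independently.

## Synthetic phantoms

The generator emulates what the enhancement stages actually respond to in
a clinical frame: a seeded recursive branching tree (default depth 4, root
radius 6 px tapering by 0.72 per generation, jittered polyline segments)
rendered as dark Gaussian-profile tubes on a 0.65 background; smooth
multiplicative illumination drift (±15%); two broad low-contrast elongated
absorbers standing in for vertebral structures; a 1-px dark wire with two
marker dots; Poisson photon noise with `photon_scale` = 5000 expected
photons at unit intensity (the 13-fold reduction emulates a low-radiation
fluoroscopy run), and `contrast_dilution` scaling vessel depth to emulate
dye clearance. Defaults were fixed once to plausible desk-scale values:
256 px frames keep three Gabor scales active and one enhancement under a
second.

Not emulated: cardiac/respiratory motion, scatter and beam-hardening
physics, 3-D projection overlap, detector blur, and structured
(non-Poisson) noise. Passing the phantom-based tests therefore shows the
pipeline enhances dark tubular structures against smooth noisy backgrounds
under the stated noise model — not clinical diagnostic value.

Visibility metric: CNR = |μ_bg − μ_vessel| / σ_bg, the common angiography
convention, with the background sampled at least 8 px away from any vessel
or tool. Published CNR-improvement figures for clinical enhancement
algorithms rarely state their region or definition, so absolute numbers
are not comparable across studies; within this package the metric is used
only for before/after comparisons under one fixed definition.

## Numerical choices

- All floating-point work in double precision; quantisation only at write
  time (8/16-bit PNG/TIFF).
- Resampling is a package-local separable Lanczos-3 with per-row weight
  normalisation: constants survive every stage to ~1e-15, which the
  constant-frame pass-through identity requires end to end.
- Oriented responses with magnitude below 1e-9 are zeroed: numerical
  residue of DC-corrected kernels on near-constant inputs, many orders
  below any genuine contrast response (the gain-control semi-saturation is
  0.1).
- Correlation uses reflective borders and "same"-size output; argmax ties
  break to the lowest orientation index; Otsu uses a 256-bin histogram with
  the strict `>` comparison.
- Degenerate inputs: constant images are rejected by the Otsu primitive
  and mapped to empty masks (with a warning) by the per-scale binariser;
  an all-zero LF field short-circuits to zero; a facilitation mask whose
  support is swallowed by the r_RF disk is all-zero with a warning.

## Known limitations

- At 256 px only pyramid scales 1–3 carry signal (kernel support 33 px);
  the coarse-scale machinery engages fully on 1024 px frames.
- The gap-closure demonstration on bar fixtures separates collinear from
  perpendicular arrangements only in *relative* facilitation strength. A
  gap small enough to sit inside the Gabor envelope (e.g. 4 px against
  σ = 8) receives a direct, gain-saturated edge response from each bar's
  own tail in both geometries, so the absolute fraction of supra-threshold
  gap pixels does not discriminate at that scale; see the fixture-level
  superposition tests for the mechanism checks.
- Facilitation is single-pass and within-(orientation, scale); no
  recurrent passes, no cross-scale or cross-orientation coupling, and no
  temporal facilitation across cine frames.
- The enhancement amplifies any elongated dark structure inside the ROI,
  including bone-edge artifacts, mirroring the behaviour reported for the
  approach on clinical material.
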