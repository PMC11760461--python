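# Per-scale defaults of the enhancement pipeline (resolution index 1 = finest).
# sigma_x / sigma_y: additive-signal Gaussian decay, as fractions of the
#   scale image's linear dimension (collinear / orthogonal axis).
# gamma_percentile: percentile used for the lateral-facilitation threshold.
# disk_radius: radius (pixels) of the disk structuring element used to close
#   the per-scale ROI candidate mask.
sigma_x: [0.05, 0.05, 0.06, 0.07, 0.07, 0.07, 0.10, 0.10]
sigma_y: [0.05, 0.05, 0.06, 0.07, 0.07, 0.07, 0.10, 0.10]
gamma_percentile: [99, 80, 97, 97, 96, 96, 96, 96]
disk_radius: [0, 2, 3, 4, 5, 5, 5, 6]
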