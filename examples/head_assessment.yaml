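# Synthetic head-mode FBP-vs-IR study at the full protocol size:
# 512 x 512 matrix, 0.55 mm pixels, 85 NPS slices, 40 TTF slices.
seed: 1
nps_slices: 85
ttf_slices: 40
roi_side_px: 82
modes:
  - name: head
    matrix_size: 512
    pixel_spacing_mm: 0.55
    fbp: {sigma: 40.0, family: fbp, peak: 0.29, psf_sigma_mm: 0.47}
    ir: {sigma: 26.0, family: ir, peak: 0.20, psf_sigma_mm: 0.44}
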