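# cbctiq — task-based image quality for CT / CBCT

`cbctiq` implements the task-based image-quality toolchain used to compare
cone-beam CT reconstructions — classically filtered back projection (FBP)
versus iterative reconstruction (IR) — on a Catphan-style quality phantom:

* **2D noise power spectrum (NPS)** from detrended square ROIs in a uniform
  module, with radial profile, noise magnitude (√AUC) and peak-frequency
  detection;
* **task transfer function (TTF)** by the circular-edge method on cylindrical
  contrast inserts (sub-pixel center refinement, radial ESF, windowed LSF,
  normalized Fourier magnitude, TTF50), which stays meaningful for nonlinear
  IR algorithms whose resolution depends on contrast and noise;
* **NPWE detectability index** (non-prewhitening observer with eye filter)
  for circular lesion-detection tasks under specified viewing conditions;
* a **synthetic phantom simulator** that generates uniform and four-insert
  modules with a prescribed radial NPS, Gaussian system blur, known insert
  contrasts and an optional cupping artefact — so the whole protocol runs,
  and can be validated against known ground truth, without any scanner data.

It is aimed at medical physicists and imaging researchers who want a tested,
scriptable reference implementation of these metrics (in the spirit of tools
such as iQMetrix-CT or pylinac) plus a ground-truth simulator for validating
analysis pipelines.

## The metrics

With pixel sizes Δx, Δy and ROI side lengths Lx, Ly (pixels), the NPS is
estimated from N detrended ROIs as

    NPS₂D(fx, fy) = (Δx Δy)/(Lx Ly) · (1/N) Σᵢ |FFT₂D(ROIᵢ − FITᵢ)|²

where FITᵢ is the least-squares 2D polynomial of total degree 2. Noise
magnitude is √(∬ NPS₂D dfx dfy), which by Parseval's relation equals the
detrended pixel standard deviation.

The TTF is |FT(LSF)| normalized to 1 at zero frequency, where the LSF is the
radial derivative of the circular-edge ESF; TTF50 is the frequency at which
it falls to 0.5.

The NPWE detectability index for a task function W (analytic transform of a
flat disk of diameter d and contrast C) with eye filter E is

    d′² = [∬ W² TTF² E² du dv]² / ∬ W² TTF² NPS E⁴ du dv

E maps image frequencies to angular frequency at the viewer's eye (default:
500 mm viewing distance, zoom 1.5, 0.2 mm display pixel pitch) and follows
the visual-response family ρⁿ·exp(−cρ²) with n = 1.3, peaking at
4 cycles/degree.

## Worked example

A full synthetic head-mode study — FBP-like (σ = 40 HU, NPS peak
0.29 mm⁻¹) versus IR-like (σ = 26 HU, peak 0.20 mm⁻¹) noise on 512 × 512
stacks with 0.55 mm pixels, 85 NPS slices and 40 TTF slices:

```python
import cbctiq as q

series = [
    q.synthetic_series("head", "FBP", 40.0, "fbp", 0.29, 0.47,
                       nps_slices=85, ttf_slices=40, seed=1),
    q.synthetic_series("head", "IR", 26.0, "ir", 0.20, 0.44,
                       nps_slices=85, ttf_slices=40, seed=2),
]
table = q.run_assessment(q.AssessmentConfig(series=series, roi_side_px=82))
print(table.human_report())
```

prints

```
== Task-based image quality summary ==

mode                       head
reconstruction              FBP           IR
row
noise_magnitude_hu    39.970246    25.970988
f_peak_mm-1_0          0.296397     0.199487
f50_mm-1 air           0.391422     0.424023
contrast_hu air    -1000.372468 -1000.175071
dprime air           125.154071   190.962272
f50_mm-1 ldpe          0.397941     0.425630
contrast_hu ldpe    -179.959593  -179.696366
dprime ldpe           22.673056    34.454311
f50_mm-1 delrin        0.383408     0.416419
contrast_hu delrin   234.458524   234.251166
dprime delrin         29.348524    44.949031
f50_mm-1 teflon        0.393473     0.424611
contrast_hu teflon   790.362384   789.701539
dprime teflon         98.808240   150.909963

== IR vs FBP percent changes ==
        head  noise_magnitude_hu -35%
        head  f50_mm-1           +8% +/- 1%
        head  contrast_hu        -0% +/- 0%
        head  dprime             +53% +/- 0%
```

The pipeline recovers the prescribed noise magnitudes (40 / 26 HU, a −35%
reduction) and NPS peak positions (0.29 / 0.20 mm⁻¹) from the synthetic
stacks, measures the four insert contrasts to within a few HU of their
nominal values (−1000, −180, +235, +790 HU), and shows the characteristic
IR pattern: lower and coarser noise, slightly higher TTF50, unchanged
contrast, and a substantially higher detectability index for every task.

The same study is available from the shell:

```
cbctiq assess --config examples/head_assessment.yaml --out results/
```

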