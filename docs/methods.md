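# Methods

This note documents the models, defaults and numerical choices behind
`cbctiq`, and what the synthetic validation does and does not demonstrate.

## Scope and data model

All analyses operate on stacks of axial slices in Hounsfield units with known
in-plane pixel spacing and slice thickness (`ImageStack`). Slices are ordered
ascending along the stack axis; in-plane coordinates are 0-based (row, col)
with pixel centers at integer coordinates, so physical x = col × spacing.
Stacks are read/written either as minimal CT-storage DICOM series (HU via
RescaleSlope/Intercept, 16-bit storage, so round trips are exact to 0.5 HU)
or as a fixed little-endian float32 raw format with a plain-text header
(bit-exact round trips). Acquisition metadata (kV, mA, CTDIvol, FOV,
reconstruction label) is carried through reports but never used in
computation.

## Noise power spectrum

The estimator averages periodograms of detrended square ROIs over all
(ROI, slice) pairs and scales by (ΔxΔy)/(LxLy). Choices:

* **Detrending.** Each ROI is fit with the least-squares 2D polynomial of
  total degree 2 (6 coefficients) on conditioning-scaled coordinates; the
  residual feeds the FFT. No window function is applied — the detrend is the
  sole leakage control. The fit removes a small number of degrees of freedom
  concentrated at the lowest spatial frequencies: the DC bin of the
  resulting NPS is ~0 and the first two radial bins are systematically
  drained. Tests therefore assert spectral flatness for white noise away
  from those bins; the noise-magnitude integral is essentially unaffected
  (≤0.2% for 64² ROIs).
* **Noise magnitude** is the square root of the full 2D spectral integral,
  which by Parseval equals the detrended pixel SD (verified to ≤0.5%). The
  alternative reading — area under the 1D radial curve — would not carry HU
  units and is not used.
* **Radial profile.** Annular averaging on bins of width 1/(L·Δ) (the FFT
  grid spacing), nearest-bin assignment, no interpolation.
* **Peak detection.** The radial profile is smoothed with a 3-point moving
  average (the ~0 DC bin is excluded from both the smoothing window and the
  search, otherwise it masks a genuine first-bin peak); interior local
  maxima are refined to sub-bin accuracy with a local parabola, which
  matters because band-pass CT noise spectra are flat-topped. A maximum
  below 0.05 mm⁻¹ is reported first as the low-frequency (cupping) peak;
  the global maximum above the cutoff is the noise-texture peak. A monotone
  decreasing profile degenerates to the first interior bin.
* **Default ROI layout**: four square ROIs at 12/3/6/9 o'clock, 50 mm from
  the phantom center (82 px side for the 0.55 mm head geometry, 46 px for
  the ~0.96 mm thorax/pelvis geometries).

## Circular-edge TTF

For one cylindrical insert: the sub-pixel center is an intensity-weighted
centroid of above-half-contrast pixels, iterated twice (≤0.1 px on synthetic
stacks); contrast is the mean over a disk of 60% of the insert radius minus
the mean of a background annulus at (1.3, 1.8) × the insert radius. The ESF
pools every pixel of an analysis disk (2 × insert radius) across the
configured slices, indexed by its exact radius.

* **ESF binning.** Radial bins of pixel-spacing/10. Each bin value is a
  local weighted *linear regression* (tent kernel over the two adjacent
  bins) evaluated at the bin center: a plain per-bin mean samples the edge
  at the mean radius of the pixels that happen to fall in the bin, a
  first-order (slope × offset) error that dominates at steep edges.
  Ill-conditioned fits (all radii clustered) fall back to the weighted
  mean; empty bins are filled by linear interpolation.
* **LSF.** Central finite differences, sign-normalized so the lobe is
  positive regardless of contrast sign. The edge is located, and its FWHM
  estimated, on a 5-bin-smoothed derivative; when the nominal insert radius
  is known the search is confined to (0.5, 1.5) × that radius so sparse
  noisy bins near the disk center cannot be mistaken for the edge.
* **Windowing.** A Tukey-style taper centered on the LSF extremum: unity to
  2 × FWHM, cosine roll-off to zero at 4 × FWHM. A plain Hann window of the
  same support attenuates the lobe itself and biases TTF50 upward by ~3%;
  the flat-topped taper leaves the lobe untouched while still suppressing
  far-from-edge noise.
* **TTF.** Magnitude of the real FFT of the windowed LSF, normalized at
  zero frequency and reported to the ESF-bin Nyquist on a 4× zero-padded
  grid; TTF50 is the first downward 0.5-crossing by linear interpolation
  (absent, with a warning, if the curve never reaches 0.5).
* **No noise-power subtraction** is applied; slice averaging is the only
  noise control, mirroring the usual 40-slice protocol.

Validation against closed forms: a synthetic insert with Gaussian blur σ
recovers TTF(f) = exp(−2π²σ²f²) within 3% up to TTF50 and TTF50 =
√(ln 2/2)/(πσ) within 3% for σ ∈ {0.3, 0.5, 1.0} mm, with the expected 1/σ
scaling. The residual ~1% bias is the curvature of the circular edge
(σ/R up to 0.16) plus binning granularity.

## NPWE detectability

d′² = [∬W²·TTF²·E² du dv]² / ∬W²·TTF²·NPS·E⁴ du dv, integrated with the
trapezoid rule on the measured NPS grid; the TTF is applied radially
(rotational symmetry) by interpolation of the measured curve, zero beyond
its support. The task function W of a flat disk is evaluated analytically,
|W(ρ)| = |C|πr²·|2J₁(2πρr)/(2πρr)|, removing rasterization error. The eye
filter is ρⁿexp(−cρ²) in cycles/degree with n = 1.3 and c set so the peak
sits at 4 cycles/degree, max-normalized; image frequency maps to the
display via f · pixel_spacing/(zoom × pitch) and to angle via the viewing
distance. Defaults: 500 mm, zoom 1.5, 0.2 mm pitch. No internal-noise term
is added (pure NPWE).

The white-noise, unit-TTF, no-eye-filter limit matches the closed form
d′ = |C|·r·√(π/N₀) to <1% on a sufficiently wide frequency grid (the
truncation error of the Airy tail decays as 1/(π²·r·f_Nyquist), so the
oracle test uses a grid extending to 2.5 mm⁻¹).

Because the eye-filter constants are a modeling choice, *absolute* d′
values are parameterization-dependent; percent changes and orderings
between reconstructions — the quantities the summary table reports — are
insensitive to it to first order.

## Synthetic phantom: study conditions and realism

The generator emulates a 200 mm quality phantom: a uniform module and a
four-insert sensitometry module (air −1000, LDPE −180, Delrin +235, Teflon
+790 HU; 12.2 mm diameter on a 50 mm ring). Default geometry follows the
head protocol: 512 × 512, 0.55 mm pixels (281.6 mm FOV), 1.991 mm slices;
protocol sizes are 85 slices for NPS and 40 for TTF.

* **Noise** is a stationary Gaussian random field per slice (no inter-slice
  correlation — slices are analyzed independently), synthesized by
  Fourier-amplitude filtering of white noise so that the expected NPS equals
  the prescription exactly and the pixel variance equals the target σ².
  Two radial families are provided: FBP-like S ∝ f·exp(−(f/f₀)²) (band-pass,
  ramp-filter-like) and IR-like S ∝ f·exp(−f/f₀) (peak at f₀ with an
  exponential roll-off). The IR family's heavier very-low-frequency mottle
  is deliberate: iterative reconstruction trades fine grain for smooth
  blotch, and this is what lets a spectrum with 35% lower magnitude and a
  lower peak frequency lie *below* the FBP-like spectrum throughout the
  eye-weighted detection band — a sharper (e.g. Gaussian- or cubic-rolloff)
  low-pass family with the same σ and peak would concentrate its power
  inside the task band and *invert* the d′ ordering.
* **Blur**: inserts are rendered as the continuous disk ⊗ Gaussian profile
  point-sampled at pixel centers (a noncentral-χ² expression), so the
  system's ground-truth transfer is exactly the Gaussian MTF. Rendering an
  area-averaged raster and then filtering would fold in the pixel-aperture
  MTF and make the ground truth σ-dependent and wrong by up to ~12% at
  σ = 0.3 mm. With zero blur, inserts are rasterized with area-weighted
  anti-aliasing (8× subsampling of edge pixels).
* **Cupping**: an optional raised-cosine radial bowl over the phantom disk
  (center-minus-edge = amplitude). A quadratic bowl would be annihilated
  exactly by the per-ROI degree-2 detrend; the cosine profile leaves a
  low-frequency residual that reproduces the characteristic ~0.02 mm⁻¹ NPS
  peak. The residual scales with amplitude²; under band-pass (FBP-like)
  noise a ~120 HU bowl yields a robust first-bin peak, while under IR-like
  noise the spectrum's own low-frequency power masks it — a genuine
  limitation of peak-based cupping detection, not of the simulator.
* **Determinism**: a `PhantomConfig` (including its seed) maps to
  bit-identical voxel data; per-slice fields use spawned child generators.

What the synthetic tests do **not** show: real CBCT noise is neither
stationary nor Gaussian (scatter, beam hardening, angular undersampling),
real IR is nonlinear (contrast- and dose-dependent TTF, which is why the
TTF rather than the MTF is measured in the first place), and real cupping
is not radially symmetric. Passing the round-trip suites demonstrates that
the *estimators* are correct and unbiased under their stated models, not
that the simulator reproduces any particular scanner.

## Study conditions for the FBP-vs-IR comparison

The default comparison reproduces the head-mode conditions of the benchmark
table in `cbctiq.benchmark`: noise 40 → 26 HU (−35%), NPS peak 0.29 → 0.20
mm⁻¹, PSF σ 0.47 → 0.44 mm (TTF50 ≈ 0.40 → 0.43 mm⁻¹, a few-percent
sharpening), identical insert contrasts. Under these conditions the
pipeline reproduces the published qualitative pattern, including a ~+52%
mean d′ change against the published +55 ± 2%.

A caveat for the coarser-pixel (≈0.96 mm) thorax/pelvis geometries: there
the eye-filter passband maps to ≈0.14 mm⁻¹ in image frequency — directly
on top of the 0.13 mm⁻¹ IR noise peak — so at the published −19% (thorax)
noise reduction the NPWE model predicts a near-zero d′ change for any
radially-parameterized IR spectrum of that magnitude and peak. The
published large per-mode d′ gains there imply in-band noise reductions
well beyond what the printed √AUC alone encodes; the end-to-end ordering
checks therefore use the head-mode conditions, where magnitude, peak and
ordering are mutually consistent.

## Report pipeline

`run_assessment` executes NPS, per-insert TTF/contrast and per-task d′ for
every (mode, reconstruction) series and assembles a long-format metric
table plus IR-vs-FBP changes: noise-magnitude percent change, and mean ±
sample SD (n−1, over exactly the four inserts) of the per-insert TTF50,
contrast and d′ percent changes. Task contrasts equal the *measured* insert
contrasts (10 mm diameter by default). Percent values are integer-rounded
only in the human-readable report; TSV outputs keep full precision. Each
run with an output directory writes a manifest (config hash, seeds) for
reproducibility.
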