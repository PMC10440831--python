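# Methods

This note documents the models, parameter choices and numerical decisions
behind `ftirfuse`, and what the synthetic phantom does and does not
establish about real tissue data.

## The phantom

### Scene geometry

`phantom.make_scene` draws a labelled map on the optical grid (default
1012×1012 pixels at 0.25 µm — a 46×46 FTIR grid at the 22:1 size ratio of
5.5 µm to 0.25 µm). Tumour aggregates are non-overlapping discs placed on a
jittered grid (sites spaced 2.1 disc radii apart, shuffled and jittered by
the seed), each partitioned concentrically into a keratinised core, bulk
tumour and a collagen rim with radii set by the requested area split; the
surround is lymphoid tissue and any unrequested area becomes a background
frame. Default area fractions: lymphoid 0.55, tumour 0.25, keratinised core
0.08, collagen rim 0.12. The jittered-grid placement makes realised
fractions track the requested ones to a few percent at any seed.

Per-class mean abundances (cytokeratin, collagen, ds-DNA):

| class            | cytokeratin | collagen | ds-DNA |
|------------------|------------:|---------:|-------:|
| background       | 0           | 0        | 0      |
| lymphoid         | 0.15        | 0.25     | 0.90   |
| tumour (bulk)    | 0.55        | 0.25     | 0.25   |
| keratinised core | 1.00        | 0.10     | 0.10   |
| collagen rim     | 0.15        | 1.00     | 0.15   |

Within-class variation is a seeded smooth multiplicative field
(1 + 0.15·Gaussian random field, σ = side/32), and lymphoid DNA carries a
nuclear speckle (×1.3 inside thresholded speckles, ×0.7 between them) to
mimic closely packed lymphocyte nuclei. No quantitative description of
within-class spectral variability exists for the real tissue; these
variability knobs are plain config constants, not calibrated values.

### Reference spectra

`phantom.make_reference_spectra` builds the three molecular spectra as sums
of Gaussian bands with fixed centre/width/amplitude tables (absorbance
units are arbitrary — no absolute scale exists for the real molecular
spectra). The constraints that carry the science: the ds-DNA band dominating
1200–1320 cm⁻¹ is centred at 1252 cm⁻¹ (asymmetric phosphate), the collagen
band at 1285 cm⁻¹ (amide III), and both proteins carry strong amide I bands
near 1650 cm⁻¹ so mixed tissue spectra pass the quality gate. The seed
applies ±5% amplitude jitter only; centres and widths are fixed so the
window argmaxes cannot move. With the class abundances above, the expected
1252/1285 ratio is ≈3 in lymphoid tissue and ≈0.5–1.5 across the tumour
classes, mirroring the direction of the real discriminant.

### Forward model

`phantom.render_ftir` blurs the truth abundances with a Gaussian PSF
(σ = 2.75 µm, half the FTIR pixel), block-averages to the 5.5 µm grid, and
mixes through the reference spectra. Distortions, each seeded and per-pixel:

- **baseline** — a convex quadratic `amp·(a + b·(t − t₀)²)` in normalised
  wavenumber t, amp default 0.1 absorbance;
- **scatter** — a broad sinusoid `amp·sin(2πt + φ)` with one period across
  the axis, amp default 0.02: a smooth surrogate for the Mie ripple, not a
  physical Mie computation — sufficient to exercise the EMSC correction,
  whose basis contains this frequency;
- **noise** — i.i.d. Gaussian, sd default 0.01 absorbance; the final cube
  is truncated at zero absorbance (a stated generator choice).

What the phantom does **not** emulate: realistic histological texture,
chromatic aberration or staining variability in the optical image,
resonant-Mie dispersion line-shape distortion, detector drift, or spatially
correlated noise. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the assumed linear-mixing model, not
performance on patient tissue.

## Preprocessing

The chain runs in a fixed order — rubber-band baseline, noise reduction,
scattering correction, quality test, paraffin/fingerprint truncation,
vector normalisation — and the report logs the order so it is regression-
tested.

- **Rubber-band**: the lower convex hull of (wavenumber, absorbance) is
  computed by monotone chain, linearly interpolated and subtracted; the
  result is zero at hull vertices and the operation is idempotent. Tested
  against an independent O(n²) max-of-underestimating-lines oracle.
- **Noise reduction**: the method is a free choice here; PCA truncation is
  the FTIR standard. Spectra are reconstructed from the top k = 20
  mean-centred principal components; k equal to the band count is the
  identity, and a noiseless rank-3 cube is reproduced exactly at k = 3.
- **EMSC**: each spectrum is modelled as `c·m̄ + a + b·t + Σ gᵢEᵢ` with m̄
  the usable-pixel mean and Eᵢ three sine/cosine pairs (1–3 periods across
  the axis); the corrected spectrum is `(s − a − b·t − Σ gᵢEᵢ)/c`, one
  iteration by default. When the molecular reference spectra are available
  (as in the pipeline) they augment the design as retained constituent
  columns orthogonalised against m̄ — without this, genuine chemical
  deviations from the mean leak into the smooth interference terms and
  clean data is distorted by ~0.1 rad in pairwise class-mean SAM; with it
  the distortion is ~10⁻⁴ rad. Pixels with multiplicative constant below
  10⁻⁶ are flagged unusable instead of divided.
- **Quality gate**: amide I is operationalised as the maximum absorbance
  over 1600–1700 cm⁻¹ (the band is named in the protocol, the window and
  statistic are not); pixels outside [0.1, 2.0] are removed, boundary
  values retained. The gate runs before truncation, so the amide window is
  still present.
- **Truncation**: bands retained iff 900 ≤ ν ≤ 1800 (inclusive) and ν not
  strictly inside a paraffin window — open intervals, so 1350 survives. On
  the 990 + 4k grid this keeps 166 of 703 bands. The instrument collects
  from 990 cm⁻¹, so the effective lower bound is 990 despite the nominal
  900 of the fingerprint definition; the reference-spectra generator
  accordingly requires coverage of [990, 1798].
- **Vector normalisation**: unit Euclidean norm per usable spectrum;
  zero-norm spectra are flagged, never divided.

## Fusion

The pan channel is luminance greyscale (0.299/0.587/0.114) z-scored over
unmasked pixels. Registration is a least-squares control-point affine fit
(exact for affine-consistent pairs); in the synthetic pipeline the control
points come from the known misregistration transform, standing in for
manually clicked landmarks.

Per band, ordinary least squares of the low-resolution band on the pan
degraded to the FTIR grid gives gain g_b and intercept a_b; fitting at the
native FTIR grid avoids interpolation-induced correlation inflation. The
fused band is `upsample(band) + g_b·(pan − upsample(degrade(pan)))` with
bicubic (spline order 3, pixel-centre aligned, `grid_mode`) interpolation.

Two numerical choices matter:

1. **Pan degradation uses pure block averaging** (psf_sigma = 0) in the
   pipeline. The FTIR cube already embodies the instrument PSF; blurring
   the pan again before block averaging double-counts blur, so the detail
   term would not vanish under degradation and the degrade∘upsample round
   trip would fail. A Gaussian PSF (default σ = half the target pixel)
   remains available on `degrade_to_lowres` for sensor-matched protocols.
2. **Equalisation plus consistency projection.** Moment matching each fused
   band to the upsampled reference minimises per-band distributional
   distortion but flattens bands toward their means (the injected detail
   inflates the band's variance, so the matching shrinks it), breaking
   Wald consistency (~0.06 rad mean SAM). The pipeline therefore follows
   equalisation with `fused += upsample(pre − degrade(fused))`, the
   standard consistency enforcement; the net effect is a per-band damping
   of injected detail, and the degraded fused cube then reproduces the
   preprocessed cube to ~0.005 rad mean SAM.

## Quality metrics

SSIM uses scikit-image's implementation with the standard 7-pixel
Gaussian-weighted window and K₁ = 0.01, K₂ = 0.03. Band-vs-reference SSIM
is computed on 95th-percentile-rescaled images (the display convention,
configurable off); band-vs-optical SSIM is computed on z-scored images
because the pan is in standardised units while absorbance is not. SAM is
reported in radians (degrees in the CLI report) with zero-norm pixels
excluded and counted. MSE/PSNR are plain; zero MSE reports infinite PSNR.

## Clustering, ratio, unmixing

k-means (scikit-learn, k-means++ init, n_init = 10, seeded) runs on the
preprocessed FTIR-resolution spectra — cluster counts then correspond to
FTIR pixels, and centroids are recomputed as member means so the
centroid-equals-member-mean invariant holds exactly.

The ratio image divides the band nearest 1252 cm⁻¹ by the band nearest
1285 cm⁻¹ (nearest-neighbour lookup, ties to the lower wavenumber; on the
4 cm⁻¹ grid the bands actually used are 1250 and 1286 and are logged), with
a denominator floor ε = 10⁻⁶ and masked pixels rendered white. The
discriminant is evaluated at the native FTIR grid against majority-vote
truth labels: single-channel detail injection cannot restore band-specific
spectral contrast at sub-FTIR scales, so a sub-pixel evaluation would score
the fusion model rather than the discriminant.

Unmixing solves nonnegative least squares per pixel (fast path:
unconstrained solve, active-set NNLS only for pixels with negative
coefficients; an unconstrained mode is available behind a flag). No
intercept is fitted — the baseline is already removed. χ² is the reduced
residual (RSS/(bands − molecules)); because its scale depends on the noise
model, the bad-fit threshold defaults to 10× the median χ² over usable
pixels rather than any fixed literature range. The RGB composite scales
each channel by its 95th percentile over good-fit pixels; bad fits render
black.

## Sizes, tolerances, degenerate inputs

- Default problem sizes: 1012×1012 optical grid, 46×46×703 raw cube,
  46×46×166 after truncation, fused 1012×1012×166 (held in float32 in the
  high-resolution stage; coefficients and statistics in float64).
- Equalisation treats a band as constant when its sd is below
  10⁻¹²·max(1, |mean|) — the sd of a numerically constant band is rounding
  noise, and dividing by it would explode the scale.
- `fit_affine` rejects collinear control points by a rank test;
  `AffineTransform` rejects singular linear parts (|det| < 10⁻¹²).
- Upsampling is guarded against factors above 1000.
- All randomness flows from one global seed through named SHA-256
  substreams (each below 2³¹), making full reruns bit-identical.

## Known limitations

- The regression fusion injects a single pan-derived detail channel, so
  fine-scale contrast is rank-1 across bands; band ratios at sub-FTIR
  scales inherit pan structure rather than true spectral variation.
- The EMSC constituent model assumes the reference spectra span the
  chemistry; unmodelled chromophores would again leak into the smooth
  interference basis.
- The phantom's linear mixing with nonnegative abundances matches the
  unmixing model by construction; real tissue violates linearity (optical
  saturation, scattering coupling), so recovery correlations here are an
  upper bound.
- ENVI I/O is restricted to float32 band-sequential cubes with in-header
  wavelength lists; vendor formats are out of scope.
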