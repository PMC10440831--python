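# ftirfuse

Fusion of low-resolution FTIR hyperspectral tissue images with
high-resolution optical histology, and decomposition of the fused spectra
into molecular abundance maps.

## The problem

Infrared microscopy of tissue sections yields a datacube — a full absorbance
spectrum per pixel — but at a spatial resolution (~5.5 µm pixels) far too
coarse to resolve cells. H&E-stained histology resolves sub-micron detail
(~0.25 µm) but carries no chemical information. For metastases of oral
squamous cell carcinoma (OSCC) in cervical lymph nodes, the absorbance ratio
A(1252 cm⁻¹)/A(1285 cm⁻¹) discriminates metastatic tumour from lymphoid
tissue, because the numerator is dominated by ds-DNA (densely packed
lymphocyte nuclei) and the denominator by collagen (tumour-associated
stroma). This package implements, as a tested pipeline over a synthetic
phantom with known ground truth:

1. **Spectral preprocessing** in a fixed six-stage order: rubber-band
   (lower-convex-hull) baseline correction, PCA noise reduction, EMSC
   scattering correction (one iteration), an amide-I quality gate
   (0.1 ≤ max A over 1600–1700 cm⁻¹ ≤ 2.0), omission of paraffin windows
   (1350–1500, 2835–3000 cm⁻¹) with truncation to the fingerprint region
   (900–1800 cm⁻¹), and vector normalisation.
2. **Regression pansharpening**: the optical image is converted to
   greyscale, standardised (z-scored), and degraded to the FTIR grid; each
   band *b* is regressed on the degraded pan image, `A_b ≈ a_b + g_b·P`,
   and the fused band is `fused_b = upsample(A_b) + g_b·(P_hr − P_lr↑)`,
   followed by per-band moment equalisation to the FTIR reference and a
   spectral-consistency projection.
3. **Quality metrics**: SSIM (spatial fidelity to the optical image), the
   spectral angle mapper SAM = arccos⟨a,b⟩/(‖a‖‖b‖) (spectral distortion
   against the FTIR reference), PSNR and MSE, plus the Wald-protocol check
   that degrading the fused cube reproduces the native FTIR cube.
4. **Unmixing and discrimination**: k-means clustering of the spectra;
   the 1252/1285 ratio image; pixel-by-pixel nonnegative least squares
   `min ‖s − R·c‖², c ≥ 0` against reference spectra of cytokeratin,
   collagen and ds-DNA, rendered as an RGB composite (red/green/blue
   respectively) over each channel's 95th-percentile range, with bad fits
   (reduced χ² above threshold) black and poor-quality spectra white.

Patient tissue is replaced by a **synthetic phantom**: tumour-cell
aggregates (keratinised cores, collagen rims) embedded in DNA-rich lymphoid
tissue, rendered both as a pseudo-H&E image (0.25 µm) and as an FTIR cube
(5.5 µm, 990–3798 cm⁻¹ at 4 cm⁻¹) through a linear mixing model with
baseline, Mie-like scatter and noise distortions — so every stage can be
scored against known ground truth.

## Worked example

```python
from ftirfuse.pipeline import run_pipeline, validate_config

res = run_pipeline(validate_config({"seed": 1}))
q = res["quality_report"]
b = res["amide_band_index"]
print("SSIM vs optical, fused amide band:   ", q["ssim_vs_pan_per_band"][b])
print("SSIM vs optical, bicubic amide band: ",
      q["ssim_vs_pan_reference_per_band"][b])
print("Wald mean SAM (rad):", q["wald_sam_mean"])
```

prints (default 1012×1012 scene, 46×46 FTIR grid):

```
SSIM vs optical, fused amide band:    0.4754750123266725
SSIM vs optical, bicubic amide band:  0.25385184664172195
Wald mean SAM (rad): 0.0052548030107864895
```

— fusion roughly doubles the structural agreement with the optical image at
the amide I band while degrading the fused cube back to the FTIR grid
reproduces the measured spectra to ~0.005 rad mean spectral angle. The
ratio discriminant on the same run separates lymphoid from tumour pixels
with sensitivity 0.952 and specificity 0.955 (mean ratio 2.93 in lymphoid
vs 1.20 in tumour).

The numbered drivers under `analysis/` run the same stages step by step
(`01_generate_phantom.py` … `05_unmix_and_ratio.py`), writing summary
tables to `results/` and large intermediates to `scratch/`. A CLI is also
installed: `ftirfuse pipeline --seed 1 --out DIR`, plus per-stage
subcommands (`phantom`, `preprocess`, `fuse`, `quality`, `cluster`,
`ratio`, `unmix`).

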