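"""Image- and spectrum-level quality metrics for fusion assessment.

SSIM quantifies spatial correlation between the fused bands and the optical
image (1 = identical); the spectral angle mapper (SAM) quantifies spectral
distortion of the fused cube against the FTIR reference (0 = identical,
scale-invariant); PSNR and MSE complete the standard set.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .cubeio import HyperCube, PixelMask

__all__ = ["ssim", "sam", "mse", "psnr", "fusion_quality_report"]


def ssim(
    img_a: np.ndarray,
    img_b: np.ndarray,
    data_range: float | None = None,
    win_size: int = 7,
    gaussian_weights: bool = True,
) -> float:
    """Mean structural similarity index over sliding windows.

    Standard luminance-contrast-structure product with K1=0.01, K2=0.03 and
    a 7-pixel window (Gaussian-weighted by default).  ``data_range`` defaults
    to the joint value range of the two images.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(
        structural_similarity(
            a,
            b,
            win_size=win_size,
            gaussian_weights=gaussian_weights,
            data_range=data_range,
        )
    )


def sam(
    cube_a: HyperCube, cube_b: HyperCube, mask: PixelMask | None = None
) -> tuple[np.ndarray, float]:
    """Spectral angle (radians) per pixel and its mean over unmasked pixels.

    ``angle = arccos(<a, b> / (|a||b|))`` clamped to [0, pi]; zero-norm
    spectra are excluded (NaN in the map) and skipped by the mean.
    """
    if cube_a.data.shape != cube_b.data.shape:
        raise ValueError("cubes must share a grid")
    if not np.allclose(cube_a.axis, cube_b.axis):
        raise ValueError("cubes must share a wavenumber axis")
    a = cube_a.spectra()
    b = cube_b.spectra()
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    valid = (na > 0) & (nb > 0)
    cos = np.full(a.shape[0], np.nan)
    dot = np.einsum("ij,ij->i", a, b)
    cos[valid] = np.clip(dot[valid] / (na[valid] * nb[valid]), -1.0, 1.0)
    angles = np.arccos(cos).reshape(cube_a.spatial_shape)
    sel = mask.mask if mask is not None else np.ones(cube_a.spatial_shape, bool)
    vals = angles[sel & np.isfinite(angles)]
    mean = float(vals.mean()) if vals.size else float("nan")
    return angles, mean


def mse(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Mean squared difference between two equal-shape images."""
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    return float(np.mean((a - b) ** 2))


def psnr(img_a: np.ndarray, img_b: np.ndarray, peak: float) -> float:
    """Peak signal-to-noise ratio in dB; infinite for identical images."""
    if peak <= 0:
        raise ValueError("peak must be positive")
    err = mse(img_a, img_b)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def _p95_rescale(img: np.ndarray) -> np.ndarray:
    p = np.percentile(img, 95)
    return np.clip(img, None, p) / p if p > 0 else img


def _zscore(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    return (img - img.mean()) / sd if sd > 0 else img - img.mean()


def fusion_quality_report(
    fused: HyperCube,
    reference: HyperCube,
    pan: np.ndarray | None = None,
    mask: PixelMask | None = None,
    rescale_p95: bool = True,
) -> dict:
    """Per-band SSIM/PSNR/MSE against the reference plus the SAM summary.

    Band images are rescaled to their 95th percentile before SSIM (the
    display convention) unless ``rescale_p95`` is false.  When ``pan`` is
    given, SSIM of each fused band and each reference band against the pan
    image is also reported; those comparisons are computed on z-scored
    images because the pan is in standardised units while absorbance bands
    are not.
    """
    n = fused.nbands
    ssim_ref = np.empty(n)
    ssim_pan = np.empty(n) if pan is not None else None
    ssim_pan_ref = np.empty(n) if pan is not None else None
    psnr_b = np.empty(n)
    mse_b = np.empty(n)
    prep = _p95_rescale if rescale_p95 else (lambda x: x)
    pan_z = _zscore(np.asarray(pan, dtype=np.float64)) if pan is not None else None
    for b in range(n):
        fb = fused.data[:, :, b]
        rb = reference.data[:, :, b]
        ssim_ref[b] = ssim(prep(fb), prep(rb))
        mse_b[b] = mse(fb, rb)
        peak = max(rb.max(), 1e-12)
        psnr_b[b] = psnr(fb, rb, peak)
        if pan_z is not None:
            ssim_pan[b] = ssim(_zscore(fb), pan_z)
            ssim_pan_ref[b] = ssim(_zscore(rb), pan_z)
    sam_map, sam_mean = sam(fused, reference, mask)
    report = {
        "ssim_per_band": ssim_ref,
        "psnr_per_band": psnr_b,
        "mse_per_band": mse_b,
        "sam_map": sam_map,
        "sam_mean": sam_mean,
    }
    if pan_z is not None:
        report["ssim_vs_pan_per_band"] = ssim_pan
        report["ssim_vs_pan_reference_per_band"] = ssim_pan_ref
    return report
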