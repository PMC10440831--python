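"""Regression pansharpening of FTIR cubes with a high-resolution pan image.

The pan channel is the greyscale of the optical (H&E-style) image,
standardised to zero mean and unit standard deviation.  The fusion model is
classic regression pansharpening: for each band, ordinary least squares of
the low-resolution band on the pan image degraded to the FTIR grid yields a
gain; the fused band is the bicubically upsampled band plus gain times the
pan detail (high-resolution pan minus its degraded-and-upsampled self).
Spectral distortion is then minimised by equalising each fused band's mean
and standard deviation to the upsampled FTIR reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cubeio import HyperCube, PixelMask
from .phantom import degrade_map

__all__ = [
    "GrayImage",
    "FusionModel",
    "upsample_bicubic",
    "grayscale_standardise",
    "degrade_to_lowres",
    "degrade_cube",
    "fit_fusion_model",
    "apply_fusion",
    "equalise_to_reference",
]

#: Luminance weights for RGB -> grey conversion.
GREY_WEIGHTS = (0.299, 0.587, 0.114)

_MAX_UPSAMPLE = 1000.0


@dataclass
class GrayImage:
    """Single-channel image with physical pixel size (um)."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("grey image must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class FusionModel:
    """Per-band regression gains/intercepts tying bands to the pan image."""

    gains: np.ndarray
    intercepts: np.ndarray
    pan_lowres: GrayImage

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        if self.gains.shape != self.intercepts.shape:
            raise ValueError("gains and intercepts must align")
        if not (np.all(np.isfinite(self.gains)) and np.all(np.isfinite(self.intercepts))):
            raise ValueError("fusion model contains non-finite coefficients")


def _zoom2d(arr: np.ndarray, factor: float) -> np.ndarray:
    return ndimage.zoom(arr, factor, order=3, mode="nearest", grid_mode=True)


def upsample_bicubic(cube: HyperCube, target_pixel_size: float) -> HyperCube:
    """Bicubically interpolate every band onto a finer grid (pixel centres)."""
    if not target_pixel_size > 0:
        raise ValueError("target_pixel_size must be positive")
    if target_pixel_size >= cube.pixel_size:
        raise ValueError("target pixel size must be finer than the cube's")
    factor = cube.pixel_size / target_pixel_size
    if factor > _MAX_UPSAMPLE:
        raise ValueError(f"upsampling factor {factor:.0f} exceeds guard")
    out = ndimage.zoom(
        cube.data, (factor, factor, 1), order=3, mode="nearest", grid_mode=True
    )
    return HyperCube(out, cube.axis, target_pixel_size)


def upsample_gray(image: GrayImage, target_pixel_size: float) -> GrayImage:
    """Bicubic upsampling of a grey image (same convention as the cube)."""
    factor = image.pixel_size / target_pixel_size
    if factor <= 1:
        raise ValueError("target pixel size must be finer than the image's")
    return GrayImage(_zoom2d(image.values, factor), target_pixel_size)


def grayscale_standardise(
    rgb: np.ndarray, mask: PixelMask | None = None, pixel_size: float = 1.0
) -> GrayImage:
    """Luminance greyscale, z-scored over unmasked pixels.

    Raises ``ValueError`` on a constant (zero-variance) image.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim == 3 and rgb.shape[2] == 3:
        grey = rgb @ np.asarray(GREY_WEIGHTS)
    elif rgb.ndim == 2:
        grey = rgb.copy()
    else:
        raise ValueError("expected an RGB (rows, cols, 3) or 2-D image")
    sel = mask.mask if mask is not None else np.ones(grey.shape, dtype=bool)
    mu = grey[sel].mean()
    sd = grey[sel].std()
    if sd == 0:
        raise ValueError("image has zero variance; cannot standardise")
    return GrayImage((grey - mu) / sd, pixel_size)


def degrade_to_lowres(
    image: GrayImage, target_pixel_size: float, psf_sigma: float | None = None
) -> GrayImage:
    """Gaussian blur then block-average a grey image onto a coarser grid.

    ``psf_sigma`` is in micrometres and defaults to half the target pixel
    size.  The size ratio must be an integer so block averaging is exact.
    """
    if target_pixel_size <= image.pixel_size:
        raise ValueError("target pixel size must be coarser than the image's")
    ratio = target_pixel_size / image.pixel_size
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6:
        raise ValueError("pixel size ratio must be an integer")
    sigma = 0.5 * target_pixel_size if psf_sigma is None else psf_sigma
    out = degrade_map(image.values, factor, sigma / image.pixel_size)
    return GrayImage(out, target_pixel_size)


def degrade_cube(
    cube: HyperCube, target_pixel_size: float, psf_sigma: float | None = None
) -> HyperCube:
    """Band-wise blur + block-average of a cube onto a coarser grid."""
    if target_pixel_size <= cube.pixel_size:
        raise ValueError("target pixel size must be coarser than the cube's")
    ratio = target_pixel_size / cube.pixel_size
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6:
        raise ValueError("pixel size ratio must be an integer")
    sigma = 0.5 * target_pixel_size if psf_sigma is None else psf_sigma
    out = degrade_map(cube.data, factor, sigma / cube.pixel_size)
    return HyperCube(out, cube.axis, target_pixel_size)


def fit_fusion_model(
    cube_lowres: HyperCube, pan: GrayImage, mask: PixelMask | None = None
) -> FusionModel:
    """Per-band OLS of band absorbance on the degraded pan image.

    ``pan`` must live on the cube's grid.  Returns gains and intercepts per
    band; raises on a degenerate (constant) pan image.
    """
    if pan.values.shape != cube_lowres.spatial_shape:
        raise ValueError("pan image and cube grids differ")
    sel = (
        mask.mask.ravel()
        if mask is not None
        else np.ones(cube_lowres.spatial_shape, dtype=bool).ravel()
    )
    if sel.sum() < 2:
        raise ValueError("need at least 2 unmasked pixels to fit")
    p = pan.values.ravel()[sel]
    var_p = p.var()
    if var_p == 0:
        raise ValueError("pan image is constant over unmasked pixels")
    bands = cube_lowres.spectra()[sel]  # (npix, nbands)
    p_c = p - p.mean()
    gains = (p_c @ (bands - bands.mean(axis=0))) / (p_c @ p_c)
    intercepts = bands.mean(axis=0) - gains * p.mean()
    return FusionModel(gains, intercepts, pan)


def apply_fusion(
    model: FusionModel, cube_up: HyperCube, pan_hr: GrayImage
) -> HyperCube:
    """Inject pan detail into the upsampled cube band by band.

    ``fused_b = cube_up_b + g_b * (pan_hr - pan_lr_up)`` where ``pan_lr_up``
    is the model's degraded pan upsampled back to the high-resolution grid.
    With no high-frequency detail (``pan_hr == pan_lr_up``) the fused cube
    equals the upsampled cube.
    """
    if pan_hr.values.shape != cube_up.spatial_shape:
        raise ValueError("pan image and upsampled cube grids differ")
    pan_lr_up = upsample_gray(model.pan_lowres, cube_up.pixel_size)
    if pan_lr_up.values.shape != pan_hr.values.shape:
        raise ValueError(
            "degraded pan does not upsample onto the cube grid; "
            f"{pan_lr_up.values.shape} vs {pan_hr.values.shape}"
        )
    dt = cube_up.data.dtype
    detail = (pan_hr.values - pan_lr_up.values).astype(dt)
    fused = cube_up.data + detail[:, :, None] * model.gains.astype(dt)[None, None, :]
    return HyperCube(fused, cube_up.axis, cube_up.pixel_size)


def enforce_spectral_consistency(
    fused: HyperCube, cube_lowres: HyperCube, psf_sigma: float = 0.0
) -> HyperCube:
    """Project the fused cube onto the Wald-consistency constraint.

    Adds back the upsampled low-resolution residual so that degrading the
    result reproduces the native FTIR cube (up to interpolation error):
    ``fused + upsample(cube_lowres - degrade(fused))``.  Combined with
    moment-matching equalisation this nets out to a per-band damping of the
    injected pan detail: spectral content at the FTIR scale is preserved
    exactly while high-frequency detail keeps the equalised amplitude.
    """
    resid = HyperCube(
        cube_lowres.data
        - degrade_cube(fused, cube_lowres.pixel_size, psf_sigma=psf_sigma).data,
        cube_lowres.axis,
        cube_lowres.pixel_size,
    )
    dt = fused.data.dtype
    correction = ndimage.zoom(
        resid.data.astype(dt),
        (cube_lowres.pixel_size / fused.pixel_size,) * 2 + (1,),
        order=3,
        mode="nearest",
        grid_mode=True,
    )
    out = fused.data + correction
    return HyperCube(out, fused.axis, fused.pixel_size)


def equalise_to_reference(
    fused: HyperCube, reference: HyperCube, mask: PixelMask | None = None
) -> tuple[HyperCube, list[int]]:
    """Affine-rescale each fused band to the reference band's mean and sd.

    The moment matching is computed over unmasked pixels and undoes any
    per-band affine distortion introduced by fusion, minimising spectral
    distortion relative to the FTIR reference.  A zero-variance fused band
    facing a non-constant reference cannot be rescaled: it is set to the
    reference mean and its index returned in the flagged list.
    """
    if fused.data.shape != reference.data.shape:
        raise ValueError("fused and reference cubes must share a grid")
    sel = (
        mask.mask
        if mask is not None
        else np.ones(fused.spatial_shape, dtype=bool)
    )
    f = fused.spectra()[sel.ravel()]
    r = reference.spectra()[sel.ravel()]
    mu_f, sd_f = f.mean(axis=0), f.std(axis=0)
    mu_r, sd_r = r.mean(axis=0), r.std(axis=0)
    # a numerically constant band has sd at rounding level, not exactly 0
    degenerate = sd_f <= 1e-12 * np.maximum(1.0, np.abs(mu_f))
    flagged = [int(b) for b in np.flatnonzero(degenerate & (sd_r > 0))]
    scale = np.where(~degenerate, sd_r / np.where(degenerate, 1.0, sd_f), 0.0)
    dt = fused.data.dtype
    out = (fused.data - mu_f.astype(dt)) * scale.astype(dt) + mu_r.astype(dt)
    return HyperCube(out, fused.axis, fused.pixel_size), flagged
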