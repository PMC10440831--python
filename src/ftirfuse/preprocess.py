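"""Spectral preprocessing chain for FTIR tissue datacubes.

The chain runs in a fixed order: rubber-band baseline correction, PCA noise
reduction, EMSC scattering correction, amide-I quality test, truncation of
paraffin-dominated windows plus restriction to the fingerprint region, and
finally vector normalisation.  Each stage is exposed as a standalone
function; :func:`preprocess_pipeline` wires them together and reports
per-stage band and usable-pixel counts.

Quality gate: a pixel is usable iff its maximum absorbance over the amide I
window (1600-1700 cm^-1) lies in [0.1, 2.0], boundaries retained.  Paraffin
windows (1350-1500 and 2835-3000 cm^-1) are open intervals, so bands exactly
on a window edge survive truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cubeio import HyperCube, PixelMask

__all__ = [
    "PreprocessConfig",
    "rubberband_baseline",
    "lower_hull_baseline",
    "denoise",
    "emsc_mie_correct",
    "mie_extinction_basis",
    "quality_filter",
    "truncate_paraffin_and_fingerprint",
    "vector_normalise",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Preprocessing constants; defaults follow the acquisition protocol."""

    amide_window: tuple[float, float] = (1600.0, 1700.0)
    quality_lo: float = 0.1
    quality_hi: float = 2.0
    paraffin_windows: tuple[tuple[float, float], ...] = (
        (1350.0, 1500.0),
        (2835.0, 3000.0),
    )
    fingerprint: tuple[float, float] = (900.0, 1800.0)
    denoise_components: int = 20
    emsc_iterations: int = 1

    def __post_init__(self) -> None:
        if not self.quality_lo < self.quality_hi:
            raise ValueError("quality_lo must be below quality_hi")
        for lo, hi in (self.amide_window, self.fingerprint, *self.paraffin_windows):
            if not lo < hi:
                raise ValueError(f"window [{lo}, {hi}] is not increasing")


# ---------------------------------------------------------------------------
# Rubber-band baseline
# ---------------------------------------------------------------------------

def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Monotone-chain lower convex hull of points sorted by x."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # drop i2 if it lies on or above the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def lower_hull_baseline(axis: np.ndarray, values: np.ndarray) -> np.ndarray:
    """The rubber-band baseline: the lower convex hull evaluated on ``axis``."""
    idx = _lower_hull_indices(axis, values)
    return np.interp(axis, axis[idx], values[idx])


def rubberband_baseline(values: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Subtract the lower convex hull ("rubber band") from one spectrum.

    The corrected spectrum is zero at hull vertices (including both
    endpoints) and nonnegative up to floating-point error; the operation is
    idempotent.
    """
    axis = np.asarray(axis, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("rubber-band correction needs at least 2 points")
    if not (np.all(np.isfinite(values)) and np.all(np.isfinite(axis))):
        raise ValueError("spectrum contains non-finite values")
    return values - lower_hull_baseline(axis, values)


def _rubberband_cube(cube: HyperCube) -> HyperCube:
    flat = cube.spectra()
    out = np.empty_like(flat)
    for i in range(flat.shape[0]):
        out[i] = rubberband_baseline(flat[i], cube.axis)
    return HyperCube(out.reshape(cube.data.shape), cube.axis, cube.pixel_size)


# ---------------------------------------------------------------------------
# PCA noise reduction
# ---------------------------------------------------------------------------

def denoise(cube: HyperCube, k: int, mask: PixelMask | None = None) -> HyperCube:
    """Reconstruct every spectrum from the top-``k`` principal components.

    The PCA basis is fitted on the (optionally masked) pixel-spectrum matrix
    after mean centring; ``k`` equal to the band count is the identity.
    """
    if not 1 <= k <= cube.nbands:
        raise ValueError(f"k={k} outside [1, {cube.nbands}]")
    flat = cube.spectra()
    fit_rows = flat[mask.mask.ravel()] if mask is not None else flat
    mean = fit_rows.mean(axis=0)
    centred = fit_rows - mean
    # right singular vectors = principal axes in band space
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    basis = vt[: min(k, vt.shape[0])]
    recon = mean + (flat - mean) @ basis.T @ basis
    return HyperCube(recon.reshape(cube.data.shape), cube.axis, cube.pixel_size)


# ---------------------------------------------------------------------------
# EMSC scattering correction
# ---------------------------------------------------------------------------

def mie_extinction_basis(axis: np.ndarray, n_freqs: int = 3) -> np.ndarray:
    """Fixed smooth basis of Mie-like extinction curves.

    Sine/cosine pairs with 1..``n_freqs`` periods across the axis — broad
    oscillatory-in-wavenumber shapes standing in for the Mie ripple.
    Returns ``(bands, 2*n_freqs)``.
    """
    axis = np.asarray(axis, dtype=np.float64)
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    cols = []
    for k in range(1, n_freqs + 1):
        cols.append(np.sin(2 * np.pi * k * t))
        cols.append(np.cos(2 * np.pi * k * t))
    return np.column_stack(cols)


def _chem_complement(ref: np.ndarray, constituents: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the constituent span orthogonal to ``ref``."""
    stack = np.column_stack([ref, constituents])
    q, r = np.linalg.qr(stack)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    keep[0] = False  # drop the ref direction itself
    return q[:, keep]


def emsc_mie_correct(
    cube: HyperCube,
    n_iterations: int = 1,
    mask: PixelMask | None = None,
    constituents: np.ndarray | None = None,
    c_floor: float = 1e-6,
) -> tuple[HyperCube, np.ndarray]:
    """Extended multiplicative signal correction with a Mie-like basis.

    Each spectrum ``s`` is fitted as ``c*m + a + b*t + sum_i g_i E_i`` where
    ``m`` is the usable-pixel mean spectrum, ``t`` the normalised wavenumber
    and ``E_i`` the fixed extinction basis; the corrected spectrum is
    ``(s - a - b*t - sum g_i E_i) / c``.  Iterating replaces ``m`` with the
    corrected mean.  Pixels whose multiplicative constant ``c`` falls below
    ``c_floor`` are left unchanged and flagged rather than divided.

    ``constituents`` (a ``(bands, m)`` matrix of known component spectra,
    e.g. the molecular reference spectra) optionally augments the design with
    the chemical subspace orthogonal to ``m``; those contributions are kept,
    not subtracted, so genuine chemical deviations from the mean cannot leak
    into the smooth interference terms and clean spectra pass through
    undistorted (up to the multiplicative rescale).

    Returns ``(corrected_cube, flagged)`` with ``flagged`` a boolean
    (rows, cols) array of pixels that could not be corrected.
    """
    if cube.nbands < 2:
        raise ValueError("EMSC needs at least 2 bands")
    flat = cube.spectra().copy()
    usable = (
        mask.mask.ravel() if mask is not None else np.ones(flat.shape[0], dtype=bool)
    )
    t = (cube.axis - cube.axis[0]) / (cube.axis[-1] - cube.axis[0])
    basis = mie_extinction_basis(cube.axis)
    flagged = np.zeros(flat.shape[0], dtype=bool)
    for _ in range(int(n_iterations)):
        ref = flat[usable & ~flagged].mean(axis=0)
        chem = (
            _chem_complement(ref, constituents)
            if constituents is not None
            else np.empty((cube.nbands, 0))
        )
        n_chem = chem.shape[1]
        design = np.column_stack([ref, chem, np.ones_like(t), t, basis])
        coef, *_ = np.linalg.lstsq(design, flat.T, rcond=None)  # (p, npix)
        c = coef[0]
        interference = design[:, 1 + n_chem :] @ coef[1 + n_chem :]  # (bands, npix)
        bad = c < c_floor
        good = ~bad
        c_safe = np.where(bad, 1.0, c)
        flat[good] = ((flat.T - interference) / c_safe)[:, good].T
        flagged |= bad
    out = HyperCube(flat.reshape(cube.data.shape), cube.axis, cube.pixel_size)
    return out, flagged.reshape(cube.spatial_shape)


# ---------------------------------------------------------------------------
# Quality filter, truncation, normalisation
# ---------------------------------------------------------------------------

def quality_filter(cube: HyperCube, config: PreprocessConfig | None = None) -> PixelMask:
    """Amide I quality gate: keep pixels with band maximum in [lo, hi].

    The amide I statistic is the maximum absorbance over the configured
    window (default 1600-1700 cm^-1); boundary values are retained.
    """
    cfg = config or PreprocessConfig()
    lo, hi = cfg.amide_window
    in_window = (cube.axis >= lo) & (cube.axis <= hi)
    if not in_window.any():
        raise ValueError(f"amide window [{lo}, {hi}] cm^-1 outside the cube axis")
    amide = cube.data[:, :, in_window].max(axis=2)
    return PixelMask((amide >= cfg.quality_lo) & (amide <= cfg.quality_hi))


def truncate_paraffin_and_fingerprint(
    cube: HyperCube, config: PreprocessConfig | None = None
) -> HyperCube:
    """Drop paraffin-dominated windows and restrict to the fingerprint region.

    Retains bands with ``900 <= nu <= 1800`` (inclusive) that fall in no
    paraffin window; paraffin windows are open intervals, so bands exactly at
    a window edge survive.  Pure band selection — retained values are
    untouched.
    """
    cfg = config or PreprocessConfig()
    lo, hi = cfg.fingerprint
    keep = (cube.axis >= lo) & (cube.axis <= hi)
    for wlo, whi in cfg.paraffin_windows:
        keep &= ~((cube.axis > wlo) & (cube.axis < whi))
    if not keep.any():
        raise ValueError("truncation would remove every band")
    return HyperCube(cube.data[:, :, keep], cube.axis[keep], cube.pixel_size)


def vector_normalise(
    cube: HyperCube, mask: PixelMask | None = None
) -> tuple[HyperCube, PixelMask]:
    """Scale each usable spectrum to unit Euclidean norm.

    Zero-norm spectra cannot be normalised: they are added to the removed
    set (mask set false) and left untouched.  Returns the normalised cube
    and the updated mask.
    """
    m = (
        mask.mask.copy()
        if mask is not None
        else np.ones(cube.spatial_shape, dtype=bool)
    )
    flat = cube.spectra().copy()
    norms = np.linalg.norm(flat, axis=1)
    zero = norms == 0
    m &= ~zero.reshape(cube.spatial_shape)
    ok = m.ravel()
    flat[ok] = flat[ok] / norms[ok, None]
    out = HyperCube(flat.reshape(cube.data.shape), cube.axis, cube.pixel_size)
    return out, PixelMask(m)


def preprocess_pipeline(
    cube: HyperCube,
    config: PreprocessConfig | None = None,
    constituents: np.ndarray | None = None,
) -> tuple[HyperCube, PixelMask, dict]:
    """Run the six-stage preprocessing chain in its fixed order.

    Order: rubber-band correction, noise reduction, scattering correction,
    quality test, paraffin/fingerprint truncation, vector normalisation.
    ``constituents`` (known component spectra on the cube axis) is forwarded
    to the EMSC stage.  Returns the processed cube, the usable-pixel mask,
    and a report listing per-stage band and usable-pixel counts.
    """
    cfg = config or PreprocessConfig()
    mask = PixelMask(np.ones(cube.spatial_shape, dtype=bool))
    stages: list[dict] = []

    def log(name: str, c: HyperCube) -> None:
        stages.append(
            {"stage": name, "bands": c.nbands, "usable_pixels": mask.n_usable}
        )

    cube = _rubberband_cube(cube)
    log("rubberband", cube)

    k = min(cfg.denoise_components, cube.nbands)
    cube = denoise(cube, k)
    log("denoise", cube)

    cube, flagged = emsc_mie_correct(
        cube, n_iterations=cfg.emsc_iterations, constituents=constituents
    )
    mask = PixelMask(mask.mask & ~flagged)
    log("emsc", cube)

    mask = PixelMask(mask.mask & quality_filter(cube, cfg).mask)
    log("quality_filter", cube)

    cube = truncate_paraffin_and_fingerprint(cube, cfg)
    log("truncate", cube)

    cube, mask = vector_normalise(cube, mask)
    log("vector_normalise", cube)

    report = {"stages": stages, "n_stages": len(stages)}
    return cube, mask, report
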