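"""Spectral clustering, the 1252/1285 ratio discriminant, and molecular
least-squares unmixing of fused FTIR spectra.

Each pixel spectrum is fitted as a nonnegative combination of reference
molecular spectra (cytokeratin, collagen, ds-DNA by default); coefficients
form abundance maps, the reduced residual chi^2 flags bad fits, and the
abundances render as an RGB composite (cytokeratin red, collagen green,
ds-DNA blue) scaled to each channel's 95th percentile.  The ratio of
absorbances at 1252 cm^-1 (DNA-dominated) over 1285 cm^-1
(collagen-dominated) discriminates lymphoid tissue (high ratio, densely
packed nuclei) from metastatic tumour (low ratio, keratin/collagen rich).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .cubeio import HyperCube, PixelMask
from .phantom import ReferenceSpectra

__all__ = [
    "ClusterResult",
    "UnmixResult",
    "kmeans_spectra",
    "band_image",
    "ratio_image",
    "lsf_unmix",
    "rgb_composite",
    "ratio_to_rgb",
]


@dataclass
class ClusterResult:
    """k-means clustering of pixel spectra.

    ``labels`` is per-pixel with -1 at masked pixels; ``centroids`` are the
    member-mean spectra (one row per cluster); ``counts`` the member counts.
    """

    labels: np.ndarray
    centroids: np.ndarray
    counts: np.ndarray
    seed: int
    inertia: float


@dataclass
class UnmixResult:
    """Per-molecule abundance maps with goodness of fit."""

    abundance: np.ndarray    # (rows, cols, molecules)
    chi2: np.ndarray         # (rows, cols) reduced residual
    fit_mask: np.ndarray     # True = good fit (and usable pixel)
    molecules: tuple[str, ...]
    chi2_threshold: float
    chosen_bands: dict = field(default_factory=dict)


def kmeans_spectra(
    cube: HyperCube, mask: PixelMask | None = None, k: int = 3, seed: int = 0
) -> ClusterResult:
    """k-means (k-means++ init, fixed seed) on unmasked pixel spectra.

    Deterministic given the seed.  Returned centroids are recomputed as the
    member-mean spectra, so each centroid equals the mean of its members
    exactly.
    """
    sel = (
        mask.mask.ravel()
        if mask is not None
        else np.ones(cube.spatial_shape, dtype=bool).ravel()
    )
    spectra = cube.spectra()[sel]
    if k < 1:
        raise ValueError("k must be >= 1")
    if spectra.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {spectra.shape[0]} unmasked pixels")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=int(seed))
    member_labels = km.fit_predict(spectra)
    labels = np.full(sel.shape, -1, dtype=int)
    labels[sel] = member_labels
    counts = np.bincount(member_labels, minlength=k)
    centroids = np.vstack(
        [spectra[member_labels == j].mean(axis=0) for j in range(k)]
    )
    return ClusterResult(
        labels.reshape(cube.spatial_shape),
        centroids,
        counts,
        int(seed),
        float(km.inertia_),
    )


def band_image(cube: HyperCube, wavenumber: float) -> tuple[np.ndarray, float]:
    """Absorbance image at the band nearest ``wavenumber``.

    Ties between equidistant bands go to the lower wavenumber.  Returns the
    image and the wavenumber actually used (logged so the discriminant is
    reproducible on any grid).
    """
    idx = cube.band_index(wavenumber)
    return cube.data[:, :, idx].copy(), float(cube.axis[idx])


def ratio_image(
    cube: HyperCube,
    nu_num: float = 1252.0,
    nu_den: float = 1285.0,
    mask: PixelMask | None = None,
    eps: float = 1e-6,
) -> tuple[np.ndarray, dict]:
    """Per-pixel absorbance ratio A(nu_num)/max(A(nu_den), eps).

    Masked pixels carry NaN (rendered white downstream).  Returns the ratio
    map and a log of the bands actually used.
    """
    if eps <= 0:
        raise ValueError("denominator floor eps must be positive")
    num, used_num = band_image(cube, nu_num)
    den, used_den = band_image(cube, nu_den)
    ratio = num / np.maximum(den, eps)
    if mask is not None:
        ratio = np.where(mask.mask, ratio, np.nan)
    return ratio, {"numerator_band": used_num, "denominator_band": used_den}


def _nnls_batch(R: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Nonnegative least squares per row of S against columns of R.

    Fast path: unconstrained least squares for all rows; rows with any
    negative coefficient are re-solved with active-set NNLS.
    """
    coef, *_ = np.linalg.lstsq(R.astype(S.dtype), S.T, rcond=None)
    coef = coef.T.astype(np.float64)  # (npix, m)
    tol = -1e-9 if S.dtype == np.float32 else -1e-12
    bad = np.flatnonzero((coef < tol).any(axis=1))
    for i in bad:
        coef[i], _ = nnls(R, S[i].astype(np.float64))
    return np.clip(coef, 0.0, None)


def lsf_unmix(
    cube: HyperCube,
    refs: ReferenceSpectra,
    mask: PixelMask | None = None,
    chi2_threshold: float | None = None,
    nonneg: bool = True,
) -> UnmixResult:
    """Pixel-by-pixel least-squares fit of spectra to the reference spectra.

    Solves ``min |s - R c|^2`` (subject to ``c >= 0`` unless ``nonneg`` is
    false) per pixel; ``chi2`` is the residual sum of squares divided by
    ``bands - molecules``.  ``fit_mask`` is true where ``chi2 <=
    chi2_threshold`` and the pixel is usable; the default threshold is ten
    times the median chi^2 over usable pixels.
    """
    R = refs.resample(cube.axis).values  # (bands, m)
    m = R.shape[1]
    if cube.nbands < m + 1:
        raise ValueError("need more bands than reference molecules")
    if np.linalg.matrix_rank(R) < m:
        raise ValueError("reference spectra matrix is rank deficient")
    if chi2_threshold is not None and chi2_threshold <= 0:
        raise ValueError("chi2_threshold must be positive")

    S = cube.spectra()
    if nonneg:
        coef = _nnls_batch(R, S)
    else:
        coef, *_ = np.linalg.lstsq(R, S.T, rcond=None)
        coef = coef.T
    resid = S - coef.astype(S.dtype) @ R.T.astype(S.dtype)
    dof = cube.nbands - m
    chi2 = np.einsum("ij,ij->i", resid, resid, dtype=np.float64) / dof
    del resid

    usable = (
        mask.mask
        if mask is not None
        else np.ones(cube.spatial_shape, dtype=bool)
    )
    chi2_map = chi2.reshape(cube.spatial_shape)
    if chi2_threshold is None:
        med = np.median(chi2_map[usable]) if usable.any() else 0.0
        chi2_threshold = 10.0 * med if med > 0 else np.inf
    fit_mask = (chi2_map <= chi2_threshold) & usable
    return UnmixResult(
        coef.reshape(cube.spatial_shape + (m,)),
        chi2_map,
        fit_mask,
        tuple(refs.names),
        float(chi2_threshold),
    )


#: Default molecule -> display channel assignment.
CHANNEL_ORDER = ("cytokeratin", "collagen", "dna")  # -> (R, G, B)


def rgb_composite(
    result: UnmixResult,
    percentile: float = 95.0,
    channel_order: tuple[str, str, str] = CHANNEL_ORDER,
) -> np.ndarray:
    """Render abundances as RGB, each channel scaled to its 95th percentile.

    Channel values are ``clip(abundance, 0, p)/p`` with ``p`` the channel's
    ``percentile`` over good-fit pixels; bad-fit pixels render black.
    """
    if not result.fit_mask.any():
        raise ValueError("no good-fit pixels to render")
    rows, cols, _ = result.abundance.shape
    out = np.zeros((rows, cols, 3))
    for ch, name in enumerate(channel_order):
        idx = result.molecules.index(name)
        ab = result.abundance[:, :, idx]
        p = np.percentile(ab[result.fit_mask], percentile)
        if p > 0:
            out[:, :, ch] = np.clip(ab, 0.0, p) / p
    out[~result.fit_mask] = 0.0
    return out


def ratio_to_rgb(ratio: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Greyscale RGB rendering of a ratio map; NaN (masked) pixels are white."""
    finite = np.isfinite(ratio)
    out = np.ones(ratio.shape + (3,))
    if finite.any():
        p = np.percentile(ratio[finite], percentile)
        scaled = np.clip(ratio, 0.0, p) / p if p > 0 else np.zeros_like(ratio)
        for ch in range(3):
            out[:, :, ch] = np.where(finite, scaled, 1.0)
    return out
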