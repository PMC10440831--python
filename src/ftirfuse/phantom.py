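"""Synthetic tissue phantoms with known ground truth.

The generator emulates the scene the fusion analysis assumes: metastatic
tumour-cell aggregates — disc-like regions with keratinised (cytokeratin-rich)
cores and collagen-rich rims — embedded in lymphoid tissue whose speckled
nuclei are DNA-rich.  Each scene carries per-molecule ground-truth abundance
maps on a fine optical grid (default 0.25 um); the FTIR forward model blurs
and block-averages those maps onto a coarse grid (default 5.5 um), multiplies
by reference spectra, and adds a smooth convex baseline, a broad
sinusoidal-in-wavenumber scattering surrogate, and truncated Gaussian noise.

Reference spectra are parametric Gaussian-band surrogates with fixed named
band tables (no absolute absorbance scale exists for the real molecular
spectra, so units are arbitrary); the ds-DNA band dominating the
1200-1320 cm^-1 window sits at 1252 cm^-1 and the collagen band at
1285 cm^-1, which is what makes the 1252/1285 ratio discriminant work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .cubeio import AffineTransform, HyperCube

__all__ = [
    "ReferenceSpectra",
    "PhantomScene",
    "make_reference_spectra",
    "make_scene",
    "render_pseudo_he",
    "render_ftir",
    "misregister",
    "default_axis",
    "MOLECULES",
    "CLASS_NAMES",
    "CLASS_ABUNDANCE",
    "REFERENCE_BANDS",
]

MOLECULES = ("cytokeratin", "collagen", "dna")

#: Integer class labels used in every label map.
CLASS_NAMES = {
    0: "background",
    1: "lymphoid",
    2: "tumour",
    3: "keratinised_core",
    4: "collagen_rim",
}

#: Gaussian band tables (centre cm^-1, amplitude a.u., sigma cm^-1) for the
#: three molecular reference spectra.  Amplitudes are arbitrary units; the
#: dominant 1200-1320 cm^-1 bands are pinned at 1252 (ds-DNA) and 1285
#: (collagen), and both proteins carry a strong amide I band near 1650 cm^-1.
REFERENCE_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "cytokeratin": (
        (1652.0, 1.00, 25.0),  # amide I
        (1545.0, 0.70, 22.0),  # amide II
        (1455.0, 0.30, 20.0),  # CH2/CH3 bending
        (1265.0, 0.12, 30.0),  # amide III (broad, weak)
        (1170.0, 0.08, 18.0),
    ),
    "collagen": (
        (1658.0, 1.00, 28.0),  # amide I
        (1550.0, 0.65, 24.0),  # amide II
        (1338.0, 0.20, 12.0),  # CH2 wagging (proline side chains)
        (1285.0, 0.55, 14.0),  # amide III, dominant in 1200-1320
        (1240.0, 0.15, 14.0),  # amide III shoulder
        (1080.0, 0.20, 20.0),
    ),
    "dna": (
        (1710.0, 0.20, 20.0),  # base carbonyl
        (1604.0, 0.15, 18.0),  # ring modes
        (1252.0, 0.80, 16.0),  # asymmetric phosphate, dominant in 1200-1320
        (1087.0, 0.90, 18.0),  # symmetric phosphate
        (965.0, 0.30, 12.0),   # backbone
    ),
}

#: Mean (cytokeratin, collagen, dna) abundance per tissue class.
CLASS_ABUNDANCE = {
    0: (0.00, 0.00, 0.00),
    1: (0.15, 0.25, 0.90),
    2: (0.55, 0.25, 0.25),
    3: (1.00, 0.10, 0.10),
    4: (0.15, 1.00, 0.15),
}

#: Default class area fractions (background implicit as the remainder).
DEFAULT_FRACTIONS = {1: 0.55, 2: 0.25, 3: 0.08, 4: 0.12}

#: Optical-density stain vectors (R, G, B) per molecule for the pseudo-H&E
#: rendering: DNA transmits purple, collagen pink, cytokeratin orange-pink.
_STAIN_OD = {
    "cytokeratin": (0.10, 0.70, 0.85),
    "collagen": (0.09, 0.95, 0.45),
    "dna": (0.40, 1.00, 0.35),
}

# The instrument's effective fingerprint coverage; reference spectra must
# span it so preprocessing and the ratio discriminant are well defined.
_REQUIRED_COVERAGE = (990.0, 1798.0)


def default_axis(lo: float = 990.0, hi: float = 3798.0, step: float = 4.0) -> np.ndarray:
    """The default acquisition wavenumber grid (cm^-1, ascending)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class ReferenceSpectra:
    """Reference molecular spectra on a common wavenumber axis.

    ``values`` is ``(bands, molecules)`` with columns ordered as ``names``.
    """

    axis: np.ndarray
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("reference axis must be strictly increasing")
        if self.values.shape != (self.axis.size, len(self.names)):
            raise ValueError("values must be (bands, molecules)")
        if np.any(self.values < 0):
            raise ValueError("reference spectra must be nonnegative")
        if np.any(np.all(self.values == 0, axis=0)):
            raise ValueError("reference spectra contain an all-zero column")

    def resample(self, axis: np.ndarray) -> "ReferenceSpectra":
        """Linear interpolation of every column onto ``axis``."""
        axis = np.asarray(axis, dtype=np.float64)
        vals = np.column_stack(
            [np.interp(axis, self.axis, self.values[:, j])
             for j in range(self.values.shape[1])]
        )
        return ReferenceSpectra(axis, self.names, vals)


@dataclass
class PhantomScene:
    """Ground-truth scene on the high-resolution optical grid."""

    label_map: np.ndarray          # (rows, cols) int class labels
    truth_abundance: np.ndarray    # (rows, cols, molecules) nonnegative
    pixel_size_hr: float           # um
    seed: int
    molecules: tuple[str, ...] = MOLECULES

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        self.truth_abundance = np.asarray(self.truth_abundance, dtype=np.float64)
        if self.label_map.shape != self.truth_abundance.shape[:2]:
            raise ValueError("label_map and truth_abundance shapes differ")
        if np.any(self.truth_abundance < 0):
            raise ValueError("truth abundances must be nonnegative")
        if not self.pixel_size_hr > 0:
            raise ValueError("pixel_size_hr must be positive")


def _gaussian_bands(axis: np.ndarray, bands, amp_jitter: np.ndarray) -> np.ndarray:
    out = np.zeros_like(axis)
    for (centre, amp, sigma), jit in zip(bands, amp_jitter):
        out += amp * jit * np.exp(-0.5 * ((axis - centre) / sigma) ** 2)
    return out


def make_reference_spectra(axis: np.ndarray, seed: int = 0) -> ReferenceSpectra:
    """Build the three reference spectra as sums of Gaussian bands.

    The seed applies a small (+/-5%) amplitude jitter per band so that
    different phantoms carry slightly different reference shapes; band
    centres and widths are the fixed constants in :data:`REFERENCE_BANDS`.
    """
    axis = np.asarray(axis, dtype=np.float64)
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    lo, hi = _REQUIRED_COVERAGE
    if axis[0] > lo or axis[-1] < hi:
        raise ValueError(
            f"axis [{axis[0]}, {axis[-1]}] does not cover the fingerprint "
            f"region [{lo}, {hi}] cm^-1"
        )
    rng = np.random.default_rng(seed)
    cols = []
    for name in MOLECULES:
        bands = REFERENCE_BANDS[name]
        jitter = 1.0 + 0.05 * rng.uniform(-1.0, 1.0, size=len(bands))
        cols.append(_gaussian_bands(axis, bands, jitter))
    return ReferenceSpectra(axis, MOLECULES, np.column_stack(cols))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-sd smooth Gaussian random field."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field.std()
    return field / sd if sd > 0 else field


def make_scene(
    shape: tuple[int, int] = (528, 528),
    class_fractions: dict[int, float] | None = None,
    seed: int = 0,
    pixel_size_hr: float = 0.25,
) -> PhantomScene:
    """Generate a labelled scene with tumour aggregates in lymphoid tissue.

    Tumour aggregates are non-overlapping discs partitioned concentrically
    into a keratinised core (class 3), bulk tumour (class 2) and a collagen
    rim (class 4); the surround is lymphoid tissue (class 1) and any area
    fraction not requested by classes 1-4 is background (class 0), laid down
    as an outer frame.  Abundance maps are the per-class means of
    :data:`CLASS_ABUNDANCE` modulated by seeded smooth within-class variation,
    plus a nuclear speckle boost of DNA inside lymphoid tissue.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 64 or cols < 64:
        raise ValueError("scene must be at least 64 x 64")
    fracs = dict(DEFAULT_FRACTIONS if class_fractions is None else class_fractions)
    for cls, f in fracs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"class {cls} fraction {f} outside [0, 1]")
    total = sum(fracs.get(c, 0.0) for c in (1, 2, 3, 4))
    if total > 1.0 + 1e-9:
        raise ValueError(f"class fractions sum to {total:.3f} > 1")

    rng = np.random.default_rng(seed)
    label = np.zeros((rows, cols), dtype=np.uint8)

    # background frame occupying the leftover fraction
    bg_frac = max(0.0, 1.0 - total)
    t = 0
    if bg_frac > 1e-9:
        # frame thickness t solving 1 - (rows-2t)(cols-2t)/(rows*cols) = bg_frac
        a, b, c = 4.0, -2.0 * (rows + cols), bg_frac * rows * cols
        t = int(round((-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)))
        t = max(0, min(t, min(rows, cols) // 2 - 1))
    inner = np.zeros((rows, cols), dtype=bool)
    inner[t : rows - t if t else rows, t : cols - t if t else cols] = True
    label[inner] = 1  # lymphoid fills the interior

    f_tum = fracs.get(2, 0.0) + fracs.get(3, 0.0) + fracs.get(4, 0.0)
    if f_tum > 0:
        area = rows * cols
        target = f_tum * area
        radius = max(8, min(rows, cols) // 7)
        n_discs = max(1, int(round(target / (np.pi * radius**2))))
        # concentric radii from the requested core/bulk/rim area split
        f3 = fracs.get(3, 0.0) / f_tum
        f2 = fracs.get(2, 0.0) / f_tum
        r_core = radius * np.sqrt(f3)
        r_bulk = radius * np.sqrt(f3 + f2)
        yy, xx = np.mgrid[0:rows, 0:cols]
        # jittered-grid placement: candidate sites spaced > 2 radii apart so
        # discs never overlap, shuffled and jittered by the seed
        margin = t + radius + 1
        spacing = 2.1 * radius
        gy = np.arange(margin, rows - margin + 1e-9, spacing)
        gx = np.arange(margin, cols - margin + 1e-9, spacing)
        sites = [(y, x) for y in gy for x in gx]
        rng.shuffle(sites)
        jitter = 0.04 * radius
        centres = [
            (y + rng.uniform(-jitter, jitter), x + rng.uniform(-jitter, jitter))
            for y, x in sites[:n_discs]
        ]
        for cy, cx in centres:
            r = np.hypot(yy - cy, xx - cx)
            label[(r <= radius)] = 4
            label[(r <= r_bulk)] = 2
            label[(r <= r_core)] = 3

    # abundance maps: class means x smooth within-class variation
    ab = np.zeros((rows, cols, len(MOLECULES)))
    base = np.array([CLASS_ABUNDANCE[c] for c in range(5)])
    for m in range(len(MOLECULES)):
        variation = 1.0 + 0.15 * _smooth_field(rng, (rows, cols), min(rows, cols) / 32)
        ab[:, :, m] = base[label, m] * np.clip(variation, 0.0, None)

    # lymphoid nuclear speckle: closely packed high-DNA nuclei
    speckle = _smooth_field(rng, (rows, cols), 2.0)
    nuclei = speckle > np.quantile(speckle, 0.6)
    dna_idx = MOLECULES.index("dna")
    lymph = label == 1
    ab[:, :, dna_idx] = np.where(
        lymph & nuclei, ab[:, :, dna_idx] * 1.3,
        np.where(lymph, ab[:, :, dna_idx] * 0.7, ab[:, :, dna_idx]),
    )
    return PhantomScene(label, np.clip(ab, 0.0, None), pixel_size_hr, int(seed))


def render_pseudo_he(scene: PhantomScene) -> np.ndarray:
    """Render a deterministic pseudo-H&E RGB image from the abundances.

    Beer-Lambert style: each molecule absorbs with a fixed optical-density
    colour vector, so zero abundance transmits white and values stay in
    [0, 1].  Returns ``(rows, cols, 3)`` float RGB.
    """
    od = np.zeros(scene.truth_abundance.shape[:2] + (3,))
    for m, name in enumerate(scene.molecules):
        vec = np.array(_STAIN_OD[name])
        od += scene.truth_abundance[:, :, m : m + 1] * vec
    return np.exp(-od)


def _block_average(arr: np.ndarray, factor: int) -> np.ndarray:
    rows = (arr.shape[0] // factor) * factor
    cols = (arr.shape[1] // factor) * factor
    a = arr[:rows, :cols]
    return a.reshape(rows // factor, factor, cols // factor, factor, *a.shape[2:]).mean(
        axis=(1, 3)
    )


def degrade_map(
    arr: np.ndarray, factor: int, psf_sigma_px: float
) -> np.ndarray:
    """Gaussian blur (sigma in source pixels) then block-average by ``factor``."""
    if psf_sigma_px > 0:
        sigma = (psf_sigma_px, psf_sigma_px) + (0.0,) * (arr.ndim - 2)
        arr = ndimage.gaussian_filter(arr, sigma, mode="reflect")
    return _block_average(arr, factor)


def render_ftir(
    scene: PhantomScene,
    refs: ReferenceSpectra,
    pixel_size_lr: float = 5.5,
    psf_sigma: float = 2.75,
    noise_sd: float = 0.01,
    baseline_amp: float = 0.1,
    scatter_amp: float = 0.02,
    seed: int = 0,
) -> HyperCube:
    """Forward-model an FTIR datacube from a scene and reference spectra.

    Ground-truth abundances are blurred with a Gaussian PSF (``psf_sigma`` in
    um) and block-averaged onto the coarse grid, then mixed linearly through
    the reference spectra.  Per-pixel distortions: a smooth convex quadratic
    baseline scaled by ``baseline_amp``, a broad sinusoid in wavenumber
    (one period across the axis, random phase) scaled by ``scatter_amp`` as
    a Mie-ripple surrogate, and i.i.d. Gaussian noise of sd ``noise_sd``.
    The final cube is truncated at zero absorbance.
    """
    if pixel_size_lr <= 0:
        raise ValueError("pixel_size_lr must be positive")
    if pixel_size_lr <= scene.pixel_size_hr:
        raise ValueError("pixel_size_lr must exceed the scene's pixel size")
    ratio = pixel_size_lr / scene.pixel_size_hr
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6:
        raise ValueError("pixel size ratio must be an integer for block averaging")

    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma / scene.pixel_size_hr
    ab_lr = degrade_map(scene.truth_abundance, factor, sigma_px)
    cube = ab_lr @ refs.values.T  # (rows_lr, cols_lr, bands)

    rows, cols, bands = cube.shape
    tgrid = (refs.axis - refs.axis[0]) / (refs.axis[-1] - refs.axis[0])
    if baseline_amp > 0:
        a0 = rng.uniform(0.0, 0.5, (rows, cols, 1))
        curv = rng.uniform(0.0, 1.0, (rows, cols, 1))
        t0 = rng.uniform(0.0, 1.0, (rows, cols, 1))
        cube = cube + baseline_amp * (a0 + curv * (tgrid - t0) ** 2)
    if scatter_amp > 0:
        phase = rng.uniform(0.0, 2 * np.pi, (rows, cols, 1))
        amp = rng.uniform(0.5, 1.0, (rows, cols, 1))
        cube = cube + scatter_amp * amp * np.sin(2 * np.pi * tgrid + phase)
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, cube.shape)
    if noise_sd > 0 or scatter_amp > 0:
        cube = np.clip(cube, 0.0, None)  # absorbance floor (generator choice)
    return HyperCube(cube, refs.axis, pixel_size_lr)


def misregister(image: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Resample an image under an affine transform (bicubic interpolation).

    A pixel at target coordinate ``p`` takes the value of the source at
    ``T^-1 p``, so ``misregister(misregister(img, T), T.inverse())`` recovers
    the original up to interpolation and edge-padding error.
    """
    inv = transform.inverse().as_3x3()
    tf = sktransform.AffineTransform(matrix=inv)
    return sktransform.warp(
        np.asarray(image, dtype=np.float64), tf, order=3, mode="edge",
        preserve_range=True,
    )
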