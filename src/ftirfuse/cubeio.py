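"""Hyperspectral cube container and I/O.

The central in-memory object is :class:`HyperCube`: a ``rows x cols x bands``
absorbance array with a strictly increasing wavenumber axis (cm^-1) and a
square pixel size in micrometres.  On disk a cube is stored as an ENVI-style
pair: a plain-text ``.hdr`` header next to a band-sequential (BSQ) float32
binary payload — the de-facto language-neutral hyperspectral container.

Coordinate convention used by every module: pixel centres, 0-based,
``x`` = column, ``y`` = row, row 0 at the top.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HyperCube",
    "PixelMask",
    "AffineTransform",
    "read_cube",
    "write_cube",
    "crop_axis",
    "fit_affine",
    "um_to_px",
    "px_to_um",
]


def um_to_px(value_um: float, pixel_size: float) -> float:
    """Convert a physical length in micrometres to (fractional) pixels."""
    return float(value_um) / float(pixel_size)


def px_to_um(value_px: float, pixel_size: float) -> float:
    """Convert a length in pixels to micrometres."""
    return float(value_px) * float(pixel_size)


@dataclass
class HyperCube:
    """Absorbance datacube with spatial and spectral dimensions.

    Parameters
    ----------
    data
        ``(rows, cols, bands)`` float array of absorbance.
    axis
        ``(bands,)`` wavenumber axis in cm^-1, strictly increasing.
    pixel_size
        Square pixel edge in micrometres, > 0.
    """

    data: np.ndarray
    axis: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.axis.ndim != 1 or self.axis.size != self.data.shape[2]:
            raise ValueError("axis length must equal the number of bands")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if not np.all(np.isfinite(self.axis)):
            raise ValueError("axis contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.pixel_size = float(self.pixel_size)

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def nbands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def spectra(self) -> np.ndarray:
        """Flattened ``(rows*cols, bands)`` view of the pixel spectra."""
        return self.data.reshape(-1, self.nbands)

    def band_index(self, wavenumber: float) -> int:
        """Index of the band nearest ``wavenumber``; ties go to the lower band.

        Raises ``ValueError`` when the wavenumber lies outside the axis range.
        """
        nu = float(wavenumber)
        if nu < self.axis[0] or nu > self.axis[-1]:
            raise ValueError(
                f"wavenumber {nu} cm^-1 outside axis range "
                f"[{self.axis[0]}, {self.axis[-1]}]"
            )
        dist = np.abs(self.axis - nu)
        best = dist.min()
        # ties broken toward the lower wavenumber: first index at min distance
        return int(np.flatnonzero(np.isclose(dist, best, rtol=0, atol=1e-9))[0])

    def copy(self) -> "HyperCube":
        return HyperCube(self.data.copy(), self.axis.copy(), self.pixel_size)


@dataclass
class PixelMask:
    """Boolean per-pixel quality mask; ``True`` marks a usable spectrum."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum())

    def __and__(self, other: "PixelMask") -> "PixelMask":
        return PixelMask(self.mask & other.mask)


@dataclass
class AffineTransform:
    """2x3 affine map from source (x, y) pixel coordinates to target ones.

    ``matrix`` is ``[[a, b, tx], [c, d, ty]]`` acting on column vectors
    ``(x, y, 1)``; the 2x2 linear part must be invertible.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]]))

    def as_3x3(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.as_3x3())[:2, :])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` points (x, y) through the transform."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


# ---------------------------------------------------------------------------
# ENVI-style cube I/O
# ---------------------------------------------------------------------------

_HDR_TEMPLATE = """ENVI
description = {{ftirfuse hyperspectral cube}}
samples = {cols}
lines = {rows}
bands = {bands}
header offset = 0
file type = ENVI Standard
data type = 4
interleave = bsq
byte order = 0
pixel size = {{{px}, {px}}}
wavelength units = cm-1
wavelength = {{
{wavelengths}
}}
"""


def _data_path(header_path: str) -> str:
    base, ext = os.path.splitext(header_path)
    if ext.lower() == ".hdr":
        return base + ".dat"
    return header_path + ".dat"


def _header_path(path: str) -> str:
    if path.lower().endswith(".hdr"):
        return path
    return path + ".hdr"


def write_cube(cube: HyperCube, path: str) -> str:
    """Write a cube as ENVI text header + BSQ float32 binary.

    ``path`` names the header (``.hdr`` appended if missing); the payload is
    written next to it with a ``.dat`` suffix.  Returns the header path.
    """
    hdr = _header_path(path)
    dat = _data_path(hdr)
    wl = ",\n".join(
        " " + ", ".join(f"{v:.6f}" for v in cube.axis[i : i + 8])
        for i in range(0, cube.nbands, 8)
    )
    with open(hdr, "w") as fh:
        fh.write(
            _HDR_TEMPLATE.format(
                cols=cube.ncols,
                rows=cube.nrows,
                bands=cube.nbands,
                px=f"{cube.pixel_size:.6f}",
                wavelengths=wl,
            )
        )
    # BSQ: band-sequential (bands, rows, cols), little-endian float32
    payload = np.ascontiguousarray(
        np.transpose(cube.data, (2, 0, 1)).astype("<f4")
    )
    payload.tofile(dat)
    return hdr


def _parse_header(text: str) -> dict:
    """Parse the small ENVI-header dialect written by :func:`write_cube`."""
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_braces = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_braces:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            buf = [value]
            in_braces = True
        else:
            fields[key] = value
    return fields


def read_cube(path: str) -> HyperCube:
    """Read an ENVI-style cube; the axis is normalised to ascending order.

    Raises ``ValueError`` on header/payload size mismatch, duplicate
    wavelengths, or non-finite payload values.
    """
    hdr = _header_path(path)
    with open(hdr) as fh:
        fields = _parse_header(fh.read())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
    except KeyError as exc:  # pragma: no cover - malformed external file
        raise ValueError(f"ENVI header missing field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave {interleave!r} (only bsq)")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (ENVI data type 4) payloads supported")

    wl_text = fields.get("wavelength", "").strip().strip("{}")
    axis = np.array(
        [float(tok) for tok in wl_text.replace(",", " ").split()], dtype=np.float64
    )
    if axis.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {axis.size} wavelengths"
        )

    px_text = fields.get("pixel size", "{1, 1}").strip().strip("{}")
    pixel_size = float(px_text.replace(",", " ").split()[0])

    dat = _data_path(hdr)
    payload = np.fromfile(dat, dtype="<f4")
    expected = rows * cols * bands
    if payload.size != expected:
        raise ValueError(
            f"payload holds {payload.size} values but header implies {expected}"
        )
    data = payload.reshape(bands, rows, cols).transpose(1, 2, 0).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("payload contains NaN or Inf values")

    order = np.argsort(axis, kind="stable")
    axis = axis[order]
    if np.any(np.diff(axis) <= 0):
        raise ValueError("wavelength axis contains duplicate values")
    data = data[:, :, order]
    return HyperCube(data, axis, pixel_size)


def crop_axis(cube: HyperCube, lo: float, hi: float) -> HyperCube:
    """Retain bands with ``lo <= wavenumber <= hi`` (inclusive)."""
    if not lo < hi and lo != hi:
        raise ValueError("crop_axis requires lo <= hi")
    keep = (cube.axis >= lo) & (cube.axis <= hi)
    if not keep.any():
        raise ValueError(f"no bands remain in [{lo}, {hi}] cm^-1")
    return HyperCube(cube.data[:, :, keep], cube.axis[keep], cube.pixel_size)


def fit_affine(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine fit from >=3 control-point pairs.

    ``src`` and ``dst`` are ``(n, 2)`` arrays of (x, y) pixel coordinates.
    Exact when the pairs are affine-consistent; raises on collinear points.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("control points must be matching (n, 2) arrays")
    if src.shape[0] < 3:
        raise ValueError("at least 3 control-point pairs are required")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("control points are collinear")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    # coef is (3, 2): rows are x-coef, y-coef, intercept for each output dim
    matrix = np.column_stack([coef[:2].T, coef[2]])
    return AffineTransform(matrix)
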