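"""Spectral data model and preprocessing for transflectance FTIR imaging.

The central objects are :class:`WavenumberAxis`, :class:`Spectrum`,
:class:`HyperspectralImage` (a rows x cols x channels absorbance cube whose
flattened pixels form the bilinear data matrix D) and :class:`PixelMask`.

Preprocessing follows standard FTIR-imaging practice for paraffin-embedded
tissue sections: per-pixel Savitzky-Golay second derivatives (polynomial
order 3, 15-point window by default) to suppress baselines and sharpen
overlapping bands, vector normalization and offset correction over a
working window (950-1800 cm-1 by default), spectral-region selection, and
masking of paraffin/substrate-only pixels by the amide II criterion at
1554 cm-1 (tissue protein gives a negative second-derivative lobe there;
embedding medium and substrate do not).

Conventions: wavenumber axes may run ascending or descending -- all range
operations are order-agnostic; image grids are row-major, origin top-left,
with the anterior-posterior disc axis along columns. Second derivatives are
kept in per-channel-index^2 units (no division by the physical spacing);
only relative values matter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    EmptyMaskError,
    IncompatibleImageError,
    InvalidParameterError,
    InvalidRegionError,
    DegenerateSpectrumError,
)

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralImage",
    "PixelMask",
    "second_derivative",
    "vector_normalize",
    "offset_correct",
    "select_region",
    "compute_mask",
    "region_average",
    "collate",
    "mosaic_dimensions",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly monotone wavenumber axis in cm-1."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise InvalidParameterError("axis needs at least 2 wavenumbers")
        d = np.diff(vals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidParameterError("axis must be strictly monotone")

    @property
    def spacing(self) -> float:
        """Nominal channel step: median absolute consecutive difference."""
        return float(np.median(np.abs(np.diff(self.values))))

    def __len__(self) -> int:
        return self.values.size

    def window_indices(self, lo: float, hi: float) -> np.ndarray:
        """Channel indices with lo <= wavenumber <= hi (order-agnostic)."""
        lo, hi = min(lo, hi), max(lo, hi)
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def __eq__(self, other) -> bool:  # value equality for collation checks
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((self.values.shape, float(self.values[0]), float(self.values[-1])))

    @classmethod
    def regular(cls, lo: float, hi: float, spacing: float,
                descending: bool = True) -> "WavenumberAxis":
        """Build an evenly spaced axis covering [lo, hi].

        Descending by default, matching the order FTIR instruments
        typically record.
        """
        if spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        n = int(round((hi - lo) / spacing)) + 1
        vals = lo + spacing * np.arange(n)
        return cls(vals[::-1].copy() if descending else vals)


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a wavenumber axis.

    ``derivative_order`` is 0 for absorbance and 2 after Savitzky-Golay
    differentiation.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    derivative_order: int = 0

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.shape != (len(self.axis),):
            raise InvalidParameterError(
                f"intensities length {arr.shape} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("spectrum contains non-finite values")
        if self.derivative_order not in (0, 2):
            raise InvalidParameterError("derivative_order must be 0 or 2")


@dataclass(frozen=True)
class HyperspectralImage:
    """A hyperspectral cube of shape (n_rows, n_cols, n_channels).

    Reshaping ``cube`` to (n_rows * n_cols, n_channels) yields the data
    matrix D of the bilinear mixture model D ~= C S^T.
    """

    axis: WavenumberAxis
    cube: np.ndarray
    derivative_order: int = 0
    pixel_size_um: float | None = None

    def __post_init__(self):
        arr = np.asarray(self.cube, dtype=float)
        object.__setattr__(self, "cube", arr)
        if arr.ndim != 3:
            raise InvalidParameterError("cube must be 3-dimensional")
        if arr.shape[2] != len(self.axis):
            raise InvalidParameterError(
                f"cube has {arr.shape[2]} channels, axis has {len(self.axis)}"
            )

    @property
    def n_rows(self) -> int:
        return self.cube.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cube.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def as_matrix(self) -> np.ndarray:
        """The (n_pixels, n_channels) data matrix D (a view when possible)."""
        return self.cube.reshape(self.n_pixels, len(self.axis))

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col].copy(),
                        self.derivative_order)


@dataclass(frozen=True)
class PixelMask:
    """Boolean tissue mask; True = pixel retained for analysis."""

    included: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.included, dtype=bool)
        object.__setattr__(self, "included", arr)
        if arr.ndim != 2:
            raise InvalidParameterError("mask must be 2-dimensional")
        if not arr.any():
            raise EmptyMaskError("mask retains no pixels")

    @property
    def n_rows(self) -> int:
        return self.included.shape[0]

    @property
    def n_cols(self) -> int:
        return self.included.shape[1]

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def check_matches(self, image: HyperspectralImage) -> None:
        if (self.n_rows, self.n_cols) != (image.n_rows, image.n_cols):
            raise IncompatibleImageError(
                f"mask {self.included.shape} does not match image grid "
                f"({image.n_rows}, {image.n_cols})"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def second_derivative(data, window_length: int = 15, poly_order: int = 3):
    """Per-trace Savitzky-Golay 2nd derivative.

    Output is in per-channel-index^2 units (the raw filter output, no
    division by the physical spacing); edge channels use a polynomial fit
    to the one-sided window so the axis length is preserved.

    Accepts a :class:`Spectrum` or :class:`HyperspectralImage` and returns
    the same type with ``derivative_order == 2``.
    """
    if window_length % 2 == 0:
        raise InvalidParameterError("window_length must be odd")
    if window_length < poly_order + 2:
        raise InvalidParameterError(
            "window_length must be at least poly_order + 2"
        )
    if poly_order < 2:
        raise InvalidParameterError("poly_order must be >= 2 for a 2nd derivative")

    if isinstance(data, Spectrum):
        if data.derivative_order != 0:
            raise InvalidParameterError("input is already differentiated")
        if len(data.axis) < window_length:
            raise InvalidParameterError("window longer than the trace")
        out = savgol_filter(data.intensities, window_length, poly_order,
                            deriv=2, delta=1.0, mode="interp")
        return Spectrum(data.axis, out, derivative_order=2)
    if isinstance(data, HyperspectralImage):
        if data.derivative_order != 0:
            raise InvalidParameterError("input is already differentiated")
        if len(data.axis) < window_length:
            raise InvalidParameterError("window longer than the trace")
        out = savgol_filter(data.cube, window_length, poly_order,
                            deriv=2, delta=1.0, mode="interp", axis=2)
        return HyperspectralImage(data.axis, out, derivative_order=2,
                                  pixel_size_um=data.pixel_size_um)
    raise InvalidParameterError(f"unsupported input type {type(data)!r}")


def vector_normalize(spectrum: Spectrum, lo: float = 950.0,
                     hi: float = 1800.0) -> Spectrum:
    """Divide by the Euclidean norm computed over channels in [lo, hi]."""
    idx = spectrum.axis.window_indices(lo, hi)
    if idx.size == 0:
        raise InvalidRegionError(f"window [{lo}, {hi}] selects no channels")
    norm = float(np.linalg.norm(spectrum.intensities[idx]))
    if norm == 0.0:
        raise DegenerateSpectrumError("zero norm over the normalization window")
    return replace(spectrum, intensities=spectrum.intensities / norm)


def offset_correct(spectrum: Spectrum, lo: float = 950.0,
                   hi: float = 1800.0) -> Spectrum:
    """Subtract a scalar so the minimum over [lo, hi] becomes zero."""
    idx = spectrum.axis.window_indices(lo, hi)
    if idx.size == 0:
        raise InvalidRegionError(f"window [{lo}, {hi}] selects no channels")
    return replace(spectrum,
                   intensities=spectrum.intensities
                   - float(spectrum.intensities[idx].min()))


def select_region(image: HyperspectralImage, lo: float,
                  hi: float) -> HyperspectralImage:
    """Restrict the cube to channels with lo <= wavenumber <= hi (inclusive)."""
    idx = image.axis.window_indices(lo, hi)
    if idx.size < 2:
        raise InvalidRegionError(
            f"region [{lo}, {hi}] selects fewer than 2 channels"
        )
    return HyperspectralImage(
        WavenumberAxis(image.axis.values[idx]),
        image.cube[:, :, idx],
        derivative_order=image.derivative_order,
        pixel_size_um=image.pixel_size_um,
    )


def compute_mask(image: HyperspectralImage, marker_wavenumber: float = 1554.0,
                 threshold: float = 0.0) -> PixelMask:
    """Mask paraffin/substrate-only pixels by the amide II criterion.

    A pixel is retained iff its 2nd-derivative value at the channel nearest
    ``marker_wavenumber`` is strictly below ``threshold``: protein amide II
    produces a negative 2nd-derivative lobe at 1554 cm-1, whereas paraffin
    and bare substrate give values near zero there.
    """
    if image.derivative_order != 2:
        raise InvalidParameterError("mask is computed on 2nd-derivative data")
    vals = image.axis.values
    if not (vals.min() <= marker_wavenumber <= vals.max()):
        raise InvalidParameterError(
            f"marker {marker_wavenumber} cm-1 outside the axis range"
        )
    ch = image.axis.nearest_index(marker_wavenumber)
    included = image.cube[:, :, ch] < threshold
    if not included.any():
        raise EmptyMaskError("amide II criterion excluded every pixel")
    return PixelMask(included)


def region_average(image: HyperspectralImage, region: PixelMask) -> Spectrum:
    """Channel-wise arithmetic mean over the pixels retained by ``region``."""
    region.check_matches(image)
    mean = image.cube[region.included].mean(axis=0)
    return Spectrum(image.axis, mean, derivative_order=image.derivative_order)


def collate(images: list[HyperspectralImage]) -> HyperspectralImage:
    """Stack cubes along the row axis, in list order.

    All images must share the wavenumber axis and column count; sections
    from several samples are collated into one matrix so a single MCR model
    resolves them jointly.
    """
    if not images:
        raise InvalidParameterError("nothing to collate")
    first = images[0]
    for im in images[1:]:
        if im.axis != first.axis:
            raise IncompatibleImageError("collate: wavenumber axes differ")
        if im.n_cols != first.n_cols:
            raise IncompatibleImageError("collate: column counts differ")
        if im.derivative_order != first.derivative_order:
            raise IncompatibleImageError("collate: derivative orders differ")
    cube = np.concatenate([im.cube for im in images], axis=0)
    return HyperspectralImage(first.axis, cube,
                              derivative_order=first.derivative_order,
                              pixel_size_um=first.pixel_size_um)


def mosaic_dimensions(tiles_rows: int, tiles_cols: int, fpa_rows: int,
                      fpa_cols: int, aggregation: int) -> tuple[int, int]:
    """Image pixel dimensions of an FPA mosaic with on-chip pixel aggregation.

    ``aggregation`` detector pixels are binned into one image pixel; it must
    be a perfect square whose root divides both FPA dimensions. E.g. a
    23 x 57 tile mosaic on a 64 x 64 FPA with aggregation 256 yields a
    92 x 228 pixel image.
    """
    for name, v in (("tiles_rows", tiles_rows), ("tiles_cols", tiles_cols),
                    ("fpa_rows", fpa_rows), ("fpa_cols", fpa_cols),
                    ("aggregation", aggregation)):
        if int(v) != v or v < 1:
            raise InvalidParameterError(f"{name} must be a positive integer")
    root = math.isqrt(int(aggregation))
    if root * root != aggregation:
        raise InvalidParameterError("aggregation must be a perfect square")
    if fpa_rows % root or fpa_cols % root:
        raise InvalidParameterError(
            "sqrt(aggregation) must divide both FPA dimensions"
        )
    return (tiles_rows * (fpa_rows // root), tiles_cols * (fpa_cols // root))
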