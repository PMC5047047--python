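"""Biological labelling of MCR results: tissue, component and ratio maps.

The amide III window (1186-1297 cm-1) integrated on the negated second
derivative serves as an overall extracellular-matrix "tissue map"; MCR
concentration columns are re-embedded into the pixel grid as component
maps and divided by the tissue map to give relative component distribution
("component/tissue") maps. Factors are assigned to reference components by
maximizing total Pearson correlation between resolved profiles and
second-derivative reference spectra (optimal injective assignment via the
Hungarian algorithm), and the two proteoglycan populations are discriminated
by the position of the sulfated C-O-S peak near 1124-1128 cm-1, refined by
three-point parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import (
    IncompatibleImageError,
    InvalidParameterError,
    InvalidRegionError,
    NoPeakError,
)
from .mcr import MCRModel
from .phantom import ReferenceLibrary
from .spectra import HyperspectralImage, PixelMask, Spectrum

__all__ = [
    "TissueMap",
    "ComponentMap",
    "RatioMap",
    "FactorAssignment",
    "tissue_map",
    "component_map",
    "ratio_map",
    "assign_factors",
    "cos_peak_position",
]

AMIDE_III_WINDOW = (1186.0, 1297.0)


@dataclass(frozen=True)
class TissueMap:
    """Per-pixel integrated amide III 2nd-derivative magnitude (NaN = masked)."""

    values: np.ndarray
    window: tuple[float, float]

    @property
    def grid(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ComponentMap:
    """One concentration column of an MCR model on the pixel grid."""

    values: np.ndarray
    label: str

    @property
    def grid(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RatioMap:
    """Component/tissue relative distribution map."""

    values: np.ndarray
    label: str
    epsilon: float

    @property
    def grid(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class FactorAssignment:
    """Injective factor -> component-name mapping with its score matrix."""

    mapping: dict[int, str]
    scores: np.ndarray          # (k, n_references)
    reference_names: tuple[str, ...]
    method: str

    def component_factor(self, name: str) -> int:
        """Factor index assigned to a component name."""
        for idx, comp in self.mapping.items():
            if comp == name:
                return idx
        raise KeyError(name)


def tissue_map(image: HyperspectralImage, mask: PixelMask,
               lo: float = AMIDE_III_WINDOW[0],
               hi: float = AMIDE_III_WINDOW[1]) -> TissueMap:
    """Integrate the negated 2nd derivative over the amide III window.

    The negated 2nd derivative is clipped at zero channelwise before the
    trapezoidal integration: a 2nd-derivative band carries compensating
    negative side lobes, so the signed integral over a window containing
    whole bands cancels to near zero -- the positive part is the band-
    magnitude measure "more tissue = larger value" requires. Masked pixels
    are NaN.
    """
    if image.derivative_order != 2:
        raise InvalidParameterError("tissue map needs a 2nd-derivative image")
    mask.check_matches(image)
    idx = image.axis.window_indices(lo, hi)
    if idx.size < 2:
        raise InvalidRegionError(f"window [{lo}, {hi}] outside the axis")
    nu = image.axis.values[idx]
    order = np.argsort(nu)
    vals = np.trapezoid(np.clip(-image.cube[:, :, idx[order]], 0.0, None),
                        x=nu[order], axis=2)
    vals[~mask.included] = np.nan
    return TissueMap(vals, (float(lo), float(hi)))


def component_map(model: MCRModel, factor_index: int, grid: tuple[int, int],
                  mask: PixelMask, label: str | None = None) -> ComponentMap:
    """Scatter one column of C back to its pixel positions (NaN = masked)."""
    if not 0 <= factor_index < model.k:
        raise InvalidParameterError(f"factor index {factor_index} out of range")
    if mask.included.shape != tuple(grid):
        raise IncompatibleImageError("mask does not match the requested grid")
    if mask.n_included != model.C.shape[0]:
        raise IncompatibleImageError(
            "mask pixel count does not match the model's C rows"
        )
    vals = np.full(grid, np.nan)
    vals[mask.included] = model.C[:, factor_index]
    return ComponentMap(vals, label or f"factor_{factor_index}")


def ratio_map(component: ComponentMap, tissue: TissueMap,
              epsilon: float | None = None) -> RatioMap:
    """Elementwise component/tissue where tissue >= epsilon; NaN elsewhere.

    ``epsilon`` defaults to 1e-3 times the median tissue value over valid
    pixels, guarding against near-zero denominators at tissue edges.
    """
    if component.values.shape != tissue.values.shape:
        raise IncompatibleImageError("component and tissue grids differ")
    tv = tissue.values
    if epsilon is None:
        med = np.nanmedian(tv)
        epsilon = 1e-3 * float(med) if np.isfinite(med) else 1e-12
    ok = np.isfinite(tv) & (tv >= epsilon) & np.isfinite(component.values)
    vals = np.full(component.values.shape, np.nan)
    vals[ok] = component.values[ok] / tv[ok]
    return RatioMap(vals, component.label, float(epsilon))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _library_profiles(model: MCRModel, library: ReferenceLibrary,
                      region: tuple[float, float] | None) -> np.ndarray:
    """Reference 2nd-derivative spectra, negated (working orientation),
    restricted to the model's axis channels."""
    if model.axis is None:
        raise InvalidParameterError("model carries no wavenumber axis")
    lib_vals = library.axis.values
    sel = np.array([int(np.argmin(np.abs(lib_vals - v)))
                    for v in model.axis.values])
    if not np.allclose(lib_vals[sel], model.axis.values):
        raise InvalidParameterError("library axis does not cover the model axis")
    if region is not None:
        in_win = ((model.axis.values >= min(region))
                  & (model.axis.values <= max(region)))
    else:
        in_win = np.ones(len(model.axis), dtype=bool)
    cols = []
    for name in library.names:
        deriv = -library.second_derivative(name)[sel]
        cols.append(deriv[in_win])
    return np.column_stack(cols)


def assign_factors(model: MCRModel, library: ReferenceLibrary,
                   region: tuple[float, float] | None = None,
                   method: str = "hungarian") -> FactorAssignment:
    """Assign factors to component names by profile/reference correlation.

    Scores are Pearson correlations between each resolved profile and each
    reference 2nd-derivative spectrum over ``region`` (default: the model's
    full axis). The injective assignment maximizing the total score is found
    by the Hungarian algorithm (or greedily); with fewer references than
    factors, leftover factors are labelled ``extra``.
    """
    if len(library) == 0:
        raise InvalidParameterError("empty reference library")
    refs = _library_profiles(model, library, region)
    names = tuple(library.names)
    if region is not None:
        in_win = ((model.axis.values >= min(region))
                  & (model.axis.values <= max(region)))
        profiles = model.S[in_win]
    else:
        profiles = model.S
    k, n_ref = model.k, refs.shape[1]
    scores = np.empty((k, n_ref))
    for i in range(k):
        for j in range(n_ref):
            scores[i, j] = _pearson(profiles[:, i], refs[:, j])

    mapping: dict[int, str] = {}
    if method == "hungarian":
        rows, cols = linear_sum_assignment(-scores)
        for r, c in zip(rows, cols):
            mapping[int(r)] = names[c]
    elif method == "greedy":
        taken_f, taken_r = set(), set()
        flat = sorted(
            ((scores[i, j], -i, i, j) for i in range(k) for j in range(n_ref)),
            reverse=True,
        )
        for _, _, i, j in flat:
            if i in taken_f or j in taken_r:
                continue
            mapping[i] = names[j]
            taken_f.add(i)
            taken_r.add(j)
    else:
        raise InvalidParameterError(f"unknown assignment method {method!r}")
    for i in range(k):
        mapping.setdefault(i, "extra")
    return FactorAssignment(dict(sorted(mapping.items())), scores, names,
                            method)


def cos_peak_position(profile: Spectrum,
                      window: tuple[float, float] = (1100.0, 1140.0)
                      ) -> float:
    """Position (cm-1, to 0.1) of the C-O-S peak maximum within ``window``.

    Expects a profile in working orientation (bands positive). The integer-
    channel maximum is refined by three-point parabolic interpolation since
    the physiologically meaningful 2 cm-1 shift equals typical channel
    spacing. A maximum must be a local one (both neighbours lower); a flat
    or edge-dominated window raises ``NoPeakError``.
    """
    nu = profile.axis.values
    y = profile.intensities
    idx = profile.axis.window_indices(*window)
    if idx.size < 3:
        raise InvalidRegionError("peak window selects fewer than 3 channels")
    # local maxima with both neighbours available in the full trace
    best = None
    for i in idx:
        if i == 0 or i == nu.size - 1:
            continue
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            if best is None or y[i] > y[best]:
                best = i
    if best is None:
        raise NoPeakError("no local maximum inside the C-O-S window")
    ym, y0, yp = y[best - 1], y[best], y[best + 1]
    denom = ym - 2.0 * y0 + yp
    delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
    step = nu[best + 1] - nu[best]  # signed, handles descending axes
    pos = nu[best] + delta * step
    return round(float(pos), 1)
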