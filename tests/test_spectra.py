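"""Spectral data model and preprocessing operations."""

import numpy as np
import pytest

from discspect.errors import (
    DegenerateSpectrumError,
    EmptyMaskError,
    IncompatibleImageError,
    InvalidParameterError,
    InvalidRegionError,
)
from discspect.phantom import PhantomConfig, generate_phantom
from discspect.spectra import (
    HyperspectralImage,
    PixelMask,
    Spectrum,
    WavenumberAxis,
    collate,
    compute_mask,
    mosaic_dimensions,
    offset_correct,
    region_average,
    second_derivative,
    select_region,
    vector_normalize,
)


def _image(axis, cube, **kw):
    return HyperspectralImage(axis, cube, **kw)


# ---------------------------------------------------------------------------
# WavenumberAxis
# ---------------------------------------------------------------------------

class TestAxis:
    def test_regular_descending_default(self):
        ax = WavenumberAxis.regular(950, 1800, 2)
        assert ax.values[0] == 1800 and ax.values[-1] == 950
        assert len(ax) == 426
        assert ax.spacing == pytest.approx(2.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidParameterError):
            WavenumberAxis(np.array([1.0, 3.0, 2.0]))

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            WavenumberAxis(np.array([1.0]))

    def test_window_indices_order_agnostic(self):
        ax = WavenumberAxis.regular(950, 1800, 2)
        idx = ax.window_indices(1800, 950)
        assert idx.size == len(ax)

    def test_nearest_index(self):
        ax = WavenumberAxis.regular(950, 1800, 2)
        assert ax.values[ax.nearest_index(1553.4)] == 1554.0


# ---------------------------------------------------------------------------
# second_derivative
# ---------------------------------------------------------------------------

class TestSecondDerivative:
    def test_constant_gives_zeros(self, small_axis):
        s = Spectrum(small_axis, np.full(len(small_axis), 4.2))
        out = second_derivative(s)
        assert out.derivative_order == 2
        assert np.allclose(out.intensities, 0.0, atol=1e-12)

    def test_quadratic_gives_2a_interior(self, small_axis):
        i = np.arange(len(small_axis), dtype=float)
        s = Spectrum(small_axis, 3.0 * i**2 - 5.0 * i + 7.0)
        out = second_derivative(s, 15, 3).intensities
        assert np.allclose(out[7:-7], 6.0, atol=1e-9)

    def test_sine_matches_local_polyfit_oracle(self, small_axis):
        n = len(small_axis)
        i = np.arange(n, dtype=float)
        y = np.sin(2 * np.pi * i / 50.0)
        out = second_derivative(Spectrum(small_axis, y), 15, 3).intensities
        # brute-force oracle: least-squares cubic on the 15-point window
        # centred at i=100, second derivative at its centre
        w = np.arange(-7, 8, dtype=float)
        coef = np.polyfit(w, y[100 - 7:100 + 8], 3)
        oracle = 2.0 * coef[1]  # d2/dx2 of c3 x^3 + c2 x^2 + ... at x = 0
        assert out[100] == pytest.approx(oracle, abs=1e-12)

    def test_image_variant_matches_spectrum(self, small_axis):
        rng = np.random.default_rng(0)
        cube = rng.normal(size=(3, 4, len(small_axis)))
        img = second_derivative(_image(small_axis, cube))
        spec = second_derivative(Spectrum(small_axis, cube[1, 2]))
        assert np.allclose(img.cube[1, 2], spec.intensities)

    def test_even_window_rejected(self, small_axis):
        s = Spectrum(small_axis, np.zeros(len(small_axis)))
        with pytest.raises(InvalidParameterError):
            second_derivative(s, 14, 3)

    def test_window_longer_than_trace_rejected(self):
        ax = WavenumberAxis.regular(1000, 1020, 2)
        s = Spectrum(ax, np.zeros(len(ax)))
        with pytest.raises(InvalidParameterError):
            second_derivative(s, 15, 3)

    def test_double_differentiation_rejected(self, small_axis):
        s = Spectrum(small_axis, np.zeros(len(small_axis)), derivative_order=2)
        with pytest.raises(InvalidParameterError):
            second_derivative(s)


# ---------------------------------------------------------------------------
# vector_normalize / offset_correct
# ---------------------------------------------------------------------------

class TestNormalization:
    def test_unit_norm_unchanged(self, small_axis):
        y = np.zeros(len(small_axis))
        y[small_axis.nearest_index(1200)] = 1.0
        out = vector_normalize(Spectrum(small_axis, y), 950, 1800)
        assert np.allclose(out.intensities, y)

    def test_constant_closed_form(self, small_axis):
        idx = small_axis.window_indices(950, 1800)
        out = vector_normalize(
            Spectrum(small_axis, np.full(len(small_axis), 3.0)), 950, 1800)
        assert np.allclose(out.intensities[idx], 1.0 / np.sqrt(idx.size))

    def test_random_matches_direct_sum(self, small_axis, rng):
        y = rng.normal(size=len(small_axis))
        out = vector_normalize(Spectrum(small_axis, y), 1000, 1400)
        idx = small_axis.window_indices(1000, 1400)
        norm = np.sqrt(np.sum(y[idx] ** 2))
        assert np.allclose(out.intensities, y / norm)

    def test_idempotent(self, small_axis, rng):
        s = Spectrum(small_axis, rng.normal(size=len(small_axis)))
        once = vector_normalize(s, 950, 1800)
        twice = vector_normalize(once, 950, 1800)
        assert np.allclose(once.intensities, twice.intensities)

    def test_zero_norm_rejected(self, small_axis):
        with pytest.raises(DegenerateSpectrumError):
            vector_normalize(Spectrum(small_axis, np.zeros(len(small_axis))),
                             950, 1800)

    def test_offset_min_zero_unchanged(self, small_axis):
        y = np.abs(np.sin(np.arange(len(small_axis))))
        y[10] = 0.0
        out = offset_correct(Spectrum(small_axis, y), 950, 1800)
        assert np.allclose(out.intensities, y)

    def test_offset_shift_invariant(self, small_axis, rng):
        y = rng.normal(size=len(small_axis))
        a = offset_correct(Spectrum(small_axis, y), 950, 1800)
        b = offset_correct(Spectrum(small_axis, y + 5.0), 950, 1800)
        assert np.allclose(a.intensities, b.intensities)

    def test_offset_postcondition(self, small_axis, rng):
        y = rng.normal(size=len(small_axis))
        out = offset_correct(Spectrum(small_axis, y), 950, 1800)
        idx = small_axis.window_indices(950, 1800)
        assert out.intensities[idx].min() == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# select_region
# ---------------------------------------------------------------------------

class TestSelectRegion:
    def test_channel_counts(self, small_axis, rng):
        img = _image(small_axis, rng.normal(size=(2, 2, len(small_axis))))
        assert len(select_region(img, 950, 1600).axis) == 326
        assert len(select_region(img, 950, 1300).axis) == 176

    def test_full_span_identity(self, small_axis, rng):
        img = _image(small_axis, rng.normal(size=(2, 2, len(small_axis))))
        out = select_region(img, 900, 1800)
        assert np.array_equal(out.cube, img.cube)

    def test_nested_composition(self, small_axis, rng):
        img = _image(small_axis, rng.normal(size=(2, 2, len(small_axis))))
        a = select_region(select_region(img, 950, 1600), 1000, 1300)
        b = select_region(img, 1000, 1300)
        assert np.array_equal(a.cube, b.cube)

    def test_empty_selection_rejected(self, small_axis, rng):
        img = _image(small_axis, rng.normal(size=(2, 2, len(small_axis))))
        with pytest.raises(InvalidRegionError):
            select_region(img, 100, 200)


# ---------------------------------------------------------------------------
# compute_mask / region_average
# ---------------------------------------------------------------------------

class TestMask:
    def test_mask_equals_ground_truth_noise_free(self, clean_phantom):
        _, image, truth, _ = clean_phantom
        mask = compute_mask(second_derivative(image))
        assert np.array_equal(mask.included, truth.tissue_mask.included)

    def test_all_tissue_all_included(self, small_axis):
        # amide II band at 1554: negative 2nd-derivative lobe in every pixel
        nu = small_axis.values
        band = np.exp(-((nu - 1554.0) / 8.0) ** 2)
        cube = np.tile(band, (3, 4, 1))
        mask = compute_mask(second_derivative(_image(small_axis, cube)))
        assert mask.n_included == 12

    def test_threshold_minus_inf_empty(self, small_axis):
        cube = np.tile(np.exp(-((small_axis.values - 1554.0) / 8.0) ** 2),
                       (2, 2, 1))
        deriv = second_derivative(_image(small_axis, cube))
        with pytest.raises(EmptyMaskError):
            compute_mask(deriv, threshold=-np.inf)

    def test_requires_second_derivative(self, small_axis, rng):
        img = _image(small_axis, rng.normal(size=(2, 2, len(small_axis))))
        with pytest.raises(InvalidParameterError):
            compute_mask(img)

    def test_region_average_single_pixel(self, small_axis, rng):
        cube = rng.normal(size=(3, 3, len(small_axis)))
        sel = np.zeros((3, 3), dtype=bool)
        sel[1, 2] = True
        out = region_average(_image(small_axis, cube), PixelMask(sel))
        assert np.allclose(out.intensities, cube[1, 2])

    def test_region_average_midpoint(self, small_axis, rng):
        a = rng.normal(size=len(small_axis))
        cube = np.stack([[a, a + 2.0]])
        out = region_average(_image(small_axis, cube),
                             PixelMask(np.ones((1, 2), dtype=bool)))
        assert np.allclose(out.intensities, a + 1.0)

    def test_region_average_direct_sum_oracle(self, small_axis, rng):
        cube = rng.normal(size=(2, 5, len(small_axis)))
        sel = np.ones((2, 5), dtype=bool)
        out = region_average(_image(small_axis, cube), PixelMask(sel))
        assert np.allclose(out.intensities,
                           cube.reshape(10, -1).sum(axis=0) / 10.0)


# ---------------------------------------------------------------------------
# collate / mosaic_dimensions
# ---------------------------------------------------------------------------

class TestCollate:
    def test_identity(self, small_axis, rng):
        img = _image(small_axis, rng.normal(size=(4, 5, len(small_axis))))
        out = collate([img])
        assert np.array_equal(out.cube, img.cube)

    def test_three_images_additive(self, small_axis, rng):
        imgs = [_image(small_axis, rng.normal(size=(10, 20, len(small_axis))))
                for _ in range(3)]
        assert collate(imgs).n_rows == 30 and collate(imgs).n_cols == 20

    def test_associative(self, small_axis, rng):
        a, b, c = (
            _image(small_axis, rng.normal(size=(2, 3, len(small_axis))))
            for _ in range(3))
        left = collate([collate([a, b]), c])
        flat = collate([a, b, c])
        assert np.array_equal(left.cube, flat.cube)

    def test_axis_mismatch_rejected(self, small_axis, rng):
        other = WavenumberAxis.regular(900, 1798, 2)
        a = _image(small_axis, rng.normal(size=(2, 3, len(small_axis))))
        b = _image(other, rng.normal(size=(2, 3, len(other))))
        with pytest.raises(IncompatibleImageError):
            collate([a, b])

    def test_column_mismatch_rejected(self, small_axis, rng):
        a = _image(small_axis, rng.normal(size=(2, 3, len(small_axis))))
        b = _image(small_axis, rng.normal(size=(2, 4, len(small_axis))))
        with pytest.raises(IncompatibleImageError):
            collate([a, b])


class TestMosaic:
    def test_no_aggregation(self):
        assert mosaic_dimensions(1, 1, 64, 64, 1) == (64, 64)

    def test_human_geometry(self):
        assert mosaic_dimensions(28, 62, 64, 64, 256) == (112, 248)

    def test_non_square_aggregation_rejected(self):
        with pytest.raises(InvalidParameterError):
            mosaic_dimensions(1, 1, 64, 64, 200)

    def test_non_dividing_aggregation_rejected(self):
        with pytest.raises(InvalidParameterError):
            mosaic_dimensions(1, 1, 60, 64, 256)
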