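"""MCR-ALS: NIPALS/SVD extraction, simplex rotation, ALS refinement."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from discspect.errors import (
    DegenerateInputError,
    EmptyMaskError,
    InvalidParameterError,
)
from discspect.mapping import assign_factors
from discspect.mcr import (
    ConstraintSpec,
    als_optimize,
    lack_of_fit,
    nipals_decompose,
    resolve,
    simplex_initial_estimates,
    svd_initial_estimates,
)
from discspect.spectra import PixelMask


def _corr(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _three_component_problem(rng, n=200, m=120):
    """Noise-free bilinear D = C* S*^T with distinct non-negative parts."""
    x = np.linspace(0, 1, m)
    S = np.column_stack([np.exp(-((x - c) / 0.08) ** 2)
                         for c in (0.25, 0.5, 0.75)])
    S /= np.linalg.norm(S, axis=0)
    C = rng.uniform(0, 1, size=(n, 3))
    C[:3] = np.eye(3) * 2.0      # a few near-pure pixels
    return C, S, C @ S.T


# ---------------------------------------------------------------------------
# NIPALS / SVD
# ---------------------------------------------------------------------------

class TestNipals:
    def test_rank_one(self, rng):
        u = rng.normal(size=7)
        v = rng.normal(size=5)
        scores, loadings = nipals_decompose(np.outer(u, v), 1)
        vn = v / np.linalg.norm(v)
        assert np.allclose(np.abs(loadings[:, 0]), np.abs(vn), atol=1e-10)
        assert np.allclose(np.outer(scores[:, 0], loadings[:, 0]),
                           np.outer(u, v), atol=1e-10)

    def test_singular_values_match_svd(self, rng):
        D = rng.normal(size=(8, 6))
        scores, _ = nipals_decompose(D, 3)
        sv = np.linalg.norm(scores, axis=0)
        s_true = np.linalg.svd(D, compute_uv=False)[:3]
        assert np.allclose(sv, s_true, rtol=1e-6)

    def test_full_rank_recovery(self, rng):
        D = rng.normal(size=(6, 6))
        scores, loadings = nipals_decompose(D, 6)
        assert np.allclose(scores @ loadings.T, D, atol=1e-8)

    def test_k_out_of_range(self, rng):
        with pytest.raises(InvalidParameterError):
            nipals_decompose(rng.normal(size=(4, 4)), 5)


class TestSvdInit:
    def test_orthogonal_columns(self):
        Q = np.linalg.qr(np.random.default_rng(1).normal(size=(8, 3)))[0]
        D = Q * np.array([3.0, 2.0, 1.0])
        _, loadings = svd_initial_estimates(D, 3)
        # loadings are the right singular vectors: unit axes up to sign
        assert np.allclose(np.abs(loadings), np.eye(3), atol=1e-10)

    def test_k_zero_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            svd_initial_estimates(rng.normal(size=(4, 4)), 0)

    def test_reconstruction_error_matches_nipals(self, rng):
        D = rng.normal(size=(8, 6))
        s1, l1 = nipals_decompose(D, 3)
        s2, l2 = svd_initial_estimates(D, 3)
        e1 = np.linalg.norm(D - s1 @ l1.T)
        e2 = np.linalg.norm(D - s2 @ l2.T)
        assert e1 == pytest.approx(e2, rel=1e-6)


# ---------------------------------------------------------------------------
# Simplex (purest-pixel) rotation
# ---------------------------------------------------------------------------

class TestSimplexInit:
    def test_recovers_pure_components(self, rng):
        C, S, D = _three_component_problem(rng)
        scores, loadings = nipals_decompose(D, 3)
        S0 = simplex_initial_estimates(scores, loadings)
        best = [max(abs(_corr(S0[:, i], S[:, j])) for i in range(3))
                for j in range(3)]
        assert min(best) >= 0.999

    def test_shape_validation(self, rng):
        with pytest.raises(InvalidParameterError):
            simplex_initial_estimates(rng.normal(size=(5, 2)),
                                      rng.normal(size=(7, 3)))

    def test_needs_k_pixels(self, rng):
        with pytest.raises(InvalidParameterError):
            simplex_initial_estimates(rng.normal(size=(2, 3)),
                                      rng.normal(size=(7, 3)))

    def test_deterministic(self, rng):
        C, S, D = _three_component_problem(rng)
        scores, loadings = nipals_decompose(D, 3)
        a = simplex_initial_estimates(scores, loadings)
        b = simplex_initial_estimates(scores, loadings)
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# lack_of_fit
# ---------------------------------------------------------------------------

class TestLackOfFit:
    def test_perfect_reconstruction(self, rng):
        C, S, D = _three_component_problem(rng)
        assert lack_of_fit(D, C=C, S=S) == pytest.approx(0.0, abs=1e-10)

    def test_zero_model_is_100(self, rng):
        D = rng.normal(size=(5, 4))
        assert lack_of_fit(D, C=np.zeros((5, 2)),
                           S=np.zeros((4, 2))) == pytest.approx(100.0)

    def test_matches_direct_formula(self, rng):
        D = rng.normal(size=(6, 5))
        C = rng.normal(size=(6, 2))
        S = rng.normal(size=(5, 2))
        resid = D - C @ S.T
        expected = 100.0 * np.sqrt((resid ** 2).sum() / (D ** 2).sum())
        assert lack_of_fit(D, C=C, S=S) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_data_rejected(self):
        with pytest.raises(DegenerateInputError):
            lack_of_fit(np.zeros((4, 3)), C=np.zeros((4, 1)),
                        S=np.zeros((3, 1)))


# ---------------------------------------------------------------------------
# ALS
# ---------------------------------------------------------------------------

class TestAls:
    def test_near_truth_init_recovery(self, rng):
        C, S, D = _three_component_problem(rng)
        init = S + 0.05 * rng.normal(size=S.shape) * np.abs(S).max()
        model = als_optimize(D, init, max_iter=500, tol=1e-12)
        for j in range(3):
            assert max(abs(_corr(model.S[:, i], S[:, j]))
                       for i in range(3)) >= 0.999
        assert model.lack_of_fit < 1e-6

    def test_exact_init_fixed_point(self, rng):
        C, S, D = _three_component_problem(rng)
        model = als_optimize(D, S.copy())
        assert model.iterations_run <= 2
        assert model.lack_of_fit == pytest.approx(0.0, abs=1e-8)
        assert model.converged

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_lof_history_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        C, S, D = _three_component_problem(rng)
        D = D + 0.01 * rng.normal(size=D.shape)
        init = rng.uniform(0, 1, size=S.shape)
        model = als_optimize(D, init, ConstraintSpec(0.5, 0.0))
        hist = np.asarray(model.lof_history)
        assert np.all(np.diff(hist) <= 1e-12)
        assert model.lack_of_fit == pytest.approx(hist[-1])

    def test_unit_norm_profiles(self, rng):
        C, S, D = _three_component_problem(rng)
        model = als_optimize(D + 0.01 * rng.normal(size=D.shape),
                             rng.uniform(0, 1, size=S.shape))
        assert np.allclose(np.linalg.norm(model.S, axis=0), 1.0)

    def test_zero_init_column_rejected(self, rng):
        C, S, D = _three_component_problem(rng)
        bad = S.copy()
        bad[:, 1] = 0.0
        with pytest.raises(InvalidParameterError):
            als_optimize(D, bad)

    def test_constraint_strength_validated(self):
        with pytest.raises(InvalidParameterError):
            ConstraintSpec(alpha_C=1.5)


# ---------------------------------------------------------------------------
# Rotational-ambiguity honesty
# ---------------------------------------------------------------------------

def test_overlapping_profiles_recover_subspace(rng):
    """Heavily overlapping 2-component mixtures: individual factors are only
    identified up to the feasible rotations, but the recovered 2-D spectral
    subspace must agree with the truth (principal angles < 1 degree)."""
    x = np.linspace(0, 1, 150)
    S = np.column_stack([np.exp(-((x - 0.45) / 0.12) ** 2),
                         np.exp(-((x - 0.55) / 0.12) ** 2)])
    S /= np.linalg.norm(S, axis=0)
    t = np.linspace(0, 1, 300)
    C = np.column_stack([0.4 + 0.3 * np.exp(-((t - 0.45) / 0.3) ** 2),
                         0.4 + 0.3 * np.exp(-((t - 0.55) / 0.3) ** 2)])
    D = C @ S.T + 1e-6 * rng.normal(size=(300, 150))
    scores, loadings = nipals_decompose(D, 2)
    model = als_optimize(D, simplex_initial_estimates(scores, loadings))
    angles = subspace_angles(model.S, S)
    assert np.degrees(angles).max() < 1.0


# ---------------------------------------------------------------------------
# resolve on the phantom
# ---------------------------------------------------------------------------

class TestResolve:
    def test_pg1_factor_found(self, phantom_default, model5):
        _, _, truth, _ = phantom_default
        lib = truth.true_spectra
        sel = np.isin(lib.axis.values, model5.axis.values)
        ref = -lib.second_derivative("PG1")[sel]
        best = max(abs(_corr(model5.S[:, i], ref)) for i in range(5))
        assert best >= 0.95

    def test_k_range_returns_models(self, preprocessed):
        deriv, mask = preprocessed
        models = resolve(deriv, mask, range(2, 4), max_iter=30)
        assert [m.k for m in models] == [2, 3]
        for m in models:
            assert np.allclose(np.linalg.norm(m.S, axis=0), 1.0)
            assert np.all(np.diff(m.lof_history) <= 1e-12)

    def test_requires_second_derivative(self, phantom_default, preprocessed):
        _, image, _, _ = phantom_default
        _, mask = preprocessed
        with pytest.raises(InvalidParameterError):
            resolve(image, mask, 5)

    def test_empty_mask_impossible(self):
        with pytest.raises(EmptyMaskError):
            PixelMask(np.zeros((4, 4), dtype=bool))

    def test_model_region_and_axis_recorded(self, model5):
        assert model5.region == (950.0, 1300.0)
        assert model5.axis is not None
        nu = model5.axis.values
        assert nu.min() >= 950.0 and nu.max() <= 1300.0


def test_k_stability_of_pg1_profile(phantom_default, preprocessed, model5):
    """The PG1-assigned profile barely changes across k = 4, 5, 6."""
    _, _, truth, _ = phantom_default
    deriv, mask = preprocessed
    profiles = []
    for model in (resolve(deriv, mask, 4), model5, resolve(deriv, mask, 6)):
        asg = assign_factors(model, truth.true_spectra, region=model.region)
        profiles.append(model.S[:, asg.component_factor("PG1")])
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            assert _corr(profiles[i], profiles[j]) >= 0.9
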