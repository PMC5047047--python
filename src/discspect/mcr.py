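"""Multivariate curve resolution by alternating least squares (MCR-ALS).

The bilinear model: a data matrix D (pixels x channels) of Beer-Lambert
mixtures factorizes as D ~= C S^T, with C the per-pixel component
concentrations and S the component spectral profiles. Abstract factors are
first extracted by NIPALS (sequential power iteration with deflation; an
SVD initializer is provided as the mathematically equivalent alternative)
rotated onto their purest-pixel simplex vertices (the abstract-to-chemical
transformation), and then refined by alternating least squares under soft
constraints until the lack of fit stabilizes.

Constrained bilinear factorizations are only identifiable up to the
rotations that keep every constraint satisfied; alternating least squares
essentially preserves whatever mixture its initial estimates encode. The
purest-pixel rotation therefore does the chemical work: it deterministically
picks the most mutually extreme pixels of the eigenanalysis score simplex
(whose spectra are closest to single components) and uses their
noise-filtered spectra as the starting profiles.

Soft non-negativity is implemented as a blend toward the non-negative
projection after each unconstrained half-step, X <- (1 - a) X + a max(X, 0),
applied to the concentrations by default (a = 0.5) and optionally to the
spectra; a = 1 reproduces hard clipping, a = 0 disables the constraint.
This is a transparent surrogate for proprietary soft-constraint schemes in
commercial MCR software.

Sign/scale conventions: profiles in S are unit-norm with the largest-
magnitude lobe positive; C carries the magnitude. Second-derivative images
are negated before resolution so absorbance bands appear as positive peaks
and non-negativity of C is meaningful ("working orientation").
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .errors import (
    DegenerateInputError,
    EmptyMaskError,
    InvalidParameterError,
)
from .spectra import HyperspectralImage, PixelMask, WavenumberAxis, select_region

__all__ = [
    "ConstraintSpec",
    "MCRModel",
    "nipals_decompose",
    "svd_initial_estimates",
    "simplex_initial_estimates",
    "als_optimize",
    "lack_of_fit",
    "resolve",
]

_RIDGE_REL = 1e-10  # relative ridge for degenerate normal equations


@dataclass(frozen=True)
class ConstraintSpec:
    """Soft-constraint strengths for the ALS half-steps.

    ``alpha_C``/``alpha_S`` blend the concentration/spectra estimates toward
    their non-negative projections (0 = unconstrained, 1 = hard clip).
    Spectra are left unconstrained by default because in the working
    orientation second-derivative profiles legitimately carry negative
    side lobes.
    """

    alpha_C: float = 0.5
    alpha_S: float = 0.0

    def __post_init__(self):
        for a in (self.alpha_C, self.alpha_S):
            if not 0.0 <= a <= 1.0:
                raise InvalidParameterError("constraint strengths lie in [0, 1]")


@dataclass
class MCRModel:
    """An MCR-ALS resolution: D ~= C S^T plus fit diagnostics."""

    k: int
    C: np.ndarray                      # (n_pixels_unmasked, k)
    S: np.ndarray                      # (n_channels, k)
    iterations_run: int
    lof_history: list[float]
    converged: bool
    init_method: str = "custom"
    axis: WavenumberAxis | None = None
    mask: PixelMask | None = None
    region: tuple[float, float] | None = None

    def __post_init__(self):
        if self.C.shape[1] != self.k or self.S.shape[1] != self.k:
            raise InvalidParameterError("C/S column counts must equal k")
        if not (np.all(np.isfinite(self.C)) and np.all(np.isfinite(self.S))):
            raise InvalidParameterError("model contains non-finite values")

    @property
    def lack_of_fit(self) -> float:
        return self.lof_history[-1] if self.lof_history else float("nan")

    def reconstruction(self) -> np.ndarray:
        return self.C @ self.S.T


def _fix_signs(scores: np.ndarray, loadings: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Flip factor signs so each profile's largest-magnitude lobe is positive."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    return scores, loadings


def nipals_decompose(D: np.ndarray, k: int, tol: float = 1e-12,
                     max_inner_iter: int = 1000
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Sequential NIPALS extraction of k rank-1 terms (no mean centring).

    Each factor is found by power iteration on the deflated residual:
    p <- X^T t / (t^T t), p <- p/|p|, t <- X p, until t stabilizes; then
    X <- X - t p^T. Loadings are unit-norm; on well-conditioned input the
    k-term reconstruction matches the truncated SVD.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise InvalidParameterError("D must be a matrix")
    if not np.all(np.isfinite(D)):
        raise InvalidParameterError("D must be finite")
    if not 1 <= k <= min(D.shape):
        raise InvalidParameterError(f"k={k} out of range for shape {D.shape}")

    X = D.copy()
    n, m = X.shape
    scores = np.empty((n, k))
    loadings = np.empty((m, k))
    for j in range(k):
        t = X[:, int(np.argmax((X * X).sum(axis=0)))].copy()
        if np.linalg.norm(t) == 0.0:   # residual exhausted: zero factor
            scores[:, j] = 0.0
            loadings[:, j] = 0.0
            loadings[j % m, j] = 1.0
            continue
        converged = False
        for _ in range(max_inner_iter):
            p = X.T @ t
            p_norm = np.linalg.norm(p)
            if p_norm == 0.0:
                break
            p /= p_norm
            t_new = X @ p
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                converged = True
                break
            t = t_new
        else:
            p = X.T @ t
            p /= np.linalg.norm(p)
        if not converged:
            warnings.warn(f"NIPALS factor {j} stopped at max_inner_iter; "
                          "returning best iterate", RuntimeWarning)
        scores[:, j] = t
        loadings[:, j] = p
        X -= np.outer(t, p)
    return _fix_signs(scores, loadings)


def svd_initial_estimates(D: np.ndarray, k: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Truncated SVD in score/loading form (the NIPALS cross-check)."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise InvalidParameterError("D must be a matrix")
    if not np.all(np.isfinite(D)):
        raise InvalidParameterError("D must be finite")
    if not 1 <= k <= min(D.shape):
        raise InvalidParameterError(f"k={k} out of range for shape {D.shape}")
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    return _fix_signs(scores, loadings)


def simplex_initial_estimates(scores: np.ndarray, loadings: np.ndarray
                              ) -> np.ndarray:
    """Rotate abstract factors onto their purest-pixel simplex vertices.

    Greedy orthogonal-projection vertex search in score space: start at the
    pixel with the largest score norm, then repeatedly take the pixel whose
    score vector has the largest residual after projecting out the vertices
    already chosen. The k vertex pixels are the most mutually extreme points
    of the data simplex, i.e. the pixels closest to pure components; their
    rank-k reconstructed spectra (loadings @ score, hence noise-filtered)
    become the initial spectral estimates, unit-norm and sign-fixed.

    Deterministic; ties broken by the lowest pixel index (argmax semantics).
    """
    scores = np.asarray(scores, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if scores.ndim != 2 or loadings.ndim != 2 \
            or scores.shape[1] != loadings.shape[1]:
        raise InvalidParameterError(
            "scores and loadings must be matrices with matching k")
    if not (np.all(np.isfinite(scores)) and np.all(np.isfinite(loadings))):
        raise InvalidParameterError("scores/loadings must be finite")
    k = scores.shape[1]
    if scores.shape[0] < k:
        raise InvalidParameterError("need at least k pixels to pick vertices")

    vertices = [int(np.argmax((scores * scores).sum(axis=1)))]
    for _ in range(k - 1):
        Q, _ = np.linalg.qr(scores[vertices].T)
        resid = scores - (scores @ Q) @ Q.T
        vertices.append(int(np.argmax((resid * resid).sum(axis=1))))

    S0 = loadings @ scores[vertices].T          # (n_channels, k)
    norms = np.linalg.norm(S0, axis=0)
    if np.any(norms == 0):
        raise DegenerateInputError("a vertex pixel has a zero spectrum")
    S0 = S0 / norms
    _, S0 = _fix_signs(np.zeros_like(S0), S0)
    return S0


def lack_of_fit(D: np.ndarray, model: MCRModel | None = None,
                C: np.ndarray | None = None, S: np.ndarray | None = None
                ) -> float:
    """Percent residual norm: 100 * sqrt(sum (D - C S^T)^2 / sum D^2)."""
    D = np.asarray(D, dtype=float)
    if model is not None:
        C, S = model.C, model.S
    if C.shape[0] != D.shape[0] or S.shape[0] != D.shape[1]:
        raise InvalidParameterError("model shapes inconsistent with D")
    denom = float(np.sum(D * D))
    if denom == 0.0:
        raise DegenerateInputError("all-zero data matrix")
    resid = D - C @ S.T
    return 100.0 * float(np.sqrt(np.sum(resid * resid) / denom))


def _solve_half_step(D: np.ndarray, F: np.ndarray, transpose: bool
                     ) -> np.ndarray:
    """OLS half-step: argmin_X |D - X F^T| (or |D - F X^T| when transpose).

    Falls back to a small ridge when the normal equations are degenerate.
    """
    G = F.T @ F
    rhs = (D @ F) if not transpose else (D.T @ F)
    try:
        if np.linalg.cond(G) > 1e12:
            raise np.linalg.LinAlgError
        return np.linalg.solve(G, rhs.T).T
    except np.linalg.LinAlgError:
        lam = _RIDGE_REL * np.trace(G) / G.shape[0]
        lam = lam if lam > 0 else _RIDGE_REL
        warnings.warn("rank-deficient half-step; using ridge fallback",
                      RuntimeWarning)
        return np.linalg.solve(G + lam * np.eye(G.shape[0]), rhs.T).T


def _soften(X: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0.0:
        return X
    return (1.0 - alpha) * X + alpha * np.maximum(X, 0.0)


def als_optimize(D: np.ndarray, init_S: np.ndarray,
                 constraints: ConstraintSpec | None = None,
                 max_iter: int = 500, tol: float = 1e-6,
                 init_method: str = "custom") -> MCRModel:
    """Alternating least squares from initial spectral estimates.

    Each iteration solves the two OLS half-steps (C given S, then S given C),
    applies the soft non-negativity operator after each, renormalizes S
    columns to unit norm (C absorbs the scale), and evaluates the lack of
    fit. The best iterate seen so far is retained and returned, and the
    recorded history is its running (non-increasing) lack of fit, so
    transient increases from the constraint blending cannot degrade the
    returned model. Iteration stops when the relative lack-of-fit change
    between consecutive iterates drops below ``tol``, when the best lack of
    fit has not improved by a relative ``tol`` for 50 iterations, or at
    ``max_iter``.
    """
    D = np.asarray(D, dtype=float)
    S = np.asarray(init_S, dtype=float).copy()
    if S.ndim != 2 or S.shape[0] != D.shape[1]:
        raise InvalidParameterError("init_S must be (n_channels, k)")
    if not np.all(np.isfinite(D)):
        raise InvalidParameterError("D must be finite")
    constraints = constraints or ConstraintSpec()
    k = S.shape[1]

    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        raise InvalidParameterError("init_S has a zero column")
    S = S / norms

    lof_hist: list[float] = []
    best_lof = np.inf
    best_C = best_S = None
    prev_lof = None
    stall = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = _soften(_solve_half_step(D, S, transpose=False), constraints.alpha_C)
        S_new = _soften(_solve_half_step(D, C, transpose=True),
                        constraints.alpha_S)
        norms = np.linalg.norm(S_new, axis=0)
        norms[norms == 0] = 1.0
        S_new /= norms
        C *= norms
        S = S_new
        lof = lack_of_fit(D, C=C, S=S)
        if lof < best_lof * (1.0 - tol) or best_C is None:
            stall = 0
        else:
            stall += 1
        if lof < best_lof or best_C is None:
            best_lof, best_C, best_S = lof, C.copy(), S.copy()
        lof_hist.append(best_lof)
        # Relative-change stop, with an absolute floor of tol**2 so that a
        # fit already at machine-level LOF (where round-off fluctuations are
        # relatively large) is recognized as converged.
        if prev_lof is not None \
                and abs(prev_lof - lof) <= tol * max(prev_lof, tol):
            converged = True
            break
        if stall >= 50:
            converged = True
            break
        prev_lof = lof

    C, S = best_C, best_S
    # Sign convention: concentrations predominantly positive (so the
    # dominant absorbance lobe of the profile is positive in the working
    # orientation); the lobe rule alone decides for balanced columns.
    for j in range(k):
        total = float(C[:, j].sum())
        flip = total < 0 or (total == 0.0
                             and S[np.argmax(np.abs(S[:, j])), j] < 0)
        if flip:
            C[:, j] = -C[:, j]
            S[:, j] = -S[:, j]
    return MCRModel(k=k, C=C, S=S, iterations_run=it,
                    lof_history=lof_hist, converged=converged,
                    init_method=init_method)


def resolve(image: HyperspectralImage, mask: PixelMask, k,
            region: tuple[float, float] = (950.0, 1300.0),
            init_method: str = "nipals",
            constraints: ConstraintSpec | None = None,
            max_iter: int = 500, tol: float = 1e-6):
    """Resolve a masked 2nd-derivative image over a spectral region.

    Orchestrates region selection, masked-pixel matrix assembly (the matrix
    fed to ALS is the negated 2nd derivative; see module docstring),
    NIPALS/SVD eigenanalysis, the purest-pixel simplex rotation of the
    abstract factors (see :func:`simplex_initial_estimates`) and ALS
    refinement. ``k`` may be an int or an iterable of factor counts
    (e.g. range(4, 7)); a list of models is returned for an iterable.
    """
    if image.derivative_order != 2:
        raise InvalidParameterError("resolve expects a 2nd-derivative image")
    mask.check_matches(image)
    if isinstance(k, (list, tuple, range)):
        return [resolve(image, mask, kk, region, init_method, constraints,
                        max_iter, tol) for kk in k]
    k = int(k)

    sub = select_region(image, *region)
    flat_mask = mask.included.ravel()
    if not flat_mask.any():
        raise EmptyMaskError("mask excludes every pixel")
    X = -sub.as_matrix()[flat_mask]          # working orientation

    if init_method == "nipals":
        scores, loadings = nipals_decompose(X, k)
    elif init_method == "svd":
        scores, loadings = svd_initial_estimates(X, k)
    else:
        raise InvalidParameterError(f"unknown init method {init_method!r}")
    init_S = simplex_initial_estimates(scores, loadings)

    model = als_optimize(X, init_S, constraints, max_iter, tol,
                         init_method=init_method)
    model.axis = sub.axis
    model.mask = mask
    model.region = (float(min(region)), float(max(region)))
    return model
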