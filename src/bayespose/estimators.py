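"""Orientation estimators: likelihood, posterior weights, MLE / MAP / MMSE.

Given an observation ``y = Pi(g o V) + eps`` with ``eps ~ N(0, sigma^2 I)``,
the continuous posterior over the rotation is discretized on a
:class:`~bayespose.so3.RotationGrid` with nodes ``g_l`` and quadrature
weights ``lambda_l``.  Writing ``x_l = Pi(g_l o V)`` for the templates, the
posterior quadrature weights are

    w_l  ∝  lambda_l * Prior(g_l) * exp(-||y - x_l||^2 / (2 sigma^2)),

normalized to sum to one.  The three estimators are

* MLE  — the grid node minimizing ``||y - x_l||^2`` (no prior);
* MAP  — the node maximizing ``lambda_l * Prior(g_l) * likelihood``;
* MMSE — the posterior-mean matrix ``E = sum_l w_l g_l`` projected back
  onto SO(3) by the orthogonal Procrustes solution.  This is the Bayes
  estimator for the squared chordal loss.

All weight computations happen in the log domain with max-subtraction, so
they remain finite for sigma down to 1e-6 (the max term always maps to
exp(0) = 1).

For grids of flavor ``iid-sample`` drawn from a non-uniform prior, the
prior is already encoded in the node distribution (Monte-Carlo quadrature
w.r.t. the prior); pass ``PriorSO3.uniform()`` so the density factor is not
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .forward_model import Observation, PolarImage2D, Volume3D, polar_rotate, project_volume, rotate_volume
from .so3 import (
    DegenerateProjectionError,
    PriorSO3,
    RotationGrid,
    check_rotation,
    procrustes_project,
)

__all__ = [
    "PosteriorWeights",
    "EstimationResult",
    "TemplateCache",
    "negative_log_likelihood",
    "posterior_weights",
    "estimate_mle",
    "estimate_map",
    "estimate_mmse",
    "mmse_back_rotate",
    "fast_polar_correlations",
]


@dataclass(frozen=True)
class PosteriorWeights:
    """Normalized posterior weights over a rotation grid.

    ``log_norm`` is the log of the quadrature approximation of the
    marginal likelihood p(y) (Gaussian constant included).
    """

    weights: np.ndarray
    grid_ref: RotationGrid
    log_norm: float

    def __post_init__(self) -> None:
        w = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
        if w.shape != (len(self.grid_ref),):
            raise ValueError("weights must align with grid nodes")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be a probability vector")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class EstimationResult:
    """A point estimate of the rotation.

    ``g_hat`` is always a 3x3 rotation matrix.  For grid-search estimators
    (MLE/MAP) ``node_index`` records the selected node.  For the MMSE
    estimator ``pre_projection`` holds the intermediate posterior-mean
    matrix (generally not in SO(3)) whose Procrustes projection is
    ``g_hat``; ``degenerate`` flags the measure-zero case where the
    projection was not unique and the MAP node was used instead.
    """

    g_hat: np.ndarray
    method: str
    node_index: int | None = None
    pre_projection: np.ndarray | None = None
    weights_ref: PosteriorWeights | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def cyclic_shift_indices(grid: RotationGrid, l_theta: int) -> np.ndarray:
    """Map cyclic-grid nodes (z-rotations) to angular shift indices.

    A node rotating by 2*pi*k/L corresponds to a shift of k * l_theta / L
    samples, which must be an integer for the action to be exact.
    """
    angles = np.arctan2(grid.nodes[:, 1, 0], grid.nodes[:, 0, 0]) % (2 * np.pi)
    shifts = angles * l_theta / (2 * np.pi)
    rounded = np.rint(shifts).astype(int) % l_theta
    if not np.allclose(shifts % l_theta, rounded % l_theta, atol=1e-9):
        raise ValueError("cyclic grid angles do not land on the polar angular samples")
    return rounded


def _render_template(ref, g, model: str) -> np.ndarray:
    if model == "polar-2d":
        return polar_rotate(ref, int(g)).grid
    if model == "subtomogram-3d":
        return rotate_volume(ref, g).grid
    if model == "projection-2d":
        return project_volume(rotate_volume(ref, g))
    raise ValueError(f"unknown model tag {model!r}")


class TemplateCache:
    """Precomputed templates x_l = Pi(g_l o V) for one (reference, grid) pair.

    Stored as an (L, d) float64 matrix of flattened templates, shared
    across observations; the dominant cost of grid search is then a single
    matrix-vector (or matrix-matrix, when observations are batched)
    product.
    """

    def __init__(self, ref, grid: RotationGrid, model: str):
        self.grid = grid
        self.model = model
        self.ref = ref
        if model == "polar-2d":
            if not isinstance(ref, PolarImage2D):
                raise TypeError("polar-2d model requires a PolarImage2D reference")
            self.shifts = cyclic_shift_indices(grid, ref.l_theta)
            tmpl = np.stack(
                [_render_template(ref, k, model).ravel() for k in self.shifts]
            )
        else:
            if not isinstance(ref, Volume3D):
                raise TypeError(f"{model} model requires a Volume3D reference")
            tmpl = np.stack(
                [_render_template(ref, g, model).ravel() for g in grid.nodes]
            )
        self.templates = tmpl
        self.sq_norms = np.einsum("ld,ld->l", tmpl, tmpl)

    @property
    def d(self) -> int:
        return self.templates.shape[1]

    def residual_sq(self, y_flat: np.ndarray) -> np.ndarray:
        """||y - x_l||^2 for all nodes (one observation)."""
        return self.residual_sq_batch(y_flat[None])[0]

    def residual_sq_batch(self, Y: np.ndarray) -> np.ndarray:
        """||y_i - x_l||^2 for a (T, d) batch of observations -> (T, L)."""
        ysq = np.einsum("td,td->t", Y, Y)
        cross = Y @ self.templates.T
        r = ysq[:, None] + self.sq_norms[None, :] - 2.0 * cross
        return np.maximum(r, 0.0)


def _as_cache(ref, grid, model, cache: TemplateCache | None) -> TemplateCache:
    if cache is not None:
        if cache.grid is not grid or cache.model != model:
            raise ValueError("template cache does not match grid/model")
        return cache
    return TemplateCache(ref, grid, model)


# ---------------------------------------------------------------------------
# likelihood and posterior
# ---------------------------------------------------------------------------


def negative_log_likelihood(y: Observation, ref, g) -> float:
    """Negative log of the Gaussian conditional density of y given rotation g:

        ||y - Pi(g o V)||^2 / (2 sigma^2) + (d/2) log(2 pi sigma^2).

    For the polar-2d model ``g`` is the integer cyclic-shift index;
    otherwise it is a 3x3 rotation matrix.
    """
    if y.model != "polar-2d":
        g = check_rotation(g)
    if np.any(~np.isfinite(y.data)):
        raise ValueError("observation contains non-finite values")
    x = _render_template(ref, g, y.model)
    if x.shape != y.data.shape:
        raise ValueError(f"template shape {x.shape} != observation shape {y.data.shape}")
    d = y.data.size
    resid = float(np.sum((y.data - x) ** 2))
    return resid / (2.0 * y.sigma**2) + 0.5 * d * np.log(2.0 * np.pi * y.sigma**2)


def _log_prior_terms(grid: RotationGrid, prior: PriorSO3) -> np.ndarray:
    """log(lambda_l * Prior(g_l)) over the grid nodes."""
    with np.errstate(divide="ignore"):
        lw = np.log(grid.weights)
        if prior.kind != "uniform":
            lw = lw + np.log(np.maximum(prior.density(grid.nodes), 1e-300))
    return lw


def _log_posterior(
    resid_sq: np.ndarray, sigma: float, log_prior: np.ndarray, d: int
) -> tuple[np.ndarray, float]:
    """Stabilized log posterior weights and log marginal likelihood."""
    logits = log_prior - resid_sq / (2.0 * sigma**2)
    m = logits.max(axis=-1, keepdims=True)
    log_w = logits - m - np.log(np.exp(logits - m).sum(axis=-1, keepdims=True))
    log_norm = logsumexp(logits, axis=-1) - 0.5 * d * np.log(2.0 * np.pi * sigma**2)
    return log_w, log_norm


def posterior_weights(
    y: Observation,
    ref,
    grid: RotationGrid,
    prior: PriorSO3 | None = None,
    cache: TemplateCache | None = None,
) -> PosteriorWeights:
    """Posterior quadrature weights of the rotation given one observation."""
    if np.any(~np.isfinite(y.data)):
        raise ValueError("observation contains non-finite values")
    prior = prior or PriorSO3.uniform()
    cache = _as_cache(ref, grid, y.model, cache)
    resid = cache.residual_sq(y.data.ravel())
    log_w, log_norm = _log_posterior(resid, y.sigma, _log_prior_terms(grid, prior), cache.d)
    w = np.exp(log_w)
    w /= w.sum()
    return PosteriorWeights(w, grid, float(log_norm))


def estimate_mle(
    y: Observation, ref, grid: RotationGrid, cache: TemplateCache | None = None
) -> EstimationResult:
    """Grid-search maximum-likelihood estimate: the node with the smallest
    residual ``||y - x_l||^2``.  Ties (measure-zero under noise) break to
    the lowest node index.  Independent of any prior."""
    cache = _as_cache(ref, grid, y.model, cache)
    resid = cache.residual_sq(y.data.ravel())
    idx = int(np.argmin(resid))
    return EstimationResult(grid.nodes[idx], "mle", node_index=idx)


def estimate_map(
    y: Observation,
    ref,
    grid: RotationGrid,
    prior: PriorSO3 | None = None,
    cache: TemplateCache | None = None,
) -> EstimationResult:
    """Maximum a posteriori on the grid: argmax of
    ``lambda_l * Prior(g_l) * exp(-||y - x_l||^2 / (2 sigma^2))``.

    With a uniform prior and equal quadrature weights this coincides with
    the MLE.
    """
    prior = prior or PriorSO3.uniform()
    cache = _as_cache(ref, grid, y.model, cache)
    resid = cache.residual_sq(y.data.ravel())
    logits = _log_prior_terms(grid, prior) - resid / (2.0 * y.sigma**2)
    idx = int(np.argmax(logits))
    return EstimationResult(grid.nodes[idx], "map", node_index=idx)


def estimate_mmse(
    y: Observation,
    ref,
    grid: RotationGrid,
    prior: PriorSO3 | None = None,
    cache: TemplateCache | None = None,
) -> EstimationResult:
    """Bayes (MMSE) estimate under squared chordal loss.

    Forms the posterior-mean matrix ``E = sum_l w_l g_l`` in the 3x3
    embedding, then projects onto SO(3) via orthogonal Procrustes.  In the
    measure-zero degenerate case (two vanishing singular values of E) the
    MAP node is returned and the result flagged.
    """
    prior = prior or PriorSO3.uniform()
    cache = _as_cache(ref, grid, y.model, cache)
    w = posterior_weights(y, ref, grid, prior, cache=cache)
    E = np.einsum("l,lij->ij", w.weights, grid.nodes)
    try:
        g_hat = procrustes_project(E)
        degenerate = False
    except DegenerateProjectionError:
        g_hat = estimate_map(y, ref, grid, prior, cache=cache).g_hat
        degenerate = True
    return EstimationResult(
        g_hat, "mmse", pre_projection=E, weights_ref=w, degenerate=degenerate
    )


def mmse_back_rotate(
    y: Observation,
    ref,
    grid: RotationGrid,
    prior: PriorSO3 | None = None,
    cache: TemplateCache | None = None,
    weights: PosteriorWeights | None = None,
) -> np.ndarray:
    """Posterior average of the inverse action applied to the observation:

        sum_l w_l * (g_l^{-1} o y).

    This is a linear operator acting on y — the E-step aggregation of the
    EM algorithm — and is NOT in general the same as applying the inverse
    of the MMSE rotation estimate (the average of inverse actions is not a
    group element).  Only no-projection models are supported: the
    projection operator discards the information needed to undo the
    rotation in the measurement domain.
    """
    if y.model == "projection-2d":
        raise ValueError("mmse_back_rotate requires a no-projection model")
    prior = prior or PriorSO3.uniform()
    if weights is None:
        weights = posterior_weights(y, ref, grid, prior, cache=cache)
    w = weights.weights
    out = np.zeros_like(y.data)
    if y.model == "polar-2d":
        for k, wk in zip(cyclic_shift_indices(grid, y.data.shape[1]), w):
            if wk == 0.0:
                continue
            out += wk * np.roll(y.data, -k, axis=1)
    else:
        vol = Volume3D(y.data, voxel_size=getattr(ref, "voxel_size", 1.0))
        for g, wk in zip(grid.nodes, w):
            if wk < 1e-14:
                continue
            out += wk * rotate_volume(vol, g.T).grid
    return out


def fast_polar_correlations(y: PolarImage2D, template: PolarImage2D) -> np.ndarray:
    """Residuals ``||y - shift_k(template)||^2`` for every cyclic shift k,
    evaluated simultaneously with an FFT along the angular axis
    (O(d_r * L_theta * log L_theta) instead of O(d_r * L_theta^2))."""
    if y.grid.shape != template.grid.shape:
        raise ValueError("polar grids do not match")
    Yf = np.fft.rfft(y.grid, axis=1)
    Tf = np.fft.rfft(template.grid, axis=1)
    # cross[k] = sum_{r,theta} y[r,theta] * t[r, (theta - k) mod L]
    cross = np.fft.irfft(Yf * np.conj(Tf), n=y.l_theta, axis=1).sum(axis=0)
    return float(np.sum(y.grid**2) + np.sum(template.grid**2)) - 2.0 * cross
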