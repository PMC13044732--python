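"""Iterative structure recovery from rotated noisy copies.

Model: M i.i.d. observations ``y_i = g_i o V + eps_i`` with unknown Haar
(or prior-) distributed rotations and isotropic Gaussian noise — no
projection (cryo-ET subtomogram averaging, or 2D polar image recovery).

Soft assignment (EM): the M-step averages the MMSE back-rotations,

    V^{t+1} = (1/M) sum_i  sum_l w_il * (g_l^{-1} o y_i),

where ``w_il`` are the posterior weights of observation i under the
current estimate V^t.  Hard assignment replaces the posterior average by
the single best node,

    V^{t+1} = (1/M) sum_i  g_MLE(y_i; V^t)^{-1} o y_i.

Both iterate until the relative change falls below ``tol`` (default 1e-3)
or ``max_iter`` (default 100) is reached.  The discretized marginal
log-likelihood is recorded every iteration; for the exact cyclic 2D-polar
action it is non-decreasing (EM monotonicity), in 3D only up to
interpolation error.

Implementation note: the double sum of the M-step is reordered as
``sum_l g_l^{-1} o (sum_i w_il y_i / M)`` so only L back-rotations are
applied per iteration regardless of M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import TemplateCache, _log_posterior, _log_prior_terms
from .forward_model import Observation, PolarImage2D, Volume3D
from .so3 import PriorSO3, RotationGrid

__all__ = [
    "ObservationSet",
    "EMState",
    "em_reconstruct",
    "hard_assign_reconstruct",
    "pearson_cc",
    "align_global",
    "template_bias_score",
]


@dataclass(frozen=True)
class ObservationSet:
    """M observations sharing a noise level and measurement model.

    ``data`` is the (M, *shape) stack; ``true_rotations`` (matrices) or
    ``true_shifts`` (cyclic indices) are optional simulation bookkeeping.
    """

    data: np.ndarray
    sigma: float
    model: str
    true_rotations: np.ndarray | None = None
    true_shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.ascontiguousarray(np.asarray(self.data, dtype=float))
        if len(data) < 1:
            raise ValueError("observation set must be non-empty")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "data", data)

    @classmethod
    def from_observations(cls, observations: list[Observation], **kw) -> "ObservationSet":
        if not observations:
            raise ValueError("observation set must be non-empty")
        sigma = observations[0].sigma
        model = observations[0].model
        if any(o.sigma != sigma or o.model != model for o in observations):
            raise ValueError("observations must share sigma and model")
        return cls(np.stack([o.data for o in observations]), sigma, model, **kw)

    def __len__(self) -> int:
        return len(self.data)

    def observation(self, i: int) -> Observation:
        return Observation(self.data[i], self.sigma, self.model)


@dataclass
class EMState:
    """Iteration state of the reconstruction loop."""

    estimate: object  # Volume3D or PolarImage2D
    iteration: int
    rel_change: float
    converged: bool
    loglik_trace: list = field(default_factory=list)
    diverged: bool = False


def _wrap(arr: np.ndarray, like) -> object:
    if isinstance(like, Volume3D):
        return Volume3D(arr, like.voxel_size)
    return PolarImage2D(arr)


def _log_weights_all(
    obs: ObservationSet, cache: TemplateCache, log_prior: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(M, L) stabilized log posterior weights and per-observation log p(y_i)."""
    Y = obs.data.reshape(len(obs), -1)
    resid = cache.residual_sq_batch(Y)
    return _log_posterior(resid, obs.sigma, log_prior, cache.d)


def _soft_m_step(obs: ObservationSet, W: np.ndarray, grid: RotationGrid, ref) -> np.ndarray:
    """(1/M) sum_l g_l^{-1} o (sum_i w_il y_i), reordered for L back-rotations."""
    from .forward_model import rotate_volume

    M = len(obs)
    Y = obs.data.reshape(M, -1)
    node_sums = (W.T @ Y) / M  # (L, d)
    out = np.zeros(obs.data.shape[1:])
    if obs.model == "polar-2d":
        from .estimators import cyclic_shift_indices

        for k, s in zip(cyclic_shift_indices(grid, out.shape[1]), node_sums):
            out += np.roll(s.reshape(out.shape), -k, axis=1)
    else:
        vx = getattr(ref, "voxel_size", 1.0)
        for g, s in zip(grid.nodes, node_sums):
            if np.abs(s).max() == 0.0:
                continue
            out += rotate_volume(Volume3D(s.reshape(out.shape), vx), g.T).grid
    return out


def _run(
    obs: ObservationSet,
    init,
    grid: RotationGrid,
    prior: PriorSO3,
    tol: float,
    max_iter: int,
    hard: bool,
) -> EMState:
    if len(obs) < 1:
        raise ValueError("empty observation set")
    if obs.model == "projection-2d":
        raise ValueError("reconstruction requires a no-projection model")
    prior = prior or PriorSO3.uniform()
    log_prior = _log_prior_terms(grid, prior)
    est = init
    trace: list[float] = []
    rel = np.inf
    for t in range(1, max_iter + 1):
        cache = TemplateCache(est, grid, obs.model)
        log_w, log_py = _log_weights_all(obs, cache, log_prior)
        trace.append(float(np.sum(log_py)))
        if hard:
            Y = obs.data.reshape(len(obs), -1)
            resid = cache.residual_sq_batch(Y)
            idx = np.argmin(resid, axis=1)
            W = np.zeros_like(resid)
            W[np.arange(len(obs)), idx] = 1.0
        else:
            W = np.exp(log_w)
            W /= W.sum(axis=1, keepdims=True)
        new_arr = _soft_m_step(obs, W, grid, est)
        if not np.all(np.isfinite(new_arr)):
            return EMState(est, t, rel, False, trace, diverged=True)
        prev = est.grid
        denom = float(np.linalg.norm(prev))
        rel = float(np.linalg.norm(new_arr - prev)) / denom if denom > 0 else np.inf
        est = _wrap(new_arr, init)
        if rel < tol:
            return EMState(est, t, rel, True, trace)
    return EMState(est, max_iter, rel, True, trace)


def em_reconstruct(
    obs: ObservationSet,
    init,
    grid: RotationGrid,
    prior: PriorSO3 | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> EMState:
    """Soft-assignment (EM) reconstruction via the MMSE back-rotation operator."""
    return _run(obs, init, grid, prior or PriorSO3.uniform(), tol, max_iter, hard=False)


def hard_assign_reconstruct(
    obs: ObservationSet,
    init,
    grid: RotationGrid,
    prior: PriorSO3 | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> EMState:
    """Hard-assignment reconstruction: each observation is back-rotated by the
    exact inverse of its MLE node before averaging."""
    return _run(obs, init, grid, prior or PriorSO3.uniform(), tol, max_iter, hard=True)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def pearson_cc(a, b) -> float:
    """Centered, normalized correlation of the flattened structures."""
    x = (a.grid if hasattr(a, "grid") else np.asarray(a, dtype=float)).ravel()
    y = (b.grid if hasattr(b, "grid") else np.asarray(b, dtype=float)).ravel()
    if x.shape != y.shape:
        raise ValueError("shapes do not match")
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance input")
    return float(np.dot(x, y) / (nx * ny))


def align_global(recon, target, grid: RotationGrid):
    """Best global rotation of ``recon`` toward ``target`` over the grid.

    Reconstruction from model ``y_i = g_i o V + eps`` is identifiable only
    up to a global rotation; scores are therefore computed after searching
    the grid for the node maximizing the Pearson correlation.  Returns the
    aligned structure.
    """
    from .forward_model import polar_rotate, rotate_volume

    if isinstance(recon, PolarImage2D):
        best, best_cc = recon, -np.inf
        for k in range(recon.l_theta):
            cand = polar_rotate(recon, k)
            cc = pearson_cc(cand, target)
            if cc > best_cc:
                best, best_cc = cand, cc
        return best
    best, best_cc = recon, -np.inf
    for g in grid.nodes:
        cand = rotate_volume(recon, g)
        cc = pearson_cc(cand, target)
        if cc > best_cc:
            best, best_cc = cand, cc
    return best


def template_bias_score(recon, template, truth, grid: RotationGrid) -> tuple[float, float]:
    """(correlation with initial template, correlation with truth), each after
    global-rotation alignment.  Template bias — the 'Einstein from Noise'
    effect — is flagged when the first exceeds the second."""
    cc_template = pearson_cc(align_global(recon, template, grid), template)
    cc_truth = pearson_cc(align_global(recon, truth, grid), truth)
    return cc_template, cc_truth
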