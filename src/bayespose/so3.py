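"""Rotations, metrics, Procrustes projection, SO(3) quadrature and priors.

Rotations are plain 3x3 numpy arrays (special orthogonal: ``R @ R.T = I``,
``det R = +1``).  Everything that consumes a rotation validates it with
:func:`check_rotation`; everything that produces one guarantees the
invariants to ~1e-10.

Two metrics are provided.  The chordal distance

    d_F(g1, g2) = ||g1 - g2||_F

is the Frobenius distance of the matrix embedding; its squared loss is the
one the posterior-mean (MMSE) estimator minimises.  The geodesic distance

    d_G(g1, g2) = arccos((tr(g1^T g2) - 1) / 2)

is the rotation angle of g1^T g2, the intrinsic metric on SO(3).  They are
related exactly by d_F = 2*sqrt(2)*sin(d_G / 2), hence locally equivalent
with ratio sqrt(2) for small angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _R

__all__ = [
    "check_rotation",
    "chordal_distance",
    "geodesic_distance",
    "procrustes_project",
    "DegenerateProjectionError",
    "RotationGrid",
    "build_so3_quadrature",
    "build_cyclic_grid",
    "sample_uniform_rotations",
    "PriorSO3",
    "igso3_angle_density",
    "igso3_sample",
    "haar_angle_density",
    "quaternion_from_matrix",
    "matrix_from_quaternion",
    "euler_zyz_deg_from_matrix",
]

_ORTHO_TOL = 1e-8


class InvalidRotationError(ValueError):
    """Input matrix is not special orthogonal within tolerance."""


class DegenerateProjectionError(np.linalg.LinAlgError):
    """Procrustes minimiser is not unique (>= 2 vanishing singular values)."""


def check_rotation(g: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    """Validate that ``g`` is a 3x3 rotation matrix; return it as float64."""
    g = np.asarray(g, dtype=float)
    if g.shape != (3, 3):
        raise InvalidRotationError(f"expected 3x3 matrix, got shape {g.shape}")
    if not np.all(np.isfinite(g)):
        raise InvalidRotationError("rotation matrix contains non-finite entries")
    if not np.allclose(g @ g.T, np.eye(3), atol=tol):
        raise InvalidRotationError("matrix is not orthogonal within tolerance")
    if not np.isclose(np.linalg.det(g), 1.0, atol=tol):
        raise InvalidRotationError("matrix determinant is not +1 (improper rotation)")
    return g


def chordal_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Frobenius-norm distance between two rotation matrices.

    Ranges over [0, 2*sqrt(2)]; attains the maximum for rotations that
    differ by a half-turn.
    """
    g1 = check_rotation(g1)
    g2 = check_rotation(g2)
    return float(np.linalg.norm(g1 - g2, ord="fro"))


def geodesic_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Rotation angle of ``g1.T @ g2`` in radians, in [0, pi]."""
    g1 = check_rotation(g1)
    g2 = check_rotation(g2)
    c = (np.trace(g1.T @ g2) - 1.0) / 2.0
    if c > 1.0 + 1e-8 or c < -1.0 - 1e-8:
        raise FloatingPointError(f"trace argument {c} outside [-1, 1] beyond tolerance")
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def geodesic_distance_many(G1: np.ndarray, G2: np.ndarray) -> np.ndarray:
    """Vectorised geodesic distance for stacks of rotation matrices.

    ``G1`` and ``G2`` broadcast over leading axes; no validation is
    performed (callers hold pre-validated stacks).
    """
    tr = np.einsum("...ij,...ij->...", G1, G2)
    return np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))


def procrustes_project(A: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    """Closest rotation to an arbitrary 3x3 matrix in Frobenius norm.

    Solves the orthogonal Procrustes problem via the SVD ``A = U S V^T``:
    the minimiser is ``U V^T``, with the sign of the last column of ``U``
    flipped when ``det(U V^T) = -1`` so the result is a proper rotation.

    When two or more singular values vanish the minimiser is a continuum;
    a :class:`DegenerateProjectionError` is raised unless an explicit
    ``fallback`` rotation is supplied.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3) or not np.all(np.isfinite(A)):
        raise ValueError("expected a finite 3x3 matrix")
    U, s, Vt = np.linalg.svd(A)
    if np.sum(s < 1e-12) >= 2:
        if fallback is not None:
            return check_rotation(fallback)
        raise DegenerateProjectionError(
            "projection is not unique: >= 2 singular values vanish"
        )
    if np.linalg.det(U @ Vt) < 0:
        U = U.copy()
        U[:, -1] *= -1.0
    return U @ Vt


def procrustes_project_many(A: np.ndarray) -> np.ndarray:
    """Batched Procrustes projection of an (..., 3, 3) stack (no degeneracy check)."""
    U, _, Vt = np.linalg.svd(A)
    d = np.linalg.det(U @ Vt)
    U = U.copy()
    U[d < 0, :, -1] *= -1.0
    return U @ Vt


# ---------------------------------------------------------------------------
# rotation grids / quadrature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RotationGrid:
    """Quadrature nodes with weights over SO(3) (or a cyclic in-plane group).

    ``nodes`` is an (L, 3, 3) stack of rotation matrices, ``weights`` a
    length-L non-negative vector summing to 1.  ``flavor`` records how the
    grid was built: a deterministic product quadrature, an i.i.d. sample
    (Monte-Carlo rule), or the cyclic group used by the 2D polar pipeline.
    """

    nodes: np.ndarray
    weights: np.ndarray
    flavor: str = "product-quadrature"

    def __post_init__(self) -> None:
        nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=float))
        weights = np.ascontiguousarray(np.asarray(self.weights, dtype=float))
        if nodes.ndim != 3 or nodes.shape[1:] != (3, 3) or len(nodes) < 1:
            raise ValueError("nodes must be a non-empty (L, 3, 3) stack")
        if weights.shape != (len(nodes),):
            raise ValueError("weights must align with nodes")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")
        if self.flavor not in ("product-quadrature", "iid-sample", "in-plane-cyclic"):
            raise ValueError(f"unknown grid flavor {self.flavor!r}")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return len(self.nodes)

    def covering_radius(self, n_probe: int = 2000, seed: int = 0) -> float:
        """Monte-Carlo estimate of the covering radius (max distance of a
        Haar-random rotation to its nearest node), a bound on the
        discretization error of grid-search estimators."""
        probes = sample_uniform_rotations(n_probe, seed=seed)
        # nearest node by maximal trace of probe^T node
        tr = np.einsum("pij,lij->pl", probes, self.nodes)
        best = tr.max(axis=1)
        return float(np.arccos(np.clip((best - 1.0) / 2.0, -1.0, 1.0)).max())


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform directions on S^2 (Fibonacci lattice)."""
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _rotation_to_direction(d: np.ndarray) -> np.ndarray:
    """A rotation mapping e_z to unit vector d (any smooth-enough choice works:
    the product rule sweeps the in-plane angle, so the gauge cancels)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if c < -1.0 + 1e-12:  # antipodal: half-turn about x
        return np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_so3_quadrature(L: int) -> RotationGrid:
    """Product quadrature on SO(3) with about L nodes.

    ~L^(2/3) near-uniform viewing directions (Fibonacci sphere, equal
    weights) times ~L^(1/3) equispaced in-plane angles (exact circular
    rule).  The actual node count is the product of the two rounded
    factors and may differ from the request by rounding.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if L == 1:
        return RotationGrid(np.eye(3)[None], np.array([1.0]))
    n_dir = int(np.ceil(L ** (2.0 / 3.0)))
    n_inplane = int(np.ceil(L ** (1.0 / 3.0)))
    dirs = _fibonacci_sphere(n_dir)
    alphas = 2.0 * np.pi * np.arange(n_inplane) / n_inplane
    ca, sa = np.cos(alphas), np.sin(alphas)
    Rz = np.zeros((n_inplane, 3, 3))
    Rz[:, 0, 0] = ca
    Rz[:, 0, 1] = -sa
    Rz[:, 1, 0] = sa
    Rz[:, 1, 1] = ca
    Rz[:, 2, 2] = 1.0
    Rdir = np.stack([_rotation_to_direction(d) for d in dirs])
    nodes = np.einsum("dij,ajk->daik", Rdir, Rz).reshape(-1, 3, 3)
    w = np.full(len(nodes), 1.0 / len(nodes))
    return RotationGrid(nodes, w, flavor="product-quadrature")


def build_cyclic_grid(L_theta: int) -> RotationGrid:
    """The cyclic group of L_theta in-plane rotations (2D polar pipeline).

    Nodes are embedded as rotations about z so the same container serves
    both pipelines; in the polar pipeline node ``k`` means a cyclic shift
    by ``k`` angular samples.
    """
    if L_theta < 1:
        raise ValueError("L_theta must be >= 1")
    a = 2.0 * np.pi * np.arange(L_theta) / L_theta
    nodes = np.zeros((L_theta, 3, 3))
    nodes[:, 0, 0] = np.cos(a)
    nodes[:, 0, 1] = -np.sin(a)
    nodes[:, 1, 0] = np.sin(a)
    nodes[:, 1, 1] = np.cos(a)
    nodes[:, 2, 2] = 1.0
    return RotationGrid(nodes, np.full(L_theta, 1.0 / L_theta), flavor="in-plane-cyclic")


def grid_from_samples(rotations: np.ndarray) -> RotationGrid:
    """Equal-weight Monte-Carlo grid from i.i.d. rotation samples."""
    rotations = np.asarray(rotations, dtype=float)
    return RotationGrid(
        rotations, np.full(len(rotations), 1.0 / len(rotations)), flavor="iid-sample"
    )


def sample_uniform_rotations(n: int, seed: int) -> np.ndarray:
    """n i.i.d. Haar (uniform) rotations as an (n, 3, 3) stack."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _R.random(n, random_state=rng).as_matrix().reshape(n, 3, 3)


# ---------------------------------------------------------------------------
# priors on SO(3)
# ---------------------------------------------------------------------------


def haar_angle_density(omega: np.ndarray) -> np.ndarray:
    """Marginal density of the rotation angle under the Haar measure,
    (1 - cos w) / pi on [0, pi]."""
    return (1.0 - np.cos(omega)) / np.pi


_OMEGA_GRID_SIZE = 4096


def _igso3_series(omega: np.ndarray, eta: float, l_max: int) -> np.ndarray:
    """Truncated heat-kernel series for the IGSO(3) angle density (unnormalised)."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    ls = np.arange(l_max + 1)
    coef = (2 * ls + 1) * np.exp(-ls * (ls + 1) * eta**2 / 2.0)
    half = omega / 2.0
    # sin((l + 1/2) w) / sin(w/2) -> Dirichlet-type kernel; limit 2l+1 at w=0
    with np.errstate(invalid="ignore", divide="ignore"):
        kern = np.sin(np.outer(omega, ls + 0.5)) / np.sin(half)[:, None]
    small = np.abs(half) < 1e-8
    if np.any(small):
        kern[small] = 2 * ls + 1
    series = kern @ coef
    return haar_angle_density(omega) * np.maximum(series, 0.0)


def _igso3_lmax(eta: float) -> int:
    return max(10, int(np.ceil(5.0 / eta)))


def _igso3_table(eta: float) -> tuple[np.ndarray, np.ndarray]:
    """(omega grid, normalised angle density) for IGSO3(eta^2)."""
    w = np.linspace(0.0, np.pi, _OMEGA_GRID_SIZE)
    f = _igso3_series(w, eta, _igso3_lmax(eta))
    f /= np.trapezoid(f, w)
    return w, f


def igso3_angle_density(omega, eta: float):
    """Marginal density of the rotation angle under IGSO(3)(eta^2).

    The isotropic Gaussian on SO(3) is the heat-kernel distribution with
    scalar variance eta^2: uniform (Haar) as eta -> inf, concentrated at
    the identity as eta -> 0.  Evaluated from a truncated character series
    re-normalised numerically on a 4096-point angle grid.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    w_grid, f_grid = _igso3_table(eta)
    omega_arr = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any((omega_arr < -1e-12) | (omega_arr > np.pi + 1e-12)):
        raise ValueError("omega must lie in [0, pi]")
    out = np.interp(np.clip(omega_arr, 0.0, np.pi), w_grid, f_grid)
    return float(out[0]) if np.isscalar(omega) or np.ndim(omega) == 0 else out


def igso3_sample(n: int, eta: float, seed: int) -> np.ndarray:
    """n i.i.d. IGSO(3)(eta^2) rotations via inverse-transform sampling.

    Axes uniform on the sphere; angles drawn by inverting the tabulated
    CDF of the angle marginal.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if eta <= 0:
        raise ValueError("eta must be positive")
    rng = np.random.default_rng(seed)
    w_grid, f_grid = _igso3_table(eta)
    cdf = np.concatenate([[0.0], np.cumsum((f_grid[1:] + f_grid[:-1]) / 2.0 * np.diff(w_grid))])
    cdf /= cdf[-1]
    u = rng.random(n)
    angles = np.interp(u, cdf, w_grid)
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return _R.from_rotvec(axes * angles[:, None]).as_matrix().reshape(n, 3, 3)


@dataclass(frozen=True)
class PriorSO3:
    """Prior over SO(3): Haar-uniform or isotropic Gaussian IGSO(3)(eta^2)."""

    kind: str = "uniform"
    eta: float | None = None
    _table: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "igso3"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "igso3":
            if self.eta is None or self.eta <= 0:
                raise ValueError("igso3 prior requires eta > 0")
            object.__setattr__(self, "_table", _igso3_table(self.eta))

    @classmethod
    def uniform(cls) -> "PriorSO3":
        return cls("uniform")

    @classmethod
    def igso3(cls, eta: float) -> "PriorSO3":
        return cls("igso3", eta=eta)

    def angle_density(self, omega) -> np.ndarray:
        """Density of the rotation angle on [0, pi]."""
        if self.kind == "uniform":
            return haar_angle_density(np.asarray(omega, dtype=float))
        return igso3_angle_density(omega, self.eta)

    def density(self, rotations: np.ndarray) -> np.ndarray:
        """Prior density w.r.t. the Haar measure, evaluated at an (L,3,3) stack.

        For the uniform prior this is identically 1; for IGSO(3) it is the
        ratio of the angle marginal to the Haar angle marginal, which only
        depends on the rotation angle (the distribution is isotropic).
        """
        G = np.asarray(rotations, dtype=float)
        single = G.ndim == 2
        G = G.reshape(-1, 3, 3)
        if self.kind == "uniform":
            out = np.ones(len(G))
        else:
            tr = np.einsum("lii->l", G)
            omega = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))
            # guard the removable singularity of the Haar marginal at omega=0
            w_safe = np.maximum(omega, 1e-4)
            out = self.angle_density(w_safe) / haar_angle_density(w_safe)
        return float(out[0]) if single else out

    def sample(self, n: int, seed: int) -> np.ndarray:
        if self.kind == "uniform":
            return sample_uniform_rotations(n, seed)
        return igso3_sample(n, self.eta, seed)


# ---------------------------------------------------------------------------
# parameterizations for I/O
# ---------------------------------------------------------------------------


def quaternion_from_matrix(g: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) with w >= 0 (canonical double-cover rep)."""
    q = _R.from_matrix(check_rotation(g)).as_quat()  # scipy order: x, y, z, w
    q = np.array([q[3], q[0], q[1], q[2]])
    if q[0] < 0:
        q = -q
    return q


def matrix_from_quaternion(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("quaternion must have unit norm")
    return _R.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def euler_zyz_deg_from_matrix(g: np.ndarray) -> np.ndarray:
    """Intrinsic ZYZ Euler angles in degrees (rot, tilt, psi convention)."""
    return _R.from_matrix(check_rotation(g)).as_euler("ZYZ", degrees=True)
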