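"""Ellipsoid-specific least-squares fitting of 3-D wall points and volumetry.

The bladder is modelled as an ellipsoid. Wall points are fitted with the
general quadric

    f(a; x) = a x^2 + b y^2 + c z^2 + 2d xy + 2g yz + 2h xz
              + 2p x + 2q y + 2r z + I = 0

minimizing the algebraic residual sum Sum_i f(a; x_i)^2 subject to an
ellipsoid-specific quadratic constraint of the Li type: with
I1 = a + b + c and J = ab + bc + ca - d^2 - g^2 - h^2, the constraint
k*J - I1^2 = 1 with k = 4 guarantees the solution is an ellipsoid for
any data. The constrained problem reduces, after eliminating the
linear/constant coefficients block, to a 6x6 generalized eigenproblem
whose admissible solution is the eigenvector on which the constraint
form is positive.

Coordinates are millimeters in a right-handed probe-local frame (z along
the mean beam direction); volumes are reported both in mm^3 and mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    NonEllipsoidError,
    RankDeficiencyError,
)

__all__ = [
    "QuadricCoefficients",
    "EllipsoidGeometry",
    "FitDiagnostics",
    "fit_quadric",
    "quadric_to_geometry",
    "estimate_volume",
    "sample_surface",
]

#: k = 4 makes the Li constraint ellipsoid-guaranteeing for all data.
LI_CONSTRAINT_K = 4.0
MIN_POINTS = 9
_COND_LIMIT = 1e12


@dataclass
class QuadricCoefficients:
    """10-vector (a, b, c, d, g, h, p, q, r, i) of the quadric surface."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (10,):
            raise InvalidArgumentError("quadric needs exactly 10 coefficients")
        if not np.any(self.vector[:6]):
            raise InvalidArgumentError("quadratic part must not vanish")

    @property
    def quadratic_matrix(self) -> np.ndarray:
        a, b, c, d, g, h = self.vector[:6]
        return np.array([[a, d, h], [d, b, g], [h, g, c]])

    @property
    def linear_vector(self) -> np.ndarray:
        return self.vector[6:9]

    @property
    def constant(self) -> float:
        return float(self.vector[9])

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Algebraic value f(a; x) at each point (n, 3)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return np.einsum("ni,ij,nj->n", pts, self.quadratic_matrix, pts) \
            + 2.0 * pts @ self.linear_vector + self.constant


@dataclass
class EllipsoidGeometry:
    """Center, semi-axes (descending), orientation and volume."""

    center: np.ndarray             # (3,) mm
    semi_axes: np.ndarray          # (3,) mm, A >= B >= C > 0
    rotation: np.ndarray           # (3,3) orthonormal, columns = axis directions

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.all(self.semi_axes > 0):
            raise InvalidArgumentError("semi-axes must be positive")
        if np.any(np.diff(self.semi_axes) > 1e-12):
            raise InvalidArgumentError("semi-axes must be sorted descending")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-10):
            raise InvalidArgumentError("rotation must be orthonormal")

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * float(np.prod(self.semi_axes))

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def to_quadric(self) -> QuadricCoefficients:
        """Implicit quadric with positive-definite quadratic part."""
        A = self.rotation @ np.diag(1.0 / self.semi_axes**2) @ self.rotation.T
        b = -A @ self.center
        i = float(self.center @ A @ self.center) - 1.0
        return QuadricCoefficients(np.array(
            [A[0, 0], A[1, 1], A[2, 2], A[0, 1], A[1, 2], A[0, 2],
             b[0], b[1], b[2], i]
        ))


@dataclass
class FitDiagnostics:
    n_points: int
    residual_sum_squares: float
    rms_algebraic_residual: float


def _design_matrix(points: np.ndarray) -> np.ndarray:
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    one = np.ones_like(x)
    return np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * y * z, 2 * x * z,
         2 * x, 2 * y, 2 * z, one]
    )


def _constraint_matrix(k: float) -> np.ndarray:
    C = np.zeros((6, 6))
    C[:3, :3] = k / 2.0 - 1.0
    np.fill_diagonal(C[:3, :3], -1.0)
    C[3, 3] = C[4, 4] = C[5, 5] = -k
    return C


def fit_quadric(points: np.ndarray, k: float = LI_CONSTRAINT_K) -> QuadricCoefficients:
    """Ellipsoid-specific algebraic least-squares quadric fit.

    Solves min ||D a||^2 subject to the Li-type constraint
    a1' C a1 = 1 on the quadratic block a1, via block elimination of the
    linear/constant block and a 6x6 generalized eigenproblem.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < MIN_POINTS:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} points, got {pts.shape[0]}"
        )
    # center/scale for conditioning; the constraint is invariant under
    # similarity only up to scaling of the residual, so fit in normalized
    # coordinates and map the quadric back afterwards.
    mu = pts.mean(axis=0)
    scale = float(np.abs(pts - mu).mean())
    if scale == 0.0:
        raise RankDeficiencyError("all points coincide")
    q_norm = _fit_quadric_raw((pts - mu) / scale, k)
    return _denormalize(q_norm, mu, scale)


def _fit_quadric_raw(pts: np.ndarray, k: float) -> QuadricCoefficients:
    D = _design_matrix(pts)
    S = D.T @ D
    S11, S12, S22 = S[:6, :6], S[:6, 6:], S[6:, 6:]
    if np.linalg.cond(S22) > _COND_LIMIT:
        raise RankDeficiencyError(
            "degenerate point configuration (coplanar or coincident points)"
        )
    T = linalg.solve(S22, S12.T, assume_a="sym")
    M = S11 - S12 @ T
    C = _constraint_matrix(k)
    try:
        eigvals, eigvecs = linalg.eig(M, C)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RankDeficiencyError(str(exc)) from exc
    # The admissible solution is the eigenvector on which the constraint
    # form is positive (it can be normalized to a1' C a1 = 1); among such
    # candidates take the one with the smallest residual a1' M a1. For
    # exact data the matching eigenvalue is ~0, so selecting by the sign
    # of the eigenvalue alone is numerically unreliable.
    best = None
    for i in range(eigvals.size):
        if not np.isfinite(eigvals[i]) or abs(np.imag(eigvals[i])) > 1e-6:
            continue
        v = np.real(eigvecs[:, i])
        c_val = float(v @ C @ v)
        if c_val <= 1e-12 * float(v @ v):
            continue
        v = v / math.sqrt(c_val)
        residual = float(v @ M @ v)
        if best is None or residual < best[0]:
            best = (residual, v)
    if best is None:
        raise NonEllipsoidError("no admissible eigenvector: data do not "
                                "support an ellipsoid")
    a1 = best[1]
    a2 = -T @ a1
    vec = np.concatenate([a1, a2])
    if vec[:3].sum() < 0:  # sign convention: positive-definite quadratic part
        vec = -vec
    return QuadricCoefficients(vec)


def _denormalize(q: QuadricCoefficients, mu: np.ndarray, s: float) -> QuadricCoefficients:
    """Map a quadric fitted on (x-mu)/s back to original coordinates."""
    A = q.quadratic_matrix / s**2
    b = q.linear_vector / s - A @ mu
    i = q.constant - 2.0 * (q.linear_vector / s) @ mu + float(mu @ (q.quadratic_matrix / s**2) @ mu)
    return QuadricCoefficients(np.array(
        [A[0, 0], A[1, 1], A[2, 2], A[0, 1], A[1, 2], A[0, 2],
         b[0], b[1], b[2], i]
    ))


def quadric_to_geometry(q: QuadricCoefficients) -> EllipsoidGeometry:
    """Extract center, semi-axes and orientation from an ellipsoid quadric."""
    A = q.quadratic_matrix
    if np.trace(A) < 0:
        A = -A
        q = QuadricCoefficients(-q.vector)
    w = np.linalg.eigvalsh(A)
    if np.any(w <= 0):
        raise NonEllipsoidError("quadratic part is not positive definite")
    b = q.linear_vector
    center = -linalg.solve(A, b, assume_a="sym")
    i_centered = float(b @ center) + q.constant
    if not (i_centered < 0):
        raise NonEllipsoidError("degenerate or imaginary ellipsoid (no real surface)")
    w, V = np.linalg.eigh(A / (-i_centered))
    semi = 1.0 / np.sqrt(w)          # eigh ascending -> semi descending already
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    V = V[:, order]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]           # keep the frame right-handed
    return EllipsoidGeometry(center=center, semi_axes=semi, rotation=V)


def estimate_volume(points: np.ndarray) -> tuple[EllipsoidGeometry, FitDiagnostics]:
    """Fit an ellipsoid to wall points and report its volume + diagnostics."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    q = fit_quadric(pts)
    geom = quadric_to_geometry(q)
    res = q.evaluate(pts)
    rss = float(np.sum(res**2))
    diag = FitDiagnostics(
        n_points=pts.shape[0],
        residual_sum_squares=rss,
        rms_algebraic_residual=math.sqrt(rss / pts.shape[0]),
    )
    return geom, diag


def sample_surface(geometry: EllipsoidGeometry, n: int, seed: int | None = None) -> np.ndarray:
    """Quasi-uniform points on the ellipsoid surface (for tests/oracles)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return geometry.center + (u * geometry.semi_axes) @ geometry.rotation.T
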