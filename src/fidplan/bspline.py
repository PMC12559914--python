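"""Tensor-product B-spline surfaces: definition, least-squares fit, sampling.

The candidate-implantation surface is the clamped tensor-product spline

    S(u, v) = sum_i sum_j N_{i,p}(u) N_{j,q}(v) P_{i,j},   (u, v) in [0,1]^2,

whose control points P_{i,j} are obtained by minimising the sum of
squared Euclidean distances between the surface and a parameterized
point cloud,

    E = sum_k || P_k - S(u_k, v_k) ||^2 .

Scattered clouds are parameterized cylindrically about a chosen axis
(azimuth -> u, normalised axial coordinate -> v); the fitted surface is
then sampled on a uniform (u, v) grid to produce candidate marker
positions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import PointCloud3D, ValidationError

__all__ = [
    "BSplineSurface",
    "FitResult",
    "CandidateSet",
    "basis",
    "evaluate_surface",
    "parameterize_cloud",
    "principal_axis",
    "fit_surface",
    "sample_surface",
    "clamped_uniform_knots",
    "FittingError",
    "DomainError",
]

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    """The least-squares surface fit is underdetermined or rank deficient."""


class DomainError(ValueError):
    """A parameter lies outside the spline's knot domain."""


def clamped_uniform_knots(n_ctrl: int, degree: int) -> np.ndarray:
    """Clamped knot vector on [0, 1] with uniform interior knots.

    Length is ``n_ctrl + degree + 1``; the first and last ``degree + 1``
    knots repeat so the surface interpolates its corner control points.
    """
    if n_ctrl < degree + 1:
        raise ValidationError(
            f"need at least degree+1={degree + 1} control points, got {n_ctrl}")
    interior = np.linspace(0.0, 1.0, n_ctrl - degree + 1)[1:-1]
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def basis(i: int, p: int, u: float, knots: np.ndarray) -> float:
    """Cox-de Boor B-spline basis function N_{i,p}(u).

    Uses the 0/0 -> 0 convention; the right end of the domain is treated
    as closed so that the basis sums to one at u = knots[-p-1].
    """
    knots = np.asarray(knots, dtype=float)
    if not 0 <= i <= len(knots) - p - 2:
        raise IndexError(f"basis index {i} out of range for {len(knots)} knots, degree {p}")
    lo, hi = knots[p], knots[-p - 1]
    if not (lo <= u <= hi):
        raise DomainError(f"parameter {u} outside spline domain [{lo}, {hi}]")
    return _cox_de_boor(i, p, u, knots, hi)


def _cox_de_boor(i: int, p: int, u: float, knots: np.ndarray, umax: float) -> float:
    if p == 0:
        if knots[i] <= u < knots[i + 1]:
            return 1.0
        # closed right end: last non-degenerate span owns u == umax
        if u == umax and knots[i] < knots[i + 1] and knots[i + 1] >= umax:
            return 1.0
        return 0.0
    left = 0.0
    denom = knots[i + p] - knots[i]
    if denom > 0:
        left = (u - knots[i]) / denom * _cox_de_boor(i, p - 1, u, knots, umax)
    right = 0.0
    denom = knots[i + p + 1] - knots[i + 1]
    if denom > 0:
        right = (knots[i + p + 1] - u) / denom * _cox_de_boor(i + 1, p - 1, u, knots, umax)
    return left + right


def _basis_row(p: int, u: float, knots: np.ndarray) -> np.ndarray:
    """All basis values N_{i,p}(u), i = 0..n_ctrl-1, as one row."""
    n_ctrl = len(knots) - p - 1
    return np.array([basis(i, p, u, knots) for i in range(n_ctrl)])


@dataclass
class BSplineSurface:
    """A clamped tensor-product B-spline surface S(u, v).

    ``control_points`` has shape (m+1, n+1, 3); ``knots_u``/``knots_v``
    are nondecreasing clamped vectors of lengths (m+1)+p+1 and
    (n+1)+q+1 for degrees p = ``degree_u``, q = ``degree_v``.
    """

    control_points: np.ndarray
    knots_u: np.ndarray
    knots_v: np.ndarray
    degree_u: int = 3
    degree_v: int = 3

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.knots_u = np.asarray(self.knots_u, dtype=float)
        self.knots_v = np.asarray(self.knots_v, dtype=float)
        cp = self.control_points
        if cp.ndim != 3 or cp.shape[2] != 3:
            raise ValidationError(f"control grid must be (m+1, n+1, 3), got {cp.shape}")
        p, q = self.degree_u, self.degree_v
        if cp.shape[0] < p + 1 or cp.shape[1] < q + 1:
            raise ValidationError("control grid smaller than degree allows (m >= p, n >= q)")
        for knots, n_ctrl, deg, name in ((self.knots_u, cp.shape[0], p, "u"),
                                         (self.knots_v, cp.shape[1], q, "v")):
            if len(knots) != n_ctrl + deg + 1:
                raise ValidationError(
                    f"knots_{name} must have length {n_ctrl + deg + 1}, got {len(knots)}")
            if np.any(np.diff(knots) < 0):
                raise ValidationError(f"knots_{name} must be nondecreasing")
            if not (np.all(knots[:deg + 1] == knots[0])
                    and np.all(knots[-deg - 1:] == knots[-1])):
                raise ValidationError(f"knots_{name} must be clamped")

    @property
    def n_ctrl(self) -> tuple[int, int]:
        return self.control_points.shape[0], self.control_points.shape[1]

    def evaluate(self, u: float, v: float) -> np.ndarray:
        return evaluate_surface(self, u, v)

    # --- JSON serialization for plan reproducibility ------------------
    def to_json(self, path: str | os.PathLike | None = None) -> str:
        doc = {
            "control_points": self.control_points.tolist(),
            "knots_u": self.knots_u.tolist(),
            "knots_v": self.knots_v.tolist(),
            "degree_u": self.degree_u,
            "degree_v": self.degree_v,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "BSplineSurface":
        if isinstance(source, (str,)) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(np.asarray(doc["control_points"]),
                   np.asarray(doc["knots_u"]), np.asarray(doc["knots_v"]),
                   degree_u=int(doc["degree_u"]), degree_v=int(doc["degree_v"]))


def evaluate_surface(surface: BSplineSurface, u: float, v: float) -> np.ndarray:
    """Evaluate S(u, v) as the tensor-product basis sum."""
    bu = _basis_row(surface.degree_u, float(u), surface.knots_u)
    bv = _basis_row(surface.degree_v, float(v), surface.knots_v)
    return np.einsum("i,j,ijk->k", bu, bv, surface.control_points)


@dataclass
class FitResult:
    """Outcome of the least-squares surface fit.

    ``residual_E`` is the sum of squared point-to-surface-sample
    distances (mm^2), excluding any smoothing penalty.
    """

    surface: BSplineSurface
    residual_E: float
    per_point_residuals: np.ndarray


@dataclass
class CandidateSet:
    """Sampled surface points that are candidate marker positions.

    Distance annotations (to the tumor centroid and to the tumor
    surface) are filled by the proximity filter; until then they are
    NaN.
    """

    points: np.ndarray
    params: np.ndarray
    tumor_centroid_distance: np.ndarray = field(default=None)  # type: ignore[assignment]
    tumor_surface_distance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.params = np.asarray(self.params, dtype=float).reshape(-1, 2)
        n = len(self.points)
        if len(self.params) != n:
            raise ValidationError("points and params must have equal length")
        for attr in ("tumor_centroid_distance", "tumor_surface_distance"):
            val = getattr(self, attr)
            val = np.full(n, np.nan) if val is None else np.asarray(val, dtype=float)
            if len(val) != n:
                raise ValidationError(f"{attr} must have length {n}")
            setattr(self, attr, val)

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, index: np.ndarray) -> "CandidateSet":
        """Candidate subset, preserving order and annotations."""
        return CandidateSet(self.points[index], self.params[index],
                            self.tumor_centroid_distance[index],
                            self.tumor_surface_distance[index])


def principal_axis(cloud: PointCloud3D) -> np.ndarray:
    """Longest principal component of the cloud (unit vector).

    Sign is fixed so the largest-magnitude component is positive, making
    the downstream parameterization deterministic.
    """
    pts = cloud.points - cloud.points.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    axis = vt[0]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis


def parameterize_cloud(cloud: PointCloud3D, centroid: np.ndarray,
                       axis: np.ndarray) -> np.ndarray:
    """Cylindrical (u, v) parameters for a scattered cloud.

    u = azimuth / 2*pi about ``axis`` through ``centroid`` (u in [0, 1)),
    v = axial coordinate normalised to [0, 1] over the cloud's extent.
    A point lying exactly on the axis gets u = 0 with a logged warning.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = cloud.points - np.asarray(centroid, dtype=float)
    t = rel @ axis
    radial = rel - t[:, None] * axis
    # deterministic in-plane frame: reference axis least aligned with `axis`
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(axis)))] = 1.0
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    x, y = radial @ e1, radial @ e2
    on_axis = np.hypot(x, y) < 1e-12
    if np.any(on_axis):
        logger.warning("%d point(s) lie exactly on the parameterization axis; "
                       "assigned u = 0", int(on_axis.sum()))
    u = np.where(on_axis, 0.0, np.mod(np.arctan2(y, x), 2 * np.pi) / (2 * np.pi))
    t_min, t_max = t.min(), t.max()
    if t_max - t_min < 1e-12:
        raise ValidationError("cloud is degenerate along the parameterization axis")
    v = (t - t_min) / (t_max - t_min)
    return np.column_stack([u, v])


def _second_difference(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((0, n))
    D = np.zeros((n - 2, n))
    for r in range(n - 2):
        D[r, r:r + 3] = (1.0, -2.0, 1.0)
    return D


def fit_surface(cloud: PointCloud3D, params: np.ndarray,
                degree_u: int = 3, degree_v: int = 3,
                grid: tuple[int, int] = (6, 6),
                smoothing: float = 0.0) -> FitResult:
    """Fit control points by linear least squares.

    Minimises ``sum_k ||P_k - S(u_k, v_k)||^2`` (plus an optional
    Tikhonov penalty ``smoothing`` on second differences of the control
    grid).  ``residual_E`` always reports the pure data term.

    Raises
    ------
    FittingError
        If there are fewer points than control points, or the
        collocation matrix is rank deficient and smoothing is 0.
    """
    pts = cloud.points
    params = np.asarray(params, dtype=float)
    n_cu, n_cv = grid
    n_unknowns = n_cu * n_cv
    K = len(pts)
    if np.any(params < 0) or np.any(params > 1):
        raise DomainError("parameters must lie in [0, 1]^2")
    if K < n_unknowns:
        raise FittingError(
            f"underdetermined fit: {K} points for {n_unknowns} control points; "
            "use a smaller grid or smoothing > 0")
    knots_u = clamped_uniform_knots(n_cu, degree_u)
    knots_v = clamped_uniform_knots(n_cv, degree_v)

    Bu = np.vstack([_basis_row(degree_u, u, knots_u) for u in params[:, 0]])
    Bv = np.vstack([_basis_row(degree_v, v, knots_v) for v in params[:, 1]])
    B = np.einsum("ki,kj->kij", Bu, Bv).reshape(K, n_unknowns)

    if smoothing > 0:
        Du = np.kron(_second_difference(n_cu), np.eye(n_cv))
        Dv = np.kron(np.eye(n_cu), _second_difference(n_cv))
        A = np.vstack([B, np.sqrt(smoothing) * Du, np.sqrt(smoothing) * Dv])
        rhs = np.vstack([pts, np.zeros((Du.shape[0] + Dv.shape[0], 3))])
    else:
        A, rhs = B, pts

    sol, _, rank, _ = scipy.linalg.lstsq(A, rhs)
    if smoothing == 0 and rank < n_unknowns:
        raise FittingError(
            f"rank-deficient fit (rank {rank} < {n_unknowns}); "
            "use a smaller grid or smoothing > 0")

    surface = BSplineSurface(sol.reshape(n_cu, n_cv, 3), knots_u, knots_v,
                             degree_u=degree_u, degree_v=degree_v)
    resid_vec = pts - B @ sol
    per_point = np.linalg.norm(resid_vec, axis=1)
    return FitResult(surface, float(np.sum(per_point**2)), per_point)


def sample_surface(surface: BSplineSurface, n_u: int, n_v: int) -> CandidateSet:
    """Evaluate the surface on a uniform n_u x n_v parameter grid.

    Candidate order follows the (u, v) grid (u-major), which fixes the
    downstream tie-breaking of fiducial sets.
    """
    if n_u < 2 or n_v < 2:
        raise ValidationError("n_u and n_v must both be >= 2")
    us = np.linspace(0.0, 1.0, n_u)
    vs = np.linspace(0.0, 1.0, n_v)
    Bu = np.vstack([_basis_row(surface.degree_u, u, surface.knots_u) for u in us])
    Bv = np.vstack([_basis_row(surface.degree_v, v, surface.knots_v) for v in vs])
    pts = np.einsum("ai,bj,ijk->abk", Bu, Bv, surface.control_points)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    return CandidateSet(pts.reshape(-1, 3),
                        np.column_stack([uu.ravel(), vv.ravel()]))
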