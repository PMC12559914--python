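"""Point clouds, coordinate conventions, and synthetic phantoms.

All geometry lives in the DICOM patient coordinate system (LPS), in
millimetres, with Z along the superior-inferior axis.  The phantom
generator builds ellipsoidal "tumor" surfaces plus an offset candidate
shell that emulates a superficial lesion 20-50 mm below the epidermis,
so the whole planning pipeline is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "PointCloud3D",
    "PhantomSpec",
    "generate_phantom",
    "centroid",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a geometric object violates its invariants."""


@dataclass
class PointCloud3D:
    """A labelled set of 3-D points in mm, patient coordinate system.

    Parameters
    ----------
    points : (N, 3) array_like
        Cartesian coordinates in millimetres.
    label : str
        Role tag: ``"tumor-surface"``, ``"body-surface"`` or ``"candidate"``.
    frame : str
        Coordinate-system tag; defaults to DICOM patient LPS.
    metadata : dict
        Free-form per-cloud annotations (e.g. exact construction offsets
        of phantom shell points).
    """

    points: np.ndarray
    label: str = "candidate"
    frame: str = "patient-LPS"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1 and pts.size == 3:
            pts = pts.reshape(1, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (N, 3), got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise ValidationError("point cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("all coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def translated(self, t: np.ndarray) -> "PointCloud3D":
        """Return a copy rigidly translated by ``t`` (mm)."""
        return PointCloud3D(self.points + np.asarray(t, dtype=float),
                            label=self.label, frame=self.frame,
                            metadata=dict(self.metadata))

    def transformed(self, rotation: np.ndarray, t: np.ndarray | None = None) -> "PointCloud3D":
        """Return a copy under the rigid motion ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        out = self.points @ R.T
        if t is not None:
            out = out + np.asarray(t, dtype=float)
        return PointCloud3D(out, label=self.label, frame=self.frame,
                            metadata=dict(self.metadata))


def centroid(cloud: PointCloud3D | np.ndarray) -> np.ndarray:
    """Arithmetic mean of the cloud's points (mm).

    The tumor centroid is the origin of the projection coordinate system
    and the reference point of the marker-to-tumor distance rule.
    """
    pts = cloud.points if isinstance(cloud, PointCloud3D) else np.asarray(cloud, dtype=float)
    if pts.size == 0:
        raise ValidationError("cannot take the centroid of an empty cloud")
    return pts.mean(axis=0)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic superficial-tumor phantom.

    The tumor is an ellipsoid with the given semi-axes; the candidate
    shell sits at radial offsets drawn uniformly from ``offset_band``
    outside the tumor surface, mimicking implantation sites in the
    tissue band 20-30 mm above a lesion lying 20-50 mm deep.

    Attributes
    ----------
    centroid : (3,) tuple of float, mm
    semi_axes : (3,) tuple of float, mm -- all positive.
    n_points : int
        Number of points per cloud (tumor and shell each); >= 4.
    offset_band : (lo, hi) in mm, 0 <= lo <= hi
        Depth band of the candidate shell above the tumor surface.
    noise_sd : float, mm
        Isotropic Gaussian perturbation of tumor-surface points.
    seed : int
        Seed of the generator; identical spec => bit-identical phantom.
    """

    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: tuple[float, float, float] = (15.0, 15.0, 15.0)
    n_points: int = 500
    offset_band: tuple[float, float] = (20.0, 30.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi_axes must all be positive")
        lo, hi = self.offset_band
        if not (0 <= lo <= hi):
            raise ValidationError("offset_band must satisfy 0 <= lo <= hi")
        if self.n_points < 4:
            raise ValidationError("n_points must be >= 4")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n unit vectors uniform on the sphere (Gaussian normalisation)."""
    d = rng.standard_normal((n, 3))
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    # a zero draw has probability 0; guard anyway
    norms[norms == 0] = 1.0
    return d / norms


def _ellipsoid_point(directions: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """Scale each unit direction to the ellipsoid surface (centred frame)."""
    scale = 1.0 / np.sqrt(np.sum((directions / semi_axes) ** 2, axis=1))
    return directions * scale[:, None]


def generate_phantom(spec: PhantomSpec) -> tuple[PointCloud3D, PointCloud3D, np.ndarray]:
    """Generate a synthetic tumor surface and its offset candidate shell.

    Returns ``(tumor, shell, centroid)``.  Tumor points lie on the
    ellipsoid surface (plus Gaussian noise of sd ``noise_sd``); shell
    points sit along the outward surface normal at offsets drawn
    uniformly from ``offset_band``.  Because the ellipsoid is convex, an
    outward normal offset of ``t`` mm is exactly ``t`` mm from the
    surface.  Exact offsets are recorded in
    ``shell.metadata["surface_offset"]``.

    A fixed spec (seed included) yields a bit-identical phantom.
    """
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.centroid, dtype=float)
    axes = np.asarray(spec.semi_axes, dtype=float)

    tumor_pts = _ellipsoid_point(_uniform_directions(rng, spec.n_points), axes)
    if spec.noise_sd > 0:
        tumor_pts = tumor_pts + rng.normal(scale=spec.noise_sd, size=tumor_pts.shape)

    feet = _ellipsoid_point(_uniform_directions(rng, spec.n_points), axes)
    normals = feet / axes**2
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    lo, hi = spec.offset_band
    offsets = rng.uniform(lo, hi, size=spec.n_points)
    shell_pts = feet + offsets[:, None] * normals

    tumor = PointCloud3D(tumor_pts + c, label="tumor-surface")
    shell = PointCloud3D(shell_pts + c, label="candidate",
                         metadata={"surface_offset": offsets})
    return tumor, shell, c.copy()
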