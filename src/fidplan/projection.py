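"""Oblique-view projection and marker-overlap rejection.

The CyberKnife imaging chain views the patient through two oblique
kV imagers at +45 and -45 degrees about the Z (superior-inferior)
axis.  Marker sets must remain distinguishable in both views: here
each view is an orthographic projection of the markers, taken about
the tumor centroid as origin, and two markers "overlap" when their
projected separation falls below the fiducial extent.

Default convention: the beam of a view runs along the rotated Y axis,
so the projected image coordinates are (rotated-x, z).  A literal
mode instead projects onto the X-Y plane after the rotation; since a
rotation about Z is an isometry of the X-Y plane, that recipe cannot
distinguish the two views -- the property is asserted in the test
suite and the mode is kept for traceability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import ConstraintConfig, FiducialSet

__all__ = ["ProjectedView", "rotate_z", "project_view", "check_overlap", "drr_filter"]


@dataclass
class ProjectedView:
    """2-D marker coordinates in one oblique imaging view (mm)."""

    view_angle: float
    origin: np.ndarray
    coords2d: np.ndarray
    beam_axis_convention: str = "rotated-y-beam"


def rotation_matrix_z(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the Z axis.

    R_z = [[cos a, -sin a, 0], [sin a, cos a, 0], [0, 0, 1]].
    """
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_z(point: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a point (or an (N,3) array) about the Z axis; Z unchanged."""
    p = np.asarray(point, dtype=float)
    return p @ rotation_matrix_z(angle_deg).T


def project_view(markers: np.ndarray, centroid: np.ndarray, view_angle: float,
                 literal: bool = False) -> ProjectedView:
    """Project markers into one oblique view.

    Markers are translated so the tumor centroid is the origin, rotated
    by R_z(view_angle), then flattened: default drops the rotated Y
    (beam) coordinate, returning (x', z) pairs; literal mode drops Z,
    returning (x', y').
    """
    m = np.atleast_2d(np.asarray(markers, dtype=float))
    rel = m - np.asarray(centroid, dtype=float)
    rot = rotate_z(rel, view_angle)
    if literal:
        coords = rot[:, [0, 1]]
        convention = "literal-xy-plane"
    else:
        coords = rot[:, [0, 2]]
        convention = "rotated-y-beam"
    return ProjectedView(view_angle, np.asarray(centroid, dtype=float),
                         coords, convention)


def check_overlap(view: ProjectedView, overlap_extent: float) -> tuple[bool, list[tuple[int, int]]]:
    """Report marker pairs closer than ``overlap_extent`` in this view.

    Overlap is strict (< extent): projections exactly ``overlap_extent``
    apart still count as distinguishable.  Returns
    ``(overlap_free, offending_pairs)``.
    """
    c = view.coords2d
    offending = []
    for i in range(len(c)):
        for j in range(i + 1, len(c)):
            if np.linalg.norm(c[i] - c[j]) < overlap_extent:
                offending.append((i, j))
    return (len(offending) == 0), offending


def drr_filter(sets: list[FiducialSet], centroid: np.ndarray,
               config: ConstraintConfig) -> list[FiducialSet]:
    """Retain sets that are overlap-free in every configured view.

    Per-view flags are cached on each set (``overlap_free``); order is
    preserved.
    """
    out = []
    for s in sets:
        flags = {}
        for angle in config.view_angles:
            view = project_view(s.markers, centroid, angle,
                                literal=config.literal_projection)
            free, _ = check_overlap(view, config.overlap_extent)
            flags[angle] = free
        s.overlap_free = flags
        if all(flags.values()):
            out.append(s)
    return out
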