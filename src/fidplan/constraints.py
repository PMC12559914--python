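"""Geometric constraint filtering and fiducial-triple enumeration.

Candidate implantation points are screened by a Z-band filter and
tumor-proximity rules, then organised as an undirected graph whose
edges join candidates at least ``d_min`` apart.  Valid fiducial sets
are the triangles (generally: k-cliques) of this graph whose interior
angles all reach ``theta_min``.  A brute-force enumerator over all
point triples serves as the independent correctness oracle.

Two enumeration modes exist:

* default -- every ``set_size``-subset of every maximal clique, which
  for triples is exactly the set of triangles of the graph;
* strict-paper -- only maximal cliques of size exactly ``set_size``
  (the literal published pseudocode), obtained via Bron-Kerbosch.
  "Far" graphs are dense, so full maximal-clique enumeration can be
  exponential; strict mode is intended for small candidate sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .bspline import CandidateSet
from .geometry import PointCloud3D, ValidationError

__all__ = [
    "ConstraintConfig",
    "FiducialSet",
    "filter_z_band",
    "filter_tumor_proximity",
    "build_distance_graph",
    "triangle_angles",
    "enumerate_valid_sets",
    "brute_force_plan",
    "DegenerateGeometryError",
]

logger = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Coincident points make the requested geometry undefined."""


@dataclass
class ConstraintConfig:
    """All thresholds of the placement constraint system.

    Attributes
    ----------
    d_min : float, mm
        Minimum pairwise inter-marker distance (inclusive); default 18.
    theta_min : float, degrees
        Minimum interior triangle angle (inclusive); default 30.  The
        CyberKnife manual's floor is 15 deg; 30 gives headroom against
        post-implantation marker migration.
    d_tumor_max : float, mm
        Maximum marker-to-tumor-centroid distance; default 50.
    band : (lo, hi), mm
        Admissible marker depth band above the tumor surface; default
        (20, 30) for superficial lesions.
    z_half_width : float or None, mm
        Half-width of the Z-band prefilter about the tumor mid-Z; None
        means unbounded (the pipeline derives a default from the tumor
        extent).
    set_size : int
        Number of markers per set; >= 3 for stable 6D tracking.
    strict_paper_cliques : bool
        Enumerate only maximal cliques of size exactly ``set_size``.
    view_angles : tuple of float, degrees
        Oblique imaging views; default (+45, -45).
    overlap_extent : float, mm
        Projected distance below which two markers overlap (strict <);
        default 5, a typical gold-fiducial length.
    literal_projection : bool
        Project onto the X-Y plane after rotation (the literal recipe)
        instead of onto the rotated X-Z plane.
    strict_rubric : bool
        Score with strict inequalities at the rubric boundaries.
    """

    d_min: float = 18.0
    theta_min: float = 30.0
    d_tumor_max: float = 50.0
    band: tuple[float, float] = (20.0, 30.0)
    z_half_width: float | None = None
    set_size: int = 3
    strict_paper_cliques: bool = False
    view_angles: tuple[float, ...] = (45.0, -45.0)
    overlap_extent: float = 5.0
    literal_projection: bool = False
    strict_rubric: bool = False

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValidationError("d_min must be positive")
        if not (0 < self.theta_min < 60):
            raise ValidationError("theta_min must lie in (0, 60) degrees: "
                                  "three angles >= theta_min forces theta_min <= 60")
        if self.d_tumor_max <= 0:
            raise ValidationError("d_tumor_max must be positive")
        lo, hi = self.band
        if not (0 <= lo <= hi):
            raise ValidationError("band must satisfy 0 <= lo <= hi")
        if self.set_size < 3:
            raise ValidationError("set_size must be >= 3")
        if self.overlap_extent < 0:
            raise ValidationError("overlap_extent must be >= 0")

    @classmethod
    def manual_floor(cls, **overrides) -> "ConstraintConfig":
        """Preset with the CyberKnife manual's 15 deg angular floor."""
        overrides.setdefault("theta_min", 15.0)
        return cls(**overrides)


@dataclass
class FiducialSet:
    """An ordered marker set with its cached geometric metrics.

    For a set accepted by the full pipeline: all pairwise distances
    >= d_min, all triangle angles >= theta_min, all centroid distances
    <= d_tumor_max, and overlap-free in every configured view.
    """

    markers: np.ndarray
    indices: tuple[int, ...]
    pairwise_distances: np.ndarray
    triangle_angles: np.ndarray
    centroid_distances: np.ndarray
    overlap_free: dict[float, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float).reshape(-1, 3)
        self.indices = tuple(int(i) for i in self.indices)

    def __len__(self) -> int:
        return len(self.indices)


def filter_z_band(candidates: CandidateSet, z_center: float,
                  half_width: float | None) -> CandidateSet:
    """Retain candidates with |z - z_center| <= half_width (inclusive).

    ``half_width=None`` means unbounded and returns the input unchanged.
    Order is preserved; an empty result is allowed (and logged).
    """
    if half_width is None or np.isinf(half_width):
        return candidates
    if half_width <= 0:
        raise ValidationError("z half_width must be positive or None")
    keep = np.abs(candidates.points[:, 2] - z_center) <= half_width
    if not np.any(keep):
        logger.warning("Z-band filter removed every candidate "
                       "(center %.1f mm, half-width %.1f mm)", z_center, half_width)
    return candidates.subset(np.flatnonzero(keep))


def filter_tumor_proximity(candidates: CandidateSet, tumor: PointCloud3D,
                           tumor_centroid: np.ndarray,
                           config: ConstraintConfig) -> CandidateSet:
    """Apply the centroid-distance and surface-band proximity rules.

    Keeps candidates whose distance to the tumor centroid is
    <= ``d_tumor_max`` AND whose distance to the tumor surface lies in
    ``band`` (both inclusive).  The centroid rule anchors tracking
    accuracy (marker and tumor must move together); the band keeps
    implantation superficial.

    Annotations already present on the candidate set are trusted;
    missing ones are computed -- the centroid distance exactly, the
    surface distance as the nearest-neighbour distance to the tumor
    cloud (a slight overestimate at finite sampling density).
    """
    if len(tumor) == 0:
        raise ValidationError("tumor cloud is empty")
    cen = np.asarray(tumor_centroid, dtype=float)
    d_cen = candidates.tumor_centroid_distance
    if np.any(np.isnan(d_cen)):
        d_cen = np.linalg.norm(candidates.points - cen, axis=1)
    d_surf = candidates.tumor_surface_distance
    if np.any(np.isnan(d_surf)):
        tree = cKDTree(tumor.points)
        d_surf, _ = tree.query(candidates.points)
    lo, hi = config.band
    keep = (d_cen <= config.d_tumor_max) & (d_surf >= lo) & (d_surf <= hi)
    out = CandidateSet(candidates.points[keep], candidates.params[keep],
                       d_cen[keep], d_surf[keep])
    return out


def build_distance_graph(candidates: CandidateSet, d_min: float) -> nx.Graph:
    """Graph over candidate indices with edges joining far-apart pairs.

    Edge (i, j) iff the Euclidean distance is >= ``d_min`` (inclusive).
    Close pairs (< d_min) are found by a fixed-radius kd-tree query and
    the edge set is their complement, which equals the all-pairs
    construction exactly.
    """
    n = len(candidates)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    if n < 2:
        logger.warning("distance graph over %d candidate(s): no edges", n)
        return G
    pts = candidates.points
    tree = cKDTree(pts)
    close = set()
    for i, j in tree.query_pairs(r=d_min):  # includes pairs at exactly d_min
        if np.linalg.norm(pts[i] - pts[j]) < d_min:
            close.add((min(i, j), max(i, j)))
    edges = ((i, j) for i, j in itertools.combinations(range(n), 2)
             if (i, j) not in close)
    G.add_edges_from(edges)
    return G


def triangle_angles(g1, g2, g3) -> np.ndarray:
    """Interior angles (degrees) of the triangle g1-g2-g3, in vertex order.

    Each angle is arccos of the normalised dot product of the two edge
    vectors leaving its vertex.  Collinear (but distinct) points return
    (0, 0, 180); coincident points raise ``DegenerateGeometryError``.
    """
    pts = [np.asarray(g, dtype=float) for g in (g1, g2, g3)]
    out = np.empty(3)
    for k in range(3):
        a = pts[(k + 1) % 3] - pts[k]
        b = pts[(k + 2) % 3] - pts[k]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise DegenerateGeometryError("coincident marker points")
        c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
        out[k] = np.degrees(np.arccos(c))
    return out


def _triangle_angles_batch(pts: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Vectorised interior angles for an (S, 3) array of index triples."""
    P = pts[triples]  # (S, 3, 3)
    out = np.empty((len(triples), 3))
    for k in range(3):
        a = P[:, (k + 1) % 3] - P[:, k]
        b = P[:, (k + 2) % 3] - P[:, k]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        denom = np.where((na == 0) | (nb == 0), 1.0, na * nb)
        c = np.clip(np.einsum("ij,ij->i", a, b) / denom, -1.0, 1.0)
        out[:, k] = np.degrees(np.arccos(c))
    return out


def _pairwise_distances_batch(pts: np.ndarray, sets: np.ndarray) -> np.ndarray:
    """Pairwise distances within each index set, lexicographic pair order."""
    P = pts[sets]  # (S, k, 3)
    k = sets.shape[1]
    pairs = list(itertools.combinations(range(k), 2))
    return np.stack([np.linalg.norm(P[:, i] - P[:, j], axis=1) for i, j in pairs],
                    axis=1)


def _make_sets(candidates: CandidateSet, sets_idx: np.ndarray,
               dists: np.ndarray, angles: np.ndarray) -> list[FiducialSet]:
    d_cen = candidates.tumor_centroid_distance
    return [FiducialSet(candidates.points[idx], tuple(idx), d, a, d_cen[list(idx)])
            for idx, d, a in zip(sets_idx, dists, angles)]


def _graph_triangles(G: nx.Graph) -> np.ndarray:
    """All triangles (i < j < k) of the graph as an (S, 3) index array."""
    n = G.number_of_nodes()
    A = nx.to_numpy_array(G, nodelist=range(n), dtype=bool)
    tris = []
    for e in G.edges():
        i, j = min(e), max(e)
        common = np.flatnonzero(A[i] & A[j])
        common = common[common > j]
        if common.size:
            tris.append(np.column_stack([np.full(common.size, i),
                                         np.full(common.size, j), common]))
    if not tris:
        return np.empty((0, 3), dtype=int)
    return np.vstack(tris)


def _graph_kcliques(G: nx.Graph, k: int) -> np.ndarray:
    """All k-cliques by ordered DFS extension (i1 < i2 < ... < ik)."""
    adj = {v: {u for u in G[v]} for v in G.nodes}

    def extend(clique: tuple[int, ...], allowed: set[int]):
        if len(clique) == k:
            yield clique
            return
        for v in sorted(u for u in allowed if u > clique[-1]):
            yield from extend(clique + (v,), allowed & adj[v])

    out = [c for v in sorted(G.nodes) for c in extend((v,), adj[v])]
    return np.asarray(out, dtype=int).reshape(-1, k)


def _angle_ok(pts: np.ndarray, sets_idx: np.ndarray, theta_min: float) -> np.ndarray:
    """Boolean mask: every 3-subset of each set has all angles >= theta_min."""
    if sets_idx.shape[1] == 3:
        return _triangle_angles_batch(pts, sets_idx).min(axis=1) >= theta_min
    ok = np.ones(len(sets_idx), dtype=bool)
    for sub in itertools.combinations(range(sets_idx.shape[1]), 3):
        tri = sets_idx[:, list(sub)]
        ok &= _triangle_angles_batch(pts, tri).min(axis=1) >= theta_min
    return ok


def enumerate_valid_sets(graph: nx.Graph, candidates: CandidateSet,
                         config: ConstraintConfig) -> list[FiducialSet]:
    """Enumerate fiducial sets satisfying distance and angle constraints.

    Default mode returns every ``set_size``-subset of every maximal
    clique -- i.e. every ``set_size``-clique of the graph -- whose
    triangle angles all reach ``theta_min``.  Strict-paper mode runs
    Bron-Kerbosch and keeps only maximal cliques of size exactly
    ``set_size``, angle-filtered.  Output is deduplicated and sorted by
    lexicographic candidate indices.
    """
    pts = candidates.points
    k = config.set_size
    if config.strict_paper_cliques:
        cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) == k]
        sets_idx = np.asarray(sorted(set(cliques)), dtype=int).reshape(-1, k)
    elif k == 3:
        sets_idx = _graph_triangles(graph)
    else:
        sets_idx = _graph_kcliques(graph, k)
    if len(sets_idx) == 0:
        return []
    sets_idx = sets_idx[np.lexsort(sets_idx.T[::-1])]
    keep = _angle_ok(pts, sets_idx, config.theta_min)
    sets_idx = sets_idx[keep]
    dists = _pairwise_distances_batch(pts, sets_idx)
    angles = (_triangle_angles_batch(pts, sets_idx) if k == 3
              else np.full((len(sets_idx), 3), np.nan))
    return _make_sets(candidates, sets_idx, dists, angles)


def brute_force_plan(candidates: CandidateSet,
                     config: ConstraintConfig) -> list[FiducialSet]:
    """Exhaustive k-subset enumeration: the correctness oracle.

    Applies the pairwise-distance and triangle-angle rules directly to
    every combination of candidates, with no spatial index or graph.
    """
    n = len(candidates)
    k = config.set_size
    if n < k:
        return []
    pts = candidates.points
    sets_idx = np.asarray(list(itertools.combinations(range(n), k)), dtype=int)
    out_sets, out_d, out_a = [], [], []
    for chunk in np.array_split(sets_idx, max(1, len(sets_idx) // 200_000)):
        d = _pairwise_distances_batch(pts, chunk)
        keep = d.min(axis=1) >= config.d_min
        chunk, d = chunk[keep], d[keep]
        keep = _angle_ok(pts, chunk, config.theta_min)
        out_sets.append(chunk[keep])
        out_d.append(d[keep])
    sets_idx = np.vstack(out_sets)
    dists = np.vstack(out_d)
    angles = (_triangle_angles_batch(pts, sets_idx) if k == 3
              else np.full((len(sets_idx), 3), np.nan))
    return _make_sets(candidates, sets_idx, dists, angles)
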