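"""Constraint filters, distance graph, and set enumeration vs the oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fidplan import (ConstraintConfig, PointCloud3D, ValidationError,
                     brute_force_plan, build_distance_graph,
                     enumerate_valid_sets, filter_tumor_proximity,
                     filter_z_band, generate_phantom, triangle_angles)
from fidplan.bspline import CandidateSet
from fidplan.constraints import DegenerateGeometryError
from fidplan.geometry import PhantomSpec


def _cands(pts):
    pts = np.asarray(pts, dtype=float)
    return CandidateSet(pts, np.zeros((len(pts), 2)))


class TestConfig:
    def test_defaults_match_clinical_thresholds(self):
        cfg = ConstraintConfig()
        assert (cfg.d_min, cfg.theta_min, cfg.d_tumor_max) == (18.0, 30.0, 50.0)
        assert cfg.band == (20.0, 30.0)
        assert cfg.view_angles == (45.0, -45.0)

    def test_manual_floor_preset(self):
        assert ConstraintConfig.manual_floor().theta_min == 15.0

    def test_invalid_thresholds_rejected(self):
        for bad in (dict(d_min=0), dict(theta_min=60), dict(theta_min=0),
                    dict(set_size=2), dict(band=(30, 20))):
            with pytest.raises(ValidationError):
                ConstraintConfig(**bad)


class TestZBand:
    def test_unbounded_is_identity(self, rng):
        cs = _cands(rng.uniform(-50, 50, (30, 3)))
        out = filter_z_band(cs, 0.0, None)
        assert np.array_equal(out.points, cs.points)

    def test_boundary_inclusive(self):
        cs = _cands([[0, 0, 10], [0, 0, -10], [0, 0, 10.0001]])
        out = filter_z_band(cs, 0.0, 10.0)
        assert len(out) == 2

    def test_matches_linear_scan(self, rng):
        z = rng.uniform(0, 100, 100)
        pts = np.column_stack([rng.uniform(size=(100, 2)), z])
        cs = _cands(pts)
        out = filter_z_band(cs, 50.0, 20.0)
        expected = sum(1 for zz in z if abs(zz - 50.0) <= 20.0)
        assert len(out) == expected
        # order preserved
        kept_z = [zz for zz in z if abs(zz - 50.0) <= 20.0]
        assert np.allclose(out.points[:, 2], kept_z)


class TestProximity:
    cfg = ConstraintConfig()

    def _tumor(self):
        spec = PhantomSpec(seed=1)
        tumor, _, cen = generate_phantom(spec)
        return tumor, cen

    def test_inclusive_centroid_boundary(self):
        tumor, cen = self._tumor()
        # points along +x at exactly 50 and at 51 mm from the centroid,
        # surface distances pre-annotated mid-band
        cs = CandidateSet([[50.0, 0, 0], [51.0, 0, 0]], np.zeros((2, 2)),
                          tumor_centroid_distance=[50.0, 51.0],
                          tumor_surface_distance=[25.0, 25.0])
        out = filter_tumor_proximity(cs, tumor, cen, self.cfg)
        assert len(out) == 1
        assert out.tumor_centroid_distance[0] == 50.0

    def test_phantom_shell_fully_retained_by_matching_band(self):
        spec = PhantomSpec(seed=5)
        tumor, shell, cen = generate_phantom(spec)
        offs = shell.metadata["surface_offset"]
        cs = CandidateSet(shell.points, np.zeros((len(shell), 2)),
                          tumor_surface_distance=offs)
        out = filter_tumor_proximity(cs, tumor, cen, self.cfg)
        assert len(out) == len(shell)
        # band moved above the construction offsets: nothing survives
        narrow = ConstraintConfig(band=(31.0, 40.0))
        out2 = filter_tumor_proximity(cs, tumor, cen, narrow)
        assert len(out2) == 0

    def test_recomputes_missing_annotations(self):
        tumor, cen = self._tumor()
        spec = PhantomSpec(seed=5)
        _, shell, _ = generate_phantom(spec)
        cs = CandidateSet(shell.points, np.zeros((len(shell), 2)))
        out = filter_tumor_proximity(cs, tumor, cen, self.cfg)
        assert np.all(np.isfinite(out.tumor_surface_distance))
        assert len(out) > 0.8 * len(shell)

    def test_empty_tumor_rejected(self):
        # an empty tumor cloud violates the PointCloud3D invariant itself
        with pytest.raises(ValidationError):
            PointCloud3D(np.empty((0, 3)), label="tumor-surface")


class TestDistanceGraph:
    def test_pair_below_threshold_no_edge(self):
        g = build_distance_graph(_cands([[0, 0, 0], [17.9, 0, 0]]), 18.0)
        assert g.number_of_edges() == 0

    def test_pair_at_threshold_has_edge(self):
        g = build_distance_graph(_cands([[0, 0, 0], [18.0, 0, 0]]), 18.0)
        assert g.number_of_edges() == 1

    def test_matches_all_pairs_double_loop(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 60, (100, 3))
        g = build_distance_graph(_cands(pts), 18.0)
        expected = {(i, j) for i, j in itertools.combinations(range(100), 2)
                    if np.linalg.norm(pts[i] - pts[j]) >= 18.0}
        got = {(min(e), max(e)) for e in g.edges()}
        assert got == expected

    def test_single_candidate_empty_graph(self):
        g = build_distance_graph(_cands([[0, 0, 0]]), 18.0)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0


class TestTriangleAngles:
    def test_equilateral(self):
        p = np.array([[0, 0, 0], [20, 0, 0], [10, 10 * np.sqrt(3), 0]])
        assert np.allclose(triangle_angles(*p), [60, 60, 60], atol=1e-9)

    def test_right_isoceles(self):
        angles = triangle_angles([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert np.allclose(sorted(angles), [45, 45, 90], atol=1e-9)

    def test_collinear_returns_0_0_180(self):
        angles = triangle_angles([0, 0, 0], [2, 0, 0], [1, 0, 0])
        assert np.allclose(sorted(angles), [0, 0, 180], atol=1e-9)

    def test_coincident_raises(self):
        with pytest.raises(DegenerateGeometryError):
            triangle_angles([1, 2, 3], [1, 2, 3], [0, 0, 0])

    @given(st.integers(0, 2**31 - 1))
    def test_angle_sum_is_180(self, seed):
        pts = np.random.default_rng(seed).uniform(-50, 50, (3, 3))
        if min(np.linalg.norm(pts[i] - pts[j]) for i, j in
               ((0, 1), (0, 2), (1, 2))) < 1e-6:
            return
        assert abs(triangle_angles(*pts).sum() - 180.0) < 1e-6


class TestEnumeration:
    cfg = ConstraintConfig()

    def test_equilateral_triple_accepted(self):
        pts = [[0, 0, 0], [20, 0, 0], [10, 10 * np.sqrt(3), 0]]
        cs = _cands(pts)
        g = build_distance_graph(cs, self.cfg.d_min)
        sets = enumerate_valid_sets(g, cs, self.cfg)
        assert len(sets) == 1
        assert np.allclose(sets[0].triangle_angles, [60, 60, 60], atol=1e-9)
        assert brute_force_plan(cs, self.cfg)[0].indices == sets[0].indices

    def test_near_collinear_triple_rejected(self):
        # pairwise >= 18 mm but flat: min angle < 30 deg
        pts = [[0, 0, 0], [20, 2, 0], [40, 0, 0]]
        cs = _cands(pts)
        assert min(triangle_angles(*cs.points)) < 30.0
        g = build_distance_graph(cs, self.cfg.d_min)
        assert enumerate_valid_sets(g, cs, self.cfg) == []
        assert brute_force_plan(cs, self.cfg) == []

    def test_empty_candidates_empty_plan(self):
        assert brute_force_plan(_cands(np.empty((0, 3))), self.cfg) == []
        assert brute_force_plan(_cands([[0, 0, 0], [30, 0, 0]]), self.cfg) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_instances(self, seed):
        """kd-tree/graph enumeration equals brute force, 20 instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 80))
        pts = rng.uniform(0, 70, (n, 3))
        cs = _cands(pts)
        g = build_distance_graph(cs, self.cfg.d_min)
        fast = enumerate_valid_sets(g, cs, self.cfg)
        slow = brute_force_plan(cs, self.cfg)
        assert [s.indices for s in fast] == [s.indices for s in slow]
        for f, s in zip(fast, slow):
            assert np.allclose(f.pairwise_distances, s.pairwise_distances)
            assert np.allclose(f.triangle_angles, s.triangle_angles)

    def test_oracle_equivalence_large_instance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 60, (200, 3))
        cs = _cands(pts)
        g = build_distance_graph(cs, self.cfg.d_min)
        fast = enumerate_valid_sets(g, cs, self.cfg)
        slow = brute_force_plan(cs, self.cfg)
        assert [s.indices for s in fast] == [s.indices for s in slow]

    def test_soundness_of_returned_sets(self, rng):
        pts = rng.uniform(0, 70, (40, 3))
        cs = _cands(pts)
        g = build_distance_graph(cs, self.cfg.d_min)
        for s in enumerate_valid_sets(g, cs, self.cfg):
            assert np.all(s.pairwise_distances >= self.cfg.d_min)
            assert np.all(s.triangle_angles >= self.cfg.theta_min)

    def test_strict_paper_mode_is_subset(self, rng):
        pts = rng.uniform(0, 55, (14, 3))
        cs = _cands(pts)
        g = build_distance_graph(cs, self.cfg.d_min)
        default = {s.indices for s in enumerate_valid_sets(g, cs, self.cfg)}
        strict_cfg = ConstraintConfig(strict_paper_cliques=True)
        strict = {s.indices for s in enumerate_valid_sets(g, cs, strict_cfg)}
        assert strict <= default

    def test_monotone_in_thresholds(self, rng):
        pts = rng.uniform(0, 70, (30, 3))
        cs = _cands(pts)
        counts = []
        for d_min, theta in ((18.0, 30.0), (25.0, 30.0), (25.0, 45.0)):
            cfg = ConstraintConfig(d_min=d_min, theta_min=theta)
            g = build_distance_graph(cs, cfg.d_min)
            counts.append(len(enumerate_valid_sets(g, cs, cfg)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 70, (25, 3))
        cs = _cands(pts)
        g = build_distance_graph(cs, self.cfg.d_min)
        base = enumerate_valid_sets(g, cs, self.cfg)
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        moved = _cands(pts @ q.T + np.array([10.0, -5.0, 30.0]))
        g2 = build_distance_graph(moved, self.cfg.d_min)
        other = enumerate_valid_sets(g2, moved, self.cfg)
        assert [s.indices for s in base] == [s.indices for s in other]
        for a, b in zip(base, other):
            assert np.allclose(a.pairwise_distances, b.pairwise_distances, atol=1e-9)
            assert np.allclose(a.triangle_angles, b.triangle_angles, atol=1e-9)

    def test_four_marker_sets(self, rng):
        """set_size = 4: every 3-subset must satisfy the angle rule."""
        cfg = ConstraintConfig(set_size=4)
        pts = rng.uniform(0, 80, (16, 3))
        cs = _cands(pts)
        g = build_distance_graph(cs, cfg.d_min)
        fast = enumerate_valid_sets(g, cs, cfg)
        slow = brute_force_plan(cs, cfg)
        assert [s.indices for s in fast] == [s.indices for s in slow]
        for s in fast:
            assert np.all(s.pairwise_distances >= cfg.d_min)
            for sub in itertools.combinations(range(4), 3):
                assert min(triangle_angles(*s.markers[list(sub)])) >= cfg.theta_min
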