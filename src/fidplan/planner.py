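"""End-to-end placement planning: the model/results interface.

``FiducialPlanner`` bundles the anatomy (tumor surface cloud plus,
optionally, a separate implantation-region cloud), the constraint
configuration and the surface-fit settings.  ``fit()`` runs the whole
pipeline -- B-spline fit, uniform sampling, Z-band and proximity
filters, distance-graph construction, triple enumeration, projection
overlap filtering, rubric scoring -- and returns a ``PlanResults``
object carrying every intermediate count, the surviving fiducial sets
with their cached metrics, and their rubric scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bspline, constraints, projection, scoring
from .bspline import CandidateSet, FitResult
from .constraints import ConstraintConfig, FiducialSet
from .geometry import PhantomSpec, PointCloud3D, centroid, generate_phantom
from .scoring import RubricScore

__all__ = ["FiducialPlanner", "PlanResults"]

logger = logging.getLogger(__name__)


@dataclass
class FiducialPlanner:
    """Placement-planning model for one tumor.

    Parameters
    ----------
    tumor : PointCloud3D
        Tumor-surface points (mm).
    implant_cloud : PointCloud3D, optional
        Cloud to fit the candidate surface to (e.g. an offset shell or
        a skin band).  Defaults to the tumor cloud itself, in which
        case candidates lie on the fitted tumor surface.
    config : ConstraintConfig
        All geometric thresholds.
    degrees, grid : surface fit settings (cubic, 6 x 6 by default).
    sampling : (n_u, n_v)
        Uniform candidate grid on the fitted surface (8 x 8 default,
        64 candidates -- rich enough for many triples, small enough
        for exhaustive cross-checks).
    smoothing : float
        Tikhonov weight on control-grid second differences; 0 disables.
    """

    tumor: PointCloud3D
    implant_cloud: PointCloud3D | None = None
    config: ConstraintConfig = field(default_factory=ConstraintConfig)
    degrees: tuple[int, int] = (3, 3)
    grid: tuple[int, int] = (6, 6)
    sampling: tuple[int, int] = (8, 8)
    smoothing: float = 0.0

    @classmethod
    def from_phantom(cls, spec: PhantomSpec, **kwargs) -> "FiducialPlanner":
        """Build a planner from a synthetic superficial-tumor phantom."""
        tumor, shell, _ = generate_phantom(spec)
        return cls(tumor, implant_cloud=shell, **kwargs)

    # ------------------------------------------------------------------
    def default_z_half_width(self) -> float:
        """Half the tumor's Z extent plus 10 mm."""
        z = self.tumor.points[:, 2]
        return (z.max() - z.min()) / 2.0 + 10.0

    def fit(self) -> "PlanResults":
        """Run the full planning pipeline and return its results."""
        cfg = self.config
        tumor_cen = centroid(self.tumor)
        fit_cloud = self.implant_cloud if self.implant_cloud is not None else self.tumor
        axis = bspline.principal_axis(fit_cloud)
        params = bspline.parameterize_cloud(fit_cloud, centroid(fit_cloud), axis)
        surface_fit = bspline.fit_surface(
            fit_cloud, params, degree_u=self.degrees[0], degree_v=self.degrees[1],
            grid=self.grid, smoothing=self.smoothing)
        candidates = bspline.sample_surface(surface_fit.surface, *self.sampling)
        counts = {"sampled": len(candidates)}

        half_width = cfg.z_half_width
        if half_width is None:
            half_width = self.default_z_half_width()
        after_z = constraints.filter_z_band(candidates, tumor_cen[2], half_width)
        counts["after_z_band"] = len(after_z)

        after_prox = constraints.filter_tumor_proximity(
            after_z, self.tumor, tumor_cen, cfg)
        counts["after_proximity"] = len(after_prox)

        graph = constraints.build_distance_graph(after_prox, cfg.d_min)
        counts["graph_edges"] = graph.number_of_edges()
        sets = constraints.enumerate_valid_sets(graph, after_prox, cfg)
        counts["after_angle"] = len(sets)

        final = projection.drr_filter(sets, tumor_cen, cfg)
        counts["after_drr"] = len(final)
        logger.info("pipeline stage counts: %s", counts)

        scores = []
        for s in final:
            views = [projection.project_view(s.markers, tumor_cen, a,
                                             literal=cfg.literal_projection)
                     for a in cfg.view_angles]
            scores.append(scoring.score_plan(s, tumor_cen, views, cfg))

        return PlanResults(planner=self, config=replace(cfg),
                           tumor_centroid=tumor_cen,
                           surface_fit=surface_fit, candidates=candidates,
                           stage_counts=counts, sets=final, scores=scores)


@dataclass
class PlanResults:
    """Results of a planning run.

    Attributes
    ----------
    surface_fit : FitResult
        The fitted candidate surface and its least-squares residual.
    stage_counts : dict
        Candidate/set counts after every pipeline stage.
    sets : list of FiducialSet
        Marker sets passing every constraint, lexicographically ordered
        by candidate index.
    scores : list of RubricScore
        The 10-point rubric score of each set.
    """

    planner: FiducialPlanner
    config: ConstraintConfig
    tumor_centroid: np.ndarray
    surface_fit: FitResult
    candidates: CandidateSet
    stage_counts: dict[str, int]
    sets: list[FiducialSet]
    scores: list[RubricScore]

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def best(self) -> tuple[FiducialSet, RubricScore] | None:
        """First (lexicographically smallest) surviving set, or None."""
        if not self.sets:
            return None
        return self.sets[0], self.scores[0]

    def sets_frame(self) -> pd.DataFrame:
        """Per-set metrics as a DataFrame."""
        rows = []
        for s, sc in zip(self.sets, self.scores):
            rows.append({
                "indices": s.indices,
                "min_pair_distance_mm": float(s.pairwise_distances.min()),
                "min_angle_deg": float(np.nanmin(s.triangle_angles)),
                "max_centroid_distance_mm": float(s.centroid_distances.max()),
                "score_total": sc.total,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = ["Fiducial placement plan", "=" * 46]
        lines.append(f"surface fit residual E: {self.surface_fit.residual_E:.4g} mm^2 "
                     f"over {len(self.surface_fit.per_point_residuals)} points")
        for stage, n in self.stage_counts.items():
            lines.append(f"  {stage:<18s} {n}")
        lines.append(f"feasible marker sets: {self.n_sets}")
        if self.sets:
            df = self.sets_frame()
            lines.append(f"score totals: min {df.score_total.min()}, "
                         f"max {df.score_total.max()} (of 10)")
            s, sc = self.best  # type: ignore[misc]
            lines.append("first set:")
            lines.append(f"  candidate indices {s.indices}")
            for i, m in enumerate(s.markers):
                lines.append(f"  marker {i}: ({m[0]:8.2f}, {m[1]:8.2f}, {m[2]:8.2f}) mm")
            lines.append(f"  pair distances (mm): "
                         + ", ".join(f"{d:.1f}" for d in s.pairwise_distances))
            lines.append(f"  triangle angles (deg): "
                         + ", ".join(f"{a:.1f}" for a in s.triangle_angles))
            lines.append(f"  centroid distances (mm): "
                         + ", ".join(f"{d:.1f}" for d in s.centroid_distances))
            lines.append(f"  rubric: {sc.c1_proximity_points}+{sc.c2_angle_points}"
                         f"+{sc.c3_distance_points}+{sc.c4_nonoverlap_points}"
                         f" = {sc.total}/10")
        return "\n".join(lines)

    def to_report(self) -> dict:
        extra = {
            "surface_fit": {
                "residual_E_mm2": self.surface_fit.residual_E,
                "fitted_cloud": (self.planner.implant_cloud.label
                                 if self.planner.implant_cloud is not None
                                 else self.planner.tumor.label),
                "degrees": list(self.planner.degrees),
                "grid": list(self.planner.grid),
            },
            "tumor_centroid_mm": self.tumor_centroid,
        }
        return scoring.build_report(self.config, self.stage_counts,
                                    self.sets, self.scores, extra=extra)

    def save_report(self, path, format: str = "json") -> None:
        scoring.render_report(self.to_report(), path, format=format)

    def plot(self, ax=None, max_sets: int = 1):
        """3-D scatter of tumor, candidates, and the leading marker set(s)."""
        import matplotlib.pyplot as plt  # deferred: headless envs

        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        t = self.planner.tumor.points
        ax.scatter(*t.T, s=2, alpha=0.3, label="tumor surface")
        c = self.candidates.points
        ax.scatter(*c.T, s=6, alpha=0.5, label="candidates")
        for s in self.sets[:max_sets]:
            ax.scatter(*s.markers.T, s=60, marker="^", label=f"set {s.indices}")
        ax.set_xlabel("x (mm)"); ax.set_ylabel("y (mm)"); ax.set_zlabel("z (mm)")
        ax.legend(loc="upper right", fontsize=7)
        return ax
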