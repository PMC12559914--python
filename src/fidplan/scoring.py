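"""The 10-point plan-quality rubric and report writers.

A marker set is scored on four criteria:

1. number of markers within 50 mm of the tumor centroid (1 -> 1 pt,
   2 -> 2 pts, >= 3 -> 3 pts);
2. all inter-marker angles meet the 30 deg threshold (2 pts, else 0);
3. all inter-marker distances meet the 18 mm threshold (2 pts, else 0);
4. number of markers free of projection overlap in every view
   (1 -> 1, 2 -> 2, >= 3 -> 3).

Maximum total is 10.  At exact thresholds (a pair at exactly 18 mm, an
angle at exactly 30 deg) points are awarded, so sets accepted by the
inclusive planner always score full marks; ``strict_rubric`` switches
to strict inequalities.  Zero qualifying markers on criteria 1/4 has
no rubric row and scores 0 with a warning.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .constraints import ConstraintConfig, FiducialSet
from .projection import ProjectedView, check_overlap

__all__ = ["RubricScore", "score_plan", "render_report"]

logger = logging.getLogger(__name__)

_COUNT_POINTS = {0: 0, 1: 1, 2: 2}  # >= 3 -> 3


def _count_points(n: int) -> int:
    return _COUNT_POINTS.get(n, 3)


@dataclass
class RubricScore:
    """Per-criterion and total plan-quality points."""

    c1_proximity_points: int
    c2_angle_points: int
    c3_distance_points: int
    c4_nonoverlap_points: int
    total: int
    warnings: list[str] = field(default_factory=list)


def score_plan(markers: FiducialSet, tumor_centroid: np.ndarray,
               views: list[ProjectedView], config: ConstraintConfig) -> RubricScore:
    """Score one marker set against the four-criterion rubric."""
    warnings: list[str] = []
    cen = np.asarray(tumor_centroid, dtype=float)
    d_cen = np.linalg.norm(markers.markers - cen, axis=1)
    if config.strict_rubric:
        n_close = int(np.sum(d_cen < config.d_tumor_max))
        angles_ok = bool(np.all(markers.triangle_angles > config.theta_min))
        dist_ok = bool(np.all(markers.pairwise_distances > config.d_min))
    else:
        n_close = int(np.sum(d_cen <= config.d_tumor_max))
        angles_ok = bool(np.all(markers.triangle_angles >= config.theta_min))
        dist_ok = bool(np.all(markers.pairwise_distances >= config.d_min))
    if n_close == 0:
        warnings.append("no marker within the centroid-distance threshold; "
                        "criterion 1 scored 0 (no rubric row for 0 markers)")
        logger.warning(warnings[-1])
    c1 = _count_points(n_close)
    c2 = 2 if angles_ok else 0
    c3 = 2 if dist_ok else 0

    overlapping: set[int] = set()
    for view in views:
        _, pairs = check_overlap(view, config.overlap_extent)
        for i, j in pairs:
            overlapping.update((i, j))
    n_clear = len(markers) - len(overlapping)
    if n_clear == 0:
        warnings.append("every marker overlaps in some view; criterion 4 scored 0")
        logger.warning(warnings[-1])
    c4 = _count_points(n_clear)
    return RubricScore(c1, c2, c3, c4, c1 + c2 + c3 + c4, warnings)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def build_report(config: ConstraintConfig, stage_counts: dict[str, int],
                 sets: list[FiducialSet], scores: list[RubricScore],
                 extra: dict | None = None) -> dict:
    """Assemble the full plan report as a JSON-ready dictionary."""
    entries = []
    for s, sc in zip(sets, scores):
        entries.append({
            "indices": list(s.indices),
            "markers_mm": s.markers.tolist(),
            "pairwise_distances_mm": s.pairwise_distances.tolist(),
            "triangle_angles_deg": _jsonable(s.triangle_angles),
            "centroid_distances_mm": _jsonable(s.centroid_distances),
            "overlap_free": _jsonable(s.overlap_free),
            "score": _jsonable(asdict(sc)),
        })
    report = {
        "config": _jsonable(asdict(config)),
        "stage_counts": dict(stage_counts),
        "n_sets": len(entries),
        "sets": entries,
    }
    if extra:
        report.update(_jsonable(extra))
    return report


def render_report(report: dict, path: str | os.PathLike, format: str = "json") -> None:
    """Write a plan report as JSON (lossless), CSV (per-set rows), or Markdown."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["indices", "min_pair_distance_mm", "min_angle_deg",
                             "max_centroid_distance_mm", "c1", "c2", "c3", "c4", "total"])
            for e in report["sets"]:
                sc = e["score"]
                writer.writerow([
                    " ".join(map(str, e["indices"])),
                    min(e["pairwise_distances_mm"]),
                    min(e["triangle_angles_deg"]),
                    max(e["centroid_distances_mm"]),
                    sc["c1_proximity_points"], sc["c2_angle_points"],
                    sc["c3_distance_points"], sc["c4_nonoverlap_points"], sc["total"],
                ])
    elif format == "md":
        lines = ["# Fiducial placement plan", "", "## Stage counts", ""]
        for k, v in report["stage_counts"].items():
            lines.append(f"- {k}: {v}")
        lines += ["", f"## Marker sets ({report['n_sets']})", ""]
        lines.append("| indices | min pair dist (mm) | min angle (deg) | total score |")
        lines.append("|---|---|---|---|")
        for e in report["sets"][:50]:
            lines.append("| {} | {:.2f} | {:.2f} | {} |".format(
                " ".join(map(str, e["indices"])),
                min(e["pairwise_distances_mm"]),
                min(e["triangle_angles_deg"]),
                e["score"]["total"]))
        if report["n_sets"] > 50:
            lines.append(f"| ... ({report['n_sets'] - 50} more) | | | |")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported report format: {format!r}")
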