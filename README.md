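# fidplan

Geometric planning of fiducial-marker placement for CyberKnife
stereotactic body radiotherapy (SBRT) of superficial tumors.

CyberKnife tracks a tumor through small radiopaque (gold) fiducial
markers imaged by two oblique kV X-ray views at ±45° about the
superior–inferior (Z) axis. For tracking to work, a marker set must
satisfy strict geometric constraints: every inter-marker distance
≥ 18 mm, every angle of the marker triangle ≥ 30°, every marker within
50 mm of the tumor centroid, and no two markers overlapping in either
oblique projection. Placing markers by hand to meet all of these at
once is slow and operator-dependent. `fidplan` automates it for
superficial lesions (roughly 20–50 mm below the skin), where markers
can sit in a shallow tissue band above the tumor.

## Method

1. **Candidate surface.** A clamped tensor-product B-spline surface
   `S(u,v) = Σᵢ Σⱼ N_{i,p}(u) N_{j,q}(v) P_{i,j}` is fitted to a point
   cloud around the tumor (the tumor surface itself, or an offset
   implantation shell) by minimising the least-squares error
   `E = Σₖ ‖Pₖ − S(uₖ,vₖ)‖²` over the control points `P_{i,j}`.
   Scattered clouds are parameterized cylindrically about their
   principal axis.
2. **Candidates.** The surface is sampled on a uniform `(u,v)` grid;
   samples are filtered by a Z-band about the tumor mid-plane and by
   the proximity rules (centroid distance ≤ 50 mm; depth above the
   tumor surface within a 20–30 mm band).
3. **Triple enumeration.** Candidates become the vertices of a graph
   with an edge wherever two points are ≥ 18 mm apart (close pairs are
   found by a fixed-radius kd-tree query). Valid marker sets are the
   triangles (generally k-cliques) of this graph whose interior angles
   all reach 30°; a literal maximal-clique mode (Bron–Kerbosch) is
   available, and an exhaustive brute-force enumerator serves as the
   correctness oracle.
4. **Projection check.** Each surviving set is orthographically
   projected into the two ±45° views about the tumor centroid
   (rotation `R_z`, beam along the rotated Y axis); sets with any
   projected pair closer than the fiducial extent (5 mm) are rejected.
5. **Scoring.** Each final set is scored on a 10-point rubric:
   markers within 50 mm of the centroid (up to 3 pts), angle criterion
   (2), distance criterion (2), non-overlapping markers (up to 3).

A built-in phantom generator (ellipsoidal tumor plus offset candidate
shell) makes the whole pipeline runnable and testable without any
clinical data.

## Worked example

```python
from fidplan import FiducialPlanner, PhantomSpec

spec = PhantomSpec(semi_axes=(15, 15, 15), n_points=500,
                   offset_band=(20, 30), seed=42)
results = FiducialPlanner.from_phantom(spec).fit()
print(results.summary())
```

prints

```
Fiducial placement plan
==============================================
surface fit residual E: 7882 mm^2 over 500 points
  sampled            64
  after_z_band       33
  after_proximity    33
  graph_edges        493
  after_angle        2392
  after_drr          2313
feasible marker sets: 2313
score totals: min 10, max 10 (of 10)
first set:
  candidate indices (0, 2, 4)
  marker 0: (   31.54,    -7.62,   -16.19) mm
  marker 1: (   37.83,     1.74,     7.45) mm
  marker 2: (   25.84,    28.12,   -16.91) mm
  pair distances (mm): 26.2, 36.2, 37.8
  triangle angles (deg): 72.7, 65.9, 41.4
  centroid distances (mm): 36.3, 38.7, 41.9
  rubric: 3+2+2+3 = 10/10
```

Reading: 64 candidates were sampled from the fitted shell surface, 33
survive the Z-band and proximity filters, and 2313 marker triples pass
every distance, angle, and projection-overlap constraint. The first
triple has all pair distances well above 18 mm, all triangle angles
above 30°, all markers within 50 mm of the tumor centroid, and scores
the maximum 10 points. The residual `E` is large because the shell
cloud is 10 mm thick by construction — the fitted surface runs through
its middle.

The same run from the shell:

```sh
fidplan plan --phantom-sphere 15 --seed 42 --out-dir out/
fidplan phantom --sphere 15 --n 500 --seed 42 --out-dir out/   # tumor.csv + shell.csv
fidplan score my_markers.csv out/tumor.csv                     # rubric for a hand-made triple
```

`plan` exits 0 when at least one feasible set exists, 3 when none
does, and 2 on malformed input. Reports are written as JSON, CSV, or
Markdown.

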