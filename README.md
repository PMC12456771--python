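# skelphen

Automated stem–leaf segmentation and phenotypic trait extraction for seedling
3D point clouds.

Nursery phenotyping of broadleaf seedlings (heights ~20–60 cm, thin 2–6 mm
stems, 4–15 leaves growing around the stem) still relies on rulers, calipers
and leaf scanners. Given a registered, metric point cloud of a single plant
(gravity along +Y), `skelphen` separates the stem from the leaves, isolates
each leaf instance, and computes the four standard phenotypic parameters —
plant height, stem length, stem diameter and per-leaf area — fully
automatically. It is aimed at plant-phenotyping researchers who have merged
depth-camera or laser scans and want trait tables without manual annotation.

## Method

The pipeline has five stages:

1. **Preprocessing.** Statistical outlier removal: a point is discarded when
   its mean distance to its *k* nearest neighbours exceeds
   μ + α·σ of the cloud-wide distribution (defaults k = 100, α = 1.1),
   removing time-of-flight-like far outliers; an optional bounding-box crop
   stands in for background removal.
2. **Density-weighted voxel-centroid skeletonization.** The cloud is cut into
   L×L×L cubes (L₀ = 0.01 m), each split into eight sub-cubes V_j with point
   counts m_j. Sub-cubes with m_j > θ (θ = 6) are kept and each parent cube
   emits the weighted centroid

   C_w = Σ_j m_j·C_j / Σ_j m_j,  C_j = (1/m_j)·Σ_i p_i,

   which is robust to surface noise where a plain geometric centroid is not.
   The procedure can be iterated with the cube edge doubling per pass; it
   stops automatically when the density filter would annihilate rather than
   condense the point set.
3. **Stem extraction.** A Kruskal minimum spanning tree over the skeleton
   points; nodes classed by degree (TIP ≤ 1, INTERNAL = 2, JUNCTION ≥ 3); the
   leading PCA eigenvector (sign-aligned with +Y, trimmed-refit on near-line
   points) gives the principal direction. The highest junction within 2 cm of
   that line marks the stem top; the Dijkstra path down to the root node is
   spline-smoothed (natural cubic, chord-length parameterised) into the stem
   curve, and every cloud point within a fixed radius of the curve (set from
   the measured stem diameter) is labeled stem.
4. **Leaf segmentation.** The leaf cloud (complement of the stem) is
   over-segmented into supervoxels by seeded flow clustering with the
   similarity distance D = w_c·D_c²/c_max² + w_s·D_s²/(3R_seed²) + w_n·D_n²
   over curvature, position and FPFH features (R_voxel = 8 mm,
   R_seed = 10 mm, weights 0.2/0.4/1). Locally convex adjacent supervoxels
   are merged (concavity tolerance β_th = 20°, smoothness gate θ_th = 0.1,
   clusters ≤ 100 points dropped); adhering leaves that survive merging are
   split by K-means++ with the cluster count chosen adaptively,
   K = ⌊S_e/μ̄⌋ for clusters larger than the mean leaf size μ̄ (no split when
   K < 2).
5. **Traits.** Height H = Y_max − Y_min; stem length = arc length of the stem
   curve; stem diameter = 2 × the mean minor semi-axis of ellipses fitted to
   four thin slices perpendicular to the stem's PCA axis starting 5 cm above
   the base; leaf area = summed triangle area of a hole-repaired mesh per
   leaf (Delaunay on the leaf plane, long-edge pruning, boundary-ring
   detection, minimum-angle point-link hole filling).

A synthetic seedling generator (`skelphen.synthetic`) emulates the target
specimens — bowed thin stem, elliptical leaves on short petioles, Gaussian
surface noise, uniform far outliers — with per-point labels and analytic
trait values, so the whole pipeline is testable without any scan data.

## Worked example

```python
from skelphen import (PipelineConfig, SyntheticPlantSpec, generate_plant,
                      run_pipeline)

cloud, truth = generate_plant(SyntheticPlantSpec(seed=1))
cfg = PipelineConfig(measured_stem_diameter=truth.true_stem_diameter, seed=1)
res = run_pipeline(cloud, cfg)
print(res.report.to_frame())
```

Running `python examples/full_pipeline_traits.py` (the same computation plus
scoring) prints:

```
plant height:   43.09 cm  (true 43.00)
stem length:    40.60 cm  (true 40.16)
stem diameter:   4.79 mm  (true 5.00)
leaf instances: 8 (true 8)
stem point F1: 0.962
leaf instance precision/recall: 1.00 / 1.00
mean |leaf area error|: 1.6 %
```

Height and stem length land within ~1 % of the analytic truth, the diameter
within ~4 %, all eight leaves are found one-to-one, and the mesh-based areas
are within a few percent — the measurement quality the pipeline is designed
to deliver on seedlings of this size. The other scripts under `examples/`
demonstrate individual stages (generator, skeleton/stem, adaptive-K splitting
of adhering leaves).

A thin CLI mirrors the library:

```bash
skelphen generate --seed 1 --out fixture/
skelphen run fixture/plant.ply --stem-diameter 0.005 --out results/
```

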