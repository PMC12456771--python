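# Methods

This note documents the models, parameters and numerical choices behind
`skelphen`, and what the synthetic test surface does and does not establish
about real scan data.

## Scope and assumptions

The pipeline expects a single registered plant cloud in meters, gravity along
+Y, of a seedling with one erect main stem (2–6 mm diameter, possibly gently
bowed) and leaves arranged around it. Multi-view registration, background and
pot removal are upstream concerns; a bounding-box crop is provided for rough
scene trimming. All stages except K-means++ are deterministic; one seed,
threaded through the pipeline config, controls the K-means++ initialisation
and the generator.

## Synthetic seedling generator

The generator is the package's test surface. It emulates:

- a stem sampled uniformly on the surface of a cylinder (default radius
  2.5 mm) swept along a bowed axis (lateral sine bow, amplitude a fraction —
  default 0.04 — of the height, random azimuth);
- 4–15 planar elliptical leaves (semi-axes a ≈ 2.5–4 cm, b ≈ 0.45–0.6·a,
  i.e. areas ~11–27 cm²) attached at fractions 0.25–0.97 of stem height at
  golden-angle azimuths, pitched 25–50° upward, each joined to the stem by a
  3 mm petiole stub so the stem–leaf junction ambiguity of real plants is
  present;
- Gaussian sensor noise along surface normals (default σ = 1 mm) and a fixed
  number of far outliers uniform in a 3× bounding box (default 200),
  mimicking time-of-flight artefacts;
- sampling density 2×10⁶ points/m² (≈3–4×10⁴ points per plant).

The topmost leaf attaches near the stem apex (0.97 of stem height), matching
vegetative seedlings whose apex bears the youngest leaf; this also means the
root-to-highest-bifurcation path that the pipeline measures is within ~3 % of
the full axis arc length recorded as ground truth.

What the generator does **not** emulate: occlusion and view-dependent
sampling holes, registration misalignment between views, leaf curling or
folding, double-sided leaf sampling (each synthetic leaf is a single
surface — hence mesh areas are *not* halved by default; clouds that sample
both faces should set `double_sided`), pot/soil geometry, and color. Passing
tests therefore demonstrate the correctness and noise-robustness of the
algorithms under clean acquisition geometry, not robustness to occlusion or
registration error.

## Skeletonization

Parent cubes of edge L are split into eight half-edge sub-cubes; sub-cubes
with point count m_j > θ (strict) are retained, and each parent cube emits
C_w = Σ m_j C_j / Σ m_j — algebraically the mean of the union of its retained
points, which the tests exploit as an oracle. The grid is anchored at the
cloud minimum corner, making the operator translation-equivariant.

Defaults L₀ = 0.01 m, θ = 6. The iteration doubles L each pass, but a pass
that would discard more than half of the remaining points (or leave < 2)
aborts the loop and the previous set is returned. This guard matters: after
one pass there is at most one centroid per parent cube, so a count-based θ
annihilates later passes, and the handful of cells that accidentally retain
2–5 points would otherwise *become* the skeleton. On 1 cm cubes a thin stem's
centroids track the axis to ~1 mm; coarser skeletons mix stem and leaf points
inside one cube and displace centroids by centimetres, which is also why stem
segmentation accuracy is sharply resolution-sensitive.

## Stem extraction

- **MST**: Kruskal with union-find on the complete Euclidean graph
  (skeletons are ≤ a few thousand points); ties broken by lexicographic node
  order for determinism; a connectivity-checked k-NN candidate graph is
  available for large inputs. Node classes are purely degree-based.
- **Principal line**: leading covariance eigenvector, sign-aligned to +Y.
  Leaf mass tilts this raw direction by a few degrees — enough to push the
  stem base out of the 2 cm junction band — so the pipeline refits the line
  on near-line points (trimmed PCA, coarse-to-fine: 1.5× then 1× the band,
  two passes each).
- **Stem top**: fine skeletons of leaf sheets contain many degree-3 nodes, so
  the single highest near-line junction can sit *inside* an apical leaf.
  Candidates are therefore tried from the top down and accepted only if the
  whole root-to-candidate tree path stays within 1.5× the band; the plain
  highest-junction rule is the fallback. The root is the lowest node within
  1.5× the band.
- **Curve**: a thin stem crosses several voxel columns per height slab,
  giving 2–4 parallel centroid chains; the raw tree path zigzags between
  them, inflating arc length ~20 %. Runs of consecutive path nodes within
  1.2·L₀ are averaged before fitting a natural cubic spline (chord-length
  parameterised, resampled at 1 mm arc steps). The curve is extended straight
  down to the cloud's minimum Y because the measured stem starts at the soil
  line, half a voxel below the lowest skeleton point.
- **Labeling**: a point is stem iff its exact distance to the nearest curve
  *segment* (KD-tree candidate pruning, segment-distance confirmation) is
  within the label radius. Default radius = the measured stem diameter: half
  covers the stem surface itself, half is margin for sensor noise (±3σ at
  σ = 1 mm on a 2.5 mm radius) and residual curve error. Leaf clusters whose
  points mostly lie within 2.5× this radius of the curve are folded back into
  the stem afterwards — residual stem shells are the classic contaminant of
  the leaf cloud.

## Leaf segmentation

- **Voxel features**: normals and curvature per 8 mm voxel come from the raw
  points of the voxel *and* its 26 neighbours (~2.4 cm support, O(10³)
  points). A single voxel can hold only a sliver of a blade whose in-plane
  spread is below the noise σ, and fits through a handful of voxel centroids
  carry ~15° errors; the pooled fit brings the median adjacent-normal angle
  to ~0.6°, which the convexity analysis requires. Normal signs are made
  consistent by BFS flip-propagation over the voxel adjacency graph (majority
  -voted per component against the away-from-centroid heuristic): a pointwise
  orientation rule leaves sign seams across blades that read as deep
  concavities.
- **Supervoxels**: seeds on a 10 mm grid (culled when fewer than 3 occupied
  neighbour voxels), grown by Dijkstra-style flow through 26-connected voxels
  minimising D = w_c·D_c²/c_max² + w_s·D_s²/(3R_seed²) + w_n·D_n², with D_n
  the histogram-intersection distance between 33-bin FPFH descriptors and
  c_max the neighbourhood curvature maximum. Up to 10 refinement rounds;
  unreachable voxel components become their own supervoxels so the result is
  always a partition.
- **Convexity merging**: an adjacency edge is convex iff
  (n_i − n_j)·d̂ ≥ −sin(β_th) with β_th = 20°, gated by a smoothness rule
  (normal angle < θ_th = 0.1 rad ⇒ always convex) and a sanity criterion
  that cuts geometrically singular configurations (normal cross-product
  within 30° of the connecting line). Two additions proved necessary:
  merges also require actual surface contact (minimum point distance ≤ 4 mm)
  because 26-connectivity of 8 mm voxels bridges ~14 mm air gaps between
  stacked near-parallel blades that the smoothness gate would merge; and
  clusters of ≤ 100 points are dropped as noise.
- **Adaptive K**: with coarse cluster sizes S_i and mean μ̄, clusters with
  S_e > μ̄ get K = ⌊S_e/μ̄⌋ and are split by K-means++ (D² seeding with a
  0.2 cm minimum centre separation, Lloyd iterations to a 0.1 cm tolerance,
  100 iterations max) when K ≥ 2. μ̄ is fixed from the coarse pass, not
  recomputed between splits. Note the rule's floor means a merged pair is
  only split when it exceeds *twice* the post-merge mean — adhering leaves
  of below-average size stay merged, a known limit of the rule.

## Traits

- Height = Y_max − Y_min of the denoised cloud. With σ = 1 mm noise the
  extremes add ~+2 mm per end (≈0.5–1 % on a 30–50 cm plant).
- Stem length = polyline arc length of the stem curve (root extension
  included, top at the highest bifurcation).
- Diameter: slices are perpendicular to the stem cloud's PCA axis (identical
  to world-Y slicing for upright plants, correct for leaning ones), 2 mm
  thick, at 5/6/7/8 cm above the base; each slice's in-plane projection is
  fitted with a direct least-squares conic constrained to an ellipse
  (scaled/centred for conditioning) and the diameter is 2× the mean minor
  semi-axis — a circular stem of radius r has minor semi-axis r. The
  unscaled mean minor semi-axis is available via `literal_minor_axis`.
  Slices with < 6 points are skipped with a warning.
- Leaf area: each leaf cloud is MLS-smoothed (each point projected to the
  best-fit plane of its k = 120 neighbours — raw σ = 1 mm roughness at
  0.35 mm point spacing inflates summed triangle area ~4×, and a
  convergence study on the generator shows k = 120 leaves ~+2 % bias),
  projected to its PCA plane, Delaunay-triangulated, and triangles with any
  edge beyond min(6 × median NN spacing, 1 cm) are removed, deliberately
  opening holes at sparse spots. Boundary rings (edges with exactly one
  incident triangle, walked into loops; longest ring = leaf outline) are
  then filled by minimum-interior-angle point linking, with a centroid fan
  as the degenerate-ring fallback, and triangle areas are summed. The
  pruning factor 6 reflects that Poisson-sampled surfaces have Delaunay
  edges several times the median NN spacing; factor 3 shreds ~40 % of a
  uniformly sampled disk.

## Numerical and degenerate-input conventions

Strict inequality m_j > θ; half-open voxel membership [lo, hi); MST ties by
node index; spline boundary condition natural; duplicate path points
deduplicated with a warning; empty SOR/crop results are warnings, not errors;
ellipse fits require ≥ 6 non-degenerate points; K-means++ relaxes the centre
separation by halves (with a warning) if 50 seeding attempts fail; isolated
FPFH points get zero histograms.

SOR is applied once. Re-applying it with recomputed statistics is *not* a
no-op: after the far outliers are gone the threshold μ + 1.1σ lands inside
the surface distribution's right tail and a second pass would remove ~10 % of
valid surface points (re-applying the first pass's fixed threshold removes
≤ 1 %).

## Validation protocol and problem sizes

The test suite checks each primitive against an independent oracle
(brute-force mean-kNN for SOR, floor-division re-binning and union-mean
identities for the skeleton, Prüfer-enumeration and an independent Prim for
the MST, DFS paths for Dijkstra, analytic shapes for splines, ellipses and
areas) and the whole pipeline against the generator's analytic truth on a
population of 20 seeded plants (heights 30–50 cm, 5–10 leaves, σ = 1 mm,
200 outliers — ~3×10⁴ points each), reporting mean absolute trait errors,
point-level stem F1 and mutual-majority leaf-instance precision/recall.
`scripts/acceptance.py` recomputes all of it in about a minute.

## Known limitations

- Leaves that physically overlap or interpenetrate can still merge (convex
  contact) or split a blade (concave crossing); the adaptive-K rule cannot
  split merged pairs below twice the mean size.
- The root and junction logic assumes a single dominant erect stem; rosette
  or multi-stem plants are out of scope.
- Stem diameter inherits a small positive bias from radial noise
  (√(r² + σ²) ≈ +8 % at r = 2.5 mm, σ = 1 mm before ellipse averaging).
- The 2 cm junction band and its 1.5× path-confinement margin are absolute
  lengths; unusually large or tiny plants may need them rescaled.
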