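"""Skeletonize a plant and trace its main stem.

Shows the intermediate objects of stem extraction: SOR filtering, the
density-weighted voxel-centroid skeleton, the minimum spanning tree with its
node classes, and the spline-smoothed stem curve.
"""

import warnings

import numpy as np

from skelphen import (
    SyntheticPlantSpec,
    build_mst,
    classify_nodes,
    generate_plant,
    principal_direction,
    refine_principal_line,
    root_node,
    select_highest_junction,
    skeletonize_iterative,
    smooth_curve,
    sor_filter,
    tree_path,
)

warnings.filterwarnings("ignore")

cloud, truth = generate_plant(SyntheticPlantSpec(seed=1))
filtered, removed = sor_filter(cloud)
print(f"SOR removed {len(removed)} of {len(cloud)} points "
      "(the time-of-flight-like outliers)")

skeleton = skeletonize_iterative(filtered)
print(f"skeleton: {len(skeleton)} points after iteration {skeleton.iteration_index}")

graph = build_mst(skeleton.points)
classes = classify_nodes(graph)
counts = {c: sum(v == c for v in classes.values()) for c in ("TIP", "INTERNAL", "JUNCTION")}
print(f"MST node classes: {counts}")

line = principal_direction(skeleton.points)
line = refine_principal_line(skeleton.points, line, radius=0.03)
top = select_highest_junction(graph, line)
root = root_node(graph, line)
path = tree_path(graph, root, top)
print(f"raw stem path: {len(path)} skeleton nodes from the root "
      f"(y={skeleton.points[root, 1]:.3f} m) to the highest near-line junction "
      f"(y={skeleton.points[top, 1]:.3f} m)")

# the full pipeline additionally confines the path to the near-line band,
# collapses parallel voxel chains, and splines the result into the stem curve
from skelphen import PipelineConfig, run_pipeline

res = run_pipeline(cloud, PipelineConfig(
    measured_stem_diameter=truth.true_stem_diameter, seed=1))
print(f"conditioned stem curve length: {res.stem_curve.length * 100:.2f} cm "
      f"(true stem length {truth.true_stem_length * 100:.2f} cm)")
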