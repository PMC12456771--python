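"""Run the full pipeline on a synthetic seedling and score it.

Generates a plant, runs preprocess → skeleton → stem → leaf segmentation →
traits, and compares every recovered trait to the generator's analytic truth.
"""

import warnings

from skelphen import (
    PipelineConfig,
    SyntheticPlantSpec,
    generate_plant,
    instance_precision_recall,
    run_pipeline,
    stem_f1,
    trait_errors,
)

warnings.filterwarnings("ignore")

spec = SyntheticPlantSpec(seed=1)
cloud, truth = generate_plant(spec)

# the stem-point search radius follows the manually measured stem diameter
cfg = PipelineConfig(measured_stem_diameter=truth.true_stem_diameter, seed=1)
res = run_pipeline(cloud, cfg)

r = res.report
print(f"plant height:  {r.height * 100:6.2f} cm  (true {truth.true_height * 100:.2f})")
print(f"stem length:   {r.stem_length * 100:6.2f} cm  "
      f"(true {truth.true_stem_length * 100:.2f})")
print(f"stem diameter: {r.stem_diameter * 1000:6.2f} mm  "
      f"(true {truth.true_stem_diameter * 1000:.2f})")
print(f"leaf instances: {len(r.leaf_areas)} (true {spec.n_leaves})")

true_labels = truth.per_point_label[res.kept_indices]
errs = trait_errors(r, truth, res.leaf_labels, true_labels)
precision, recall = instance_precision_recall(res.leaf_labels, true_labels)
print(f"stem point F1: {stem_f1(res.stem_mask, true_labels):.3f}")
print(f"leaf instance precision/recall: {precision:.2f} / {recall:.2f}")
print(f"mean |leaf area error|: {errs['leaf_area_mean_abs_rel_err'] * 100:.1f} %")
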