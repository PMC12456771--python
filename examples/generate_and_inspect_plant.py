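"""Generate a synthetic seedling and inspect its ground truth.

Builds one labeled plant cloud (stem + leaves + noise + outliers) and prints
the analytic trait values the rest of the pipeline will try to recover.
"""

import numpy as np

from skelphen import SyntheticPlantSpec, generate_plant

spec = SyntheticPlantSpec(seed=1)
cloud, truth = generate_plant(spec)

labels = truth.per_point_label
print(f"points: {len(cloud)}  (stem {np.sum(labels == 0)}, "
      f"leaves {np.sum(labels > 0)}, outliers {np.sum(labels == -1)})")
print(f"true plant height:   {truth.true_height * 100:.2f} cm")
print(f"true stem length:    {truth.true_stem_length * 100:.2f} cm  "
      "(arc length of the bowed axis, slightly above the height)")
print(f"true stem diameter:  {truth.true_stem_diameter * 1000:.2f} mm")
print("true leaf areas (cm^2):",
      ", ".join(f"{a * 1e4:.1f}" for a in truth.true_leaf_areas))
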