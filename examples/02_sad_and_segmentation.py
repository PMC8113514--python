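"""SAD imaging plus step 1: segment vessel structures from a phantom.

The SAD image is bright exactly where RBC flow flickers the intensity;
CLAHE normalizes its range, and the Steger ridge detector extracts the
curvilinear structures. Recall is measured against the phantom's true
flowing-vessel skeleton.
"""

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

import microflow as mf

config = mf.GeneratorConfig()
vessels = mf.sample_vessel_tree(config, seed=7)
stack, truth = mf.render_video(vessels, 220, config, seed=8)

sad = mf.compute_sad(stack)
print(f"SAD image from {sad.n_frames_used} frames; "
      f"mean inside flowing tubes {sad.values[truth.flow_mask].mean():.0f}, "
      f"outside {sad.values[~truth.flow_mask].mean():.0f} (16-bit scale)")

enhanced = mf.enhance_clahe(sad)
vessel_map = mf.segmentation.segment(enhanced)
print(f"segmentation: {vessel_map.n_components} components, "
      f"{int(vessel_map.mask.sum())} mask pixels")

skeleton = skeletonize(truth.flow_mask)
dist = ndimage.distance_transform_edt(~vessel_map.mask)
recall = (dist[skeleton] <= 2).mean()
print(f"centerline recall (true flowing skeleton within 2 px of mask): {recall:.3f}")
print("non-flowing vessels do not flicker, so step 1 sees only perfused structure")
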