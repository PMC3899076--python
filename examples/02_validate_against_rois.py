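"""Validate a classified map against labeled reference polygons (ROIs).

Also reloads the packaged Southeast-Asia 2009 validation matrix and prints
the published producer's/user's accuracies it reproduces.
"""

from sarforest import (
    GridTransform,
    build_stack,
    classify_scene,
    confusion_matrix,
    generate_class_mosaic,
    generate_rois,
    generate_scene,
    load_validation_confusion,
    overall_accuracy,
    rasterize_rois,
)
from sarforest.synthetic import LandscapeSpec

# self-validation of a synthetic scene
grid = generate_class_mosaic(LandscapeSpec(shape=(150, 150), seed=13))
scene, _ = generate_scene(grid, seed=17, sd=0.3)
lc = classify_scene(build_stack(scene))
rois = generate_rois(grid, n_per_class=5, seed=19)
ref = rasterize_rois(rois, grid.shape, GridTransform())
cm = confusion_matrix(lc.classes, ref)
print("synthetic self-validation")
print(cm.to_frame())
print(f"overall accuracy: {overall_accuracy(cm):.2f}%  "
      "(diagonal share of ROI pixels; near-100% because the synthetic "
      "classes sit at the threshold-box centers)\n")

# the published continental validation counts
cm_pub = load_validation_confusion()
print("published Southeast-Asia 2009 validation (pixel counts)")
print(cm_pub.summary().round(1).to_string(index=False))
print(f"overall accuracy: {overall_accuracy(cm_pub):.1f}%  "
      "(producer's accuracy = 1 - omission, user's = 1 - commission)")
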