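"""Train the symmetry-aware 3D U-Net on a tiny phantom cohort and evaluate
held-out subjects with sliding-window inference.

Takes a couple of minutes on one CPU core.  Dice near 1 and ASD near 0 mean
the predicted label maps closely match the planted structures.
"""

import logging

from neurocube.phantom import PhantomSpec, generate_cohort
from neurocube.pipeline import RunConfig, run_segmentation_stage
from neurocube.segnet import SegNetConfig

logging.basicConfig(level=logging.INFO, format="%(message)s")

manifest = generate_cohort(PhantomSpec(grid_edge=64, seed=1), 8,
                           "scratch/example_seg")
cfg = RunConfig(
    manifest=manifest, merge_mode="symmetric_5",
    crop_edge=64, patch_edge=32, batch_size=2,
    iterations_per_epoch=100, epochs=3, lr=1e-2, seed=0,
    segnet=SegNetConfig(n_classes=6, stem_channels=4,
                        channel_schedule=(8, 16, 24, 32), expansion=2, seed=0),
)
model, metrics = run_segmentation_stage(cfg)

print(f"\nheld-out mean Dice: {metrics['mean_dice']:.3f}")
print(f"held-out directed ASD: {metrics['mean_asd_mm']:.3f} voxels")
for cls, d in metrics["per_class_dice"].items():
    print(f"  class {cls}: Dice {d:.3f}")
# Class indices: 1 frontal gyrus, 2 hippocampus, 3 amygdala,
# 4 caudate nucleus, 5 thalamus.
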