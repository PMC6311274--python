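"""Generate a pathological vessel phantom and inspect its ground truth.

Builds a 48x48x48 CT-like volume (0.7 mm voxels) holding a curved vessel
with a 50% stenosis and a calcified arc pressed against the wall, then
prints the tissue composition and writes volume/labels/axis to disk.
"""

import numpy as np

from mhmmseg import PhantomConfig, PlaqueArc, generate_phantom
from mhmmseg.phantoms import write_phantom

config = PhantomConfig(
    axis_spec="helical",
    helix_radius_mm=1.5,
    helix_turns=0.4,
    radius_profile_mm=[(0.0, 2.0), (0.45, 2.0), (0.5, 1.0), (0.55, 2.0), (1.0, 2.0)],
    plaque_spec=[PlaqueArc(arc_frac=(0.2, 0.5), angle_deg=(0, 120), thickness_mm=1.2)],
    noise_variance=40.0,
    seed=7,
)
phantom = generate_phantom(config)

names = ["background/adventitia", "lumen", "intima (wall)", "pathology (calcification)"]
counts = np.bincount(phantom.labels.data.ravel(), minlength=4)
for name, n in zip(names, counts):
    print(f"{name:28s} {n:7d} voxels")
print(f"axis points: {len(phantom.axes[0])}, "
      f"intensity range: [{phantom.volume.data.min():.0f}, "
      f"{phantom.volume.data.max():.0f}]")

write_phantom(phantom, "scratch/example_phantom", stem="example")
print("written to scratch/example_phantom/ "
      "(NIfTI volume + labels, JSON axis, YAML config)")

# The lumen is the bright blood-filled channel the segmentation must recover;
# the calcified arc (hyperdense, ~1100) presses against the thin wall and is
# exactly the structure that confuses intensity-only segmentation.
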