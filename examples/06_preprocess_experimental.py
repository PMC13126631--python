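"""Prepare a raw experimental-style height map for the classifier.

Synthesises a lattice-with-holes scene, estimates the stage level
outside holes and molecule, fills the holes, levels the image, centres
the molecule and standardises the frame to 36 x 36 pixels.
"""

import numpy as np

from afmstate.preprocess import auto_masks, estimate_stage, preprocess_image
from afmstate.simulate import HeightImage, ImageGrid

rng = np.random.default_rng(0)
v = 1.0 + rng.normal(0, 0.03, size=(48, 48))   # lattice around 1 nm
v[6:10, 8:12] = 0.05                           # a hole in the lattice
v[28:36, 30:38] = 5.0                          # molecule, off centre

img = HeightImage(v, ImageGrid.centered(nx=48, ny=48))
hole, mol = auto_masks(img)
stage = estimate_stage(img, hole, mol)
ready = preprocess_image(img, hole, mol, target=36)

print(f"estimated stage level : {stage:.3f} nm (true 1.0)")
print(f"output frame          : {ready.values.shape}")
peak = np.unravel_index(np.argmax(ready.values), ready.values.shape)
print(f"molecule peak now at  : {peak} (centre is (18, 18))")
print(f"frame mean            : {ready.values.mean():+.4f} nm")
# After preprocessing the stage sits near 0 nm, the molecule is centred,
# and the frame matches the 36 x 36 input the trained network expects.
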