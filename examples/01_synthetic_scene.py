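"""Generate one synthetic underwater scene and inspect its optical structure.

The generator renders a lamp beam (flat core, bright lamp-axis hot spot,
exponential edge halo) over a hazy blue-green background, with a planted
object inside the beam and full ground-truth masks.
"""

import numpy as np

from lampseg import SceneSpec, generate_scene

bundle = generate_scene(SceneSpec(seed=0))
img = bundle.image.pixels
lit = bundle.lit_mask.values.astype(bool)

print(f"scene size: {bundle.image.shape}, object pixels: {bundle.object_mask.count()}")
print(f"mean intensity inside the beam:  {img[lit].mean():.3f}")
print(f"mean intensity outside the beam: {img[~lit].mean():.3f}")
print(f"mean red inside the beam:  {img[..., 0][lit].mean():.3f}")
print(f"mean red outside the beam: {img[..., 0][~lit].mean():.3f}")
# The beam region is brighter and markedly red-enhanced: water attenuates
# red fastest, so only artificial light restores it locally.
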