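"""From a SMILES string to the 1200-D topological feature vector.

Renders benzene with the built-in skeletal renderer (RDKit is used instead
when installed), computes per-channel persistence diagrams, and assembles
the concatenated Betti-curve + landscape feature vector.  The aromatic ring
shows up as a single long-lived loop in every channel.
"""

import numpy as np

from topolink import render_molecule
from topolink.vectorize import image_vector

img = render_molecule("c1ccccc1", size=128, backend="synthetic")
vector, diagrams = image_vector(img, return_diagrams=True)

print(f"rendered image: {img.shape[0]}x{img.shape[1]} RGB")
print(f"feature vector length: {vector.size} "
      "(4 channels x (50+50 Betti + 100+100 landscape))")

h1 = diagrams["gray"].pairs(1)
persistent = h1[(h1[:, 1] - h1[:, 0]) > 128]
print(f"long-lived H1 bars in the gray channel: {len(persistent)}")
for b, d in persistent:
    print(f"  loop born at {b:.1f}, filled at {d:.1f} "
          "(the benzene ring encloses a light region until the top threshold)")

blocks = vector.reshape(4, 300)
print("\nper-channel block L2 norms (gray, red, green, blue):",
      np.round(np.linalg.norm(blocks, axis=1), 1))
print("identical channels for a black-on-white drawing, as expected.")
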