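"""The sigmoid fusion gate mixing sequence and topological embeddings.

Projects a mock 768-D drug embedding and a topological vector into the
shared 512-D latent space, then fuses them with a gate.  A zero-initialized
gate gives alpha = 0.5 everywhere (the static-fusion baseline); a biased
gate shifts weight toward the sequence modality.
"""

import numpy as np

from topolink import FusionGate, ProjectionHead, fuse, mock_embeddings, project
from topolink.fusion import fuse_variant
from topolink.synthetic import TopoImageSpec, gen_topo_image
from topolink.vectorize import image_vector

emb = mock_embeddings(["aspirin"], "drug", seed=7)["aspirin"]
rgb, _ = gen_topo_image(TopoImageSpec(n_rings=2, size=64, seed=7))
topo = image_vector(rgb)

f_llm = project(emb, ProjectionHead.initialize(len(emb), seed=1))
f_tda = project(topo, ProjectionHead.initialize(len(topo), seed=2))
print(f"projected widths: sequence {f_llm.size}, topology {f_tda.size}")

alpha, fused = fuse(f_llm, f_tda, FusionGate.zeros(512))
print(f"zero gate: mean alpha = {alpha.mean():.3f} "
      f"(equals static fusion: {np.allclose(fused, (f_llm + f_tda) / 2)})")

biased = FusionGate(np.zeros((512, 1024)), np.full(512, np.log(3.0)))
alpha, fused = fuse(f_llm, f_tda, biased)
print(f"bias ln(3): mean alpha = {alpha.mean():.3f} "
      "(75% weight on the sequence modality)")

inside = np.all((fused >= np.minimum(f_llm, f_tda) - 1e-12)
                & (fused <= np.maximum(f_llm, f_tda) + 1e-12))
print(f"fused coordinates lie between the two sources: {inside}")

for mode in ("static_half", "top_only", "llm_only"):
    out = fuse_variant(f_llm, f_tda, mode)
    print(f"variant {mode:12s}: ||f|| = {np.linalg.norm(out):.2f}")
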