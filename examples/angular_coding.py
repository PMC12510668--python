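"""Angular latent codes: positions on circles, grid modules, decoding.

Builds single- and multi-module codes for a handful of positions and shows
that decoding inverts encoding exactly.
"""

import numpy as np

from placeremap import coding

p = np.array([[-1.0], [-0.5], [0.0], [0.25], [0.5]])

z = coding.encode_angles(p)
print("single-module code (columns = positions):")
print(np.round(z, 3))
print("decoded:", np.round(coding.decode_angles(z)[:, 0], 6))
# each position maps to a point on the unit circle; decode returns it exactly

f = coding.default_frequency_exponents(3)
zg = coding.encode_grid(p, f)
print(f"\nthree grid modules, frequency exponents {f.tolist()}")
print("(scale factors 1, 3/2, 2/3 on the angle):")
print(np.round(zg, 3))
print("decoded from module 1 only:", np.round(coding.decode_grid(zg, m=3)[:, 0], 6))

zn = coding.normalize_blocks(coding.encode_angles(np.array([0.3, -0.2])), zp_dim=2)
print("\nblock-normalized (position, cognitive) latent:", np.round(zn, 4))
print("block norms:", np.round([np.linalg.norm(zn[:2]), np.linalg.norm(zn[2:])], 4))
# each block is scaled to 1/sqrt(2) so the full latent vector has unit norm
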