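"""Winner-take-all tuning mosaics in angle space.

Colors a mesh over two environmental variables by the most excited neuron
(feedforward approximation) and writes a PNG; also demonstrates the gnomonic
sphere embedding used for multi-chart visualizations.
"""

from pathlib import Path

import numpy as np

from placeremap import coding, viz
from placeremap.network import build_network

rng = np.random.default_rng(0)
net = build_network(Y=4, N=24, code="C", rng=rng)

mosaic = viz.argmax_mosaic(coding.encode_angles, net.D, mesh=200)
n_winners = mosaic.distinct_winners().size
print(f"mosaic 200x200 over [-1,1]^2: {n_winners}/24 neurons win somewhere")

out = Path("scratch")
out.mkdir(exist_ok=True)
viz.plot_mosaic(mosaic, n_neurons=24, path=out / "mosaic.png",
                title="conjunctive-code tuning mosaic")
print(f"wrote {out/'mosaic.png'}")

pts = viz.gnomonic_embed(np.array([0.0, 1.0, -2.0]), np.array([0.0, 0.0, 1.5]))
print("gnomonic projections (always unit vectors):")
print(np.round(pts, 4), "norms", np.round(np.linalg.norm(pts, axis=-1), 12))
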