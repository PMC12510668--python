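"""Steady-state rates of the autoencoder network for one input.

Solves r* = argmin_{r>=0} ||y - D r||^2 + 2 T'r for a small random network
and verifies the KKT optimality certificate by hand.
"""

import numpy as np

from placeremap.network import build_network, solve_rates

rng = np.random.default_rng(0)
net = build_network(Y=4, N=32, code="M", rng=rng)

y = rng.standard_normal(4)
y *= 4.0 / np.linalg.norm(y)  # unit direction scaled like a Y=4 embedding

r = solve_rates(y, net.D, net.T)
active = np.flatnonzero(r > 0)
print(f"input ||y|| = {np.linalg.norm(y):.2f}; {active.size}/32 neurons active")
print("active neurons:", active.tolist())
print("rates:", np.round(r[active], 4))

y_hat = net.D @ r
print(f"decoded estimate error ||y_hat - y||/||y|| = "
      f"{np.linalg.norm(y_hat - y)/np.linalg.norm(y):.4f}")

g = 2 * (net.D.T @ (net.D @ r - y)) + 2 * net.T
print(f"KKT: min gradient = {g.min():.2e} (>= 0 up to tolerance), "
      f"max complementarity r*g = {np.max(r*g):.2e} (~ 0)")
# the certificate proves r is the global optimum of the convex program
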