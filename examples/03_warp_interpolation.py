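"""Interpolate per-node affine transforms to arbitrary points.

The embedded-deformation warp blends the M nearest nodes' transforms with
radially decaying weights; the farthest of the M neighbours gets weight
exactly zero, and the weights always sum to one.
"""

import numpy as np

from swayrecon.warpfield import WarpField

nodes = np.array([[1.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
field = WarpField(nodes, np.tile(np.eye(3), (3, 1, 1)), np.zeros((3, 3)),
                  m_nearest=3)
idx, w = field.node_weights([0.0, 0.0, 0.0])
print("query at origin, nodes at distance (1, 2, 4):")
print(f"  weights {np.round(w, 4)} (= (0.5625, 0.25, 0)/0.8125), sum {w.sum():.12f}")

# a constant rigid field reproduces the rigid map at every point
theta = np.radians(30)
R = np.array([[np.cos(theta), -np.sin(theta), 0],
              [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
t = np.array([0.05, -0.02, 0.01])
rng = np.random.default_rng(0)
g = rng.uniform(-1, 1, (15, 3))
rigid = WarpField(g, np.tile(R, (15, 1, 1)), g @ R.T + t - g, m_nearest=4)
pts = rng.uniform(-1, 1, (5, 3))
err = np.abs(rigid.warp(pts) - (pts @ R.T + t)).max()
print(f"constant rigid field: max deviation from R v + t = {err:.2e} m")
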