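"""Poiseuille blood flow on a branched vessel network.

Builds a vessel that splits into two parallel daughter branches of
different radii, solves the node pressures by successive displacement
(SOR) and prints the flow split - conductance scales with R^4, so the
wider branch carries most of the flow, and Kirchhoff balance holds at
every junction.
"""

import numpy as np

from angiomet.config import VascularConfig
from angiomet.lattice import Lattice
from angiomet.vasculature import (VascularNetwork, compute_blood_flow,
                                  kirchhoff_imbalance)

lattice = Lattice((11, 7, 3), 20.0)
params = VascularConfig()
net = VascularNetwork(lattice)
src = net.add_node((0, 3, 1))
fork = net.add_node((3, 3, 1))
for i in range(1, 4):
    net.add_segment(net.add_node((i - 1, 3, 1)), net.add_node((i, 3, 1)), 6.0)
join = net.add_node((8, 3, 1))
for y, radius in ((1, 6.0), (5, 4.0)):      # wide and narrow branches
    prev = fork
    for i in range(4, 8):
        nxt = net.add_node((i, y, 1))
        net.add_segment(prev, nxt, radius)
        prev = nxt
    net.add_segment(prev, join, radius)
dst = net.add_node((10, 3, 1))
net.add_segment(join, net.add_node((9, 3, 1)), 6.0)
net.add_segment(net.add_node((9, 3, 1)), dst, 6.0)
net.set_boundary(src, 4000.0)
net.set_boundary(dst, 2000.0)

compute_blood_flow(net, params)
q_wide = next(net.flow[i] for i in range(net.n_segments)
              if net.node_pos[net.seg_b[i]][1] == 1)
q_narrow = next(net.flow[i] for i in range(net.n_segments)
                if net.node_pos[net.seg_b[i]][1] == 5)
print(f"trunk flow:  {net.flow[0]:.3e} um^3/h")
print(f"wide branch (R=6 um):   {q_wide:.3e} um^3/h")
print(f"narrow branch (R=4 um): {q_narrow:.3e} um^3/h")
print(f"flow ratio {abs(q_wide / q_narrow):.2f} (R^4 ratio would be "
      f"{(6 / 4) ** 4:.2f} for equal path lengths)")
print(f"Kirchhoff imbalance: {kirchhoff_imbalance(net, params):.2e} "
      "(relative to throughput)")
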