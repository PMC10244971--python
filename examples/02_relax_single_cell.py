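"""Relax a single cell to its mechanical equilibrium.

A cell is a closed ring of wall nodes with interior cytoplasm nodes.
Turgor (soft-core Morse repulsion between wall and cytoplasm) inflates
the ring against extensibility springs and microfibril bending; the
overdamped dynamics descend the total potential energy.
"""

import numpy as np

from samsce import MechanicalState, PotentialParams, aspect_ratio
from samsce.tissue import CYTOPLASM, WALL, Cell, Node, build_tissue

nodes = {}
ring = []
for k in range(16):
    a = 2 * np.pi * k / 16
    nodes[k] = Node(np.array([3 * np.cos(a), 3 * np.sin(a)]), WALL, 0, ring_index=k)
    ring.append(k)
for j in range(6):
    a = 2 * np.pi * j / 6
    nodes[16 + j] = Node(np.array([1.2 * np.cos(a), 1.2 * np.sin(a)]), CYTOPLASM, 0)
cell = Cell(id=0, wall_ring=ring, cytoplasm=set(range(16, 22)))
tissue = build_tissue([cell], nodes)

state = MechanicalState(tissue, PotentialParams())
print(f"initial energy {state.energy():8.3f} uN*um")
state.integrate(dt=0.4, n_steps=2000)  # overdamped descent, 0.4 s steps
residual = state.relax(tol=1e-6)  # finish at the exact equilibrium
state.sync_to_tissue()
diameter = 2 * np.sqrt(tissue.cell_area(0) / np.pi)
print(f"relaxed energy {state.energy():8.3f} uN*um, residual force {residual:.2e} uN")
print(f"equilibrium cell: diameter {diameter:.2f} um, aspect ratio "
      f"{aspect_ratio(cell, tissue):.3f}")
# The cell settles to a round shape ~6 um across: forces balance between
# turgor pushing the wall out and the wall springs holding it together.
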