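"""Out-of-plane growth polarization by functional zone (pseudo-3D model).

In the P3D variant, each cell stochastically polarizes its growth out of
the section plane with a measured zone/layer-specific frequency; this
example recovers the configured table empirically by repeated sampling.
"""

import numpy as np

from samsce import GrowthParams, sample_polarization
from samsce.growth import DEFAULT_PERICLINAL_TABLE
from samsce.tissue import WALL, Cell, Node, build_tissue

gp = GrowthParams()
rng = np.random.default_rng(0)
n = 20_000

print(f"{'zone':<12} {'layer group':<15} {'table %':>8} {'sampled %':>10}")
for (zone, group), p in DEFAULT_PERICLINAL_TABLE.items():
    layer = {"tunica": "L1", "apical_corpus": "apical_corpus", "basal_corpus": "basal_corpus"}[group]
    nodes = {
        k: Node(np.array([np.cos(a), np.sin(a)]), WALL, 0, ring_index=k)
        for k, a in enumerate(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    }
    cell = Cell(id=0, wall_ring=list(range(8)), cytoplasm=set(), layer=layer, zone=zone)
    build_tissue([cell], nodes)
    hits = sum(sample_polarization(cell, rng, gp, variant="p3d") == "out_of_plane" for _ in range(n))
    print(f"{zone:<12} {group:<15} {100 * p:8.1f} {100 * hits / n:10.2f}")
# Sampled frequencies match the configured table to binomial accuracy;
# central-zone tunica cells are the most likely (47.4%) to grow out of
# the plane, central-zone basal corpus the least (10.5%).
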