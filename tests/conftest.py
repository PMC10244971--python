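import numpy as np
import pytest

from samsce import Cell, Node, PotentialParams, build_tissue
from samsce.tissue import CYTOPLASM, WALL


def square_cell_tissue(side=2.0, origin=(0.0, 0.0), layer="apical_corpus", cell_id=0):
    """One square cell: 4 wall nodes + 1 central cytoplasm node."""
    ox, oy = origin
    corners = [(ox, oy), (ox + side, oy), (ox + side, oy + side), (ox, oy + side)]
    nodes = {
        i: Node(np.array(c, dtype=float), WALL, cell_id, ring_index=i)
        for i, c in enumerate(corners)
    }
    nodes[4] = Node(np.array([ox + side / 2, oy + side / 2]), CYTOPLASM, cell_id)
    cell = Cell(id=cell_id, wall_ring=[0, 1, 2, 3], cytoplasm={4}, layer=layer)
    return build_tissue([cell], nodes)


def ring_cell(n_nodes, radius=3.0, centre=(0.0, 0.0), cell_id=0, n_cyt=4, layer="apical_corpus"):
    """A round cell: regular n-gon wall ring with cytoplasm nodes inside."""
    cx, cy = centre
    nodes = {}
    ring = []
    for k in range(n_nodes):
        a = 2 * np.pi * k / n_nodes
        nodes[k] = Node(
            np.array([cx + radius * np.cos(a), cy + radius * np.sin(a)]),
            WALL,
            cell_id,
            ring_index=k,
        )
        ring.append(k)
    cyt = set()
    for j in range(n_cyt):
        a = 2 * np.pi * j / max(n_cyt, 1)
        nid = n_nodes + j
        r = 0.0 if n_cyt == 1 else radius * 0.4
        nodes[nid] = Node(np.array([cx + r * np.cos(a), cy + r * np.sin(a)]), CYTOPLASM, cell_id)
        cyt.add(nid)
    cell = Cell(id=cell_id, wall_ring=ring, cytoplasm=cyt, layer=layer)
    return build_tissue([cell], nodes)


@pytest.fixture
def unit_square():
    return square_cell_tissue(side=1.0)


@pytest.fixture
def params():
    return PotentialParams()


@pytest.fixture(scope="session")
def small_tissue():
    """A small generated dome, shared read-only across tests."""
    from samsce import generate_initial_tissue
    from samsce.generate import GeneratorParams

    return generate_initial_tissue(seed=7, params=GeneratorParams(n_columns=6, relax_steps=300))
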