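"""Synthetic initial-tissue generator.

Builds a dome-shaped longitudinal section: single-cell L1 and L2
monolayers draped over an apical + basal corpus block, flanked on both
sides by a column of non-dividing boundary cells, with the bottom row
acting as the stiff interface to the differentiated tissue below (its
damping is raised tenfold by the mechanics).  Every cell is a closed
wall ring with interior cytoplasm nodes.  Deterministic given a seed.

This construction stands in for the initial conditions of the original
study, which are not reproduced here; it is validated by a relaxation
smoke test (the generated tissue relaxes without ring self-intersection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rng as rngmod
from .growth import GrowthParams, apply_polarization, relabel_zones, sample_polarization
from .signaling import SignalParams, assign_concentrations, place_signal_centres
from .boundary import identify_boundary_nodes
from .tissue import (
    CYTOPLASM,
    WALL,
    Cell,
    Node,
    PotentialParams,
    Tissue,
    build_tissue,
    refresh_adhesion,
)


@dataclass
class GeneratorParams:
    n_columns: int = 12  # interior columns (excluding boundary columns)
    corpus_rows: int = 2  # apical + basal corpus rows
    cell_size: float = 5.0  # µm, nominal cell width
    row_height: float = 5.0  # µm
    dome_height_fraction: float = 0.18  # dome rise as a fraction of tissue width
    wall_spacing: float = 1.2  # µm between wall nodes
    wall_gap: float = 0.2  # µm shrink so neighbouring walls abut, not overlap
    cytoplasm_per_cell: int = 6
    relax_steps: int = 500  # mechanics-only pre-relaxation of the raw geometry


def generate_initial_tissue(
    seed: int = 0,
    params: GeneratorParams | None = None,
    potential_params: PotentialParams | None = None,
    growth_params: GrowthParams | None = None,
    signal_params: SignalParams | None = None,
    variant: str = "p3d",
) -> Tissue:
    """Generate a labelled, adhered, signal-initialized dome section."""
    gp = params or GeneratorParams()
    pp = potential_params or PotentialParams()
    grow = growth_params or GrowthParams()
    sig = signal_params or SignalParams()
    if gp.n_columns < 5:
        raise ValueError("need at least 5 interior columns")
    n_rows = 2 + gp.corpus_rows
    if gp.row_height * n_rows < 2 * gp.cell_size:
        raise ValueError("geometry too small to fit the requested layers")

    ncol_total = gp.n_columns + 2  # plus one boundary column per side
    width = ncol_total * gp.cell_size
    xs = np.linspace(-width / 2.0, width / 2.0, ncol_total + 1)
    h0 = n_rows * gp.row_height
    dome = gp.dome_height_fraction * width

    def column_height(x):
        u = 2.0 * x / width
        return h0 + dome * max(1.0 - u * u, 0.0)

    base_y = 0.0
    fracs = np.linspace(0.0, 1.0, n_rows + 1)

    nodes: dict[int, Node] = {}
    cells: list[Cell] = []
    next_node = 0

    def add_node(node):
        nonlocal next_node
        nodes[next_node] = node
        next_node += 1
        return next_node - 1

    row_layers = ["basal_corpus"] * (gp.corpus_rows - gp.corpus_rows // 2) + [
        "apical_corpus"
    ] * (gp.corpus_rows // 2) + ["L2", "L1"]
    # rows are indexed bottom to top

    cell_id = 0
    for col in range(ncol_total):
        x0, x1 = xs[col], xs[col + 1]
        hl, hr = column_height(x0), column_height(x1)
        is_boundary_col = col == 0 or col == ncol_total - 1
        for row in range(n_rows):
            corners = np.array(
                [
                    [x0, base_y + fracs[row] * hl],
                    [x1, base_y + fracs[row] * hr],
                    [x1, base_y + fracs[row + 1] * hr],
                    [x0, base_y + fracs[row + 1] * hl],
                ]
            )
            centroid = corners.mean(axis=0)
            shrunk = centroid + (corners - centroid) * (
                1.0 - gp.wall_gap / gp.cell_size
            )
            ring_pts = _subdivide_ring(shrunk, gp.wall_spacing)
            layer = "boundary_cell" if is_boundary_col else row_layers[row]
            ring_ids = [add_node(Node(p, WALL, cell_id)) for p in ring_pts]
            r = rngmod.stream(seed, rngmod.INIT, cell_id)
            cyt_ids = set()
            half = (shrunk.max(axis=0) - shrunk.min(axis=0)) / 2.0 - 0.8
            for _ in range(gp.cytoplasm_per_cell):
                p = centroid + r.uniform(-1.0, 1.0, size=2) * np.maximum(half, 0.2)
                cyt_ids.add(add_node(Node(p, CYTOPLASM, cell_id)))
            cell = Cell(
                id=cell_id,
                wall_ring=ring_ids,
                cytoplasm=cyt_ids,
                layer=layer,
                zone="central",
                damping=pp.eta_base,
                target_area=grow.inplane_terminal_area,
                cycle_progress=float(r.uniform(0.0, 1.0)),
            )
            for k, nid in enumerate(ring_ids):
                nodes[nid].ring_index = k
            cells.append(cell)
            cell_id += 1

    tissue = build_tissue(cells, nodes, base_y=base_y)
    tissue.apex = _apex_of(tissue)
    if gp.relax_steps > 0:
        from .mechanics import MechanicalState

        refresh_adhesion(tissue, pp)
        state = MechanicalState(tissue, pp)
        state.integrate(0.4, gp.relax_steps)
        state.sync_to_tissue()
        tissue.time_hours = 0.0
    tissue.apex = _apex_of(tissue)
    relabel_zones(tissue, grow)
    place_signal_centres(tissue, params=sig)
    assign_concentrations(tissue, sig)
    for cell in tissue.cells.values():
        r = rngmod.stream(seed, rngmod.POLARIZATION, cell.id, cell.polarization_events)
        cell.polarization_events += 1
        cell.polarization = sample_polarization(cell, r, grow, variant=variant)
        apply_polarization(cell, tissue, pp, grow)
    refresh_adhesion(tissue, pp)
    identify_boundary_nodes(tissue)
    tissue.bump()
    return tissue


def _subdivide_ring(corners: np.ndarray, spacing: float) -> list[np.ndarray]:
    """Counter-clockwise ring of points along a convex quad, ~spacing apart."""
    from .tissue import signed_area

    if signed_area(corners) < 0:
        corners = corners[::-1]
    pts: list[np.ndarray] = []
    m = len(corners)
    for i in range(m):
        a, b = corners[i], corners[(i + 1) % m]
        length = np.linalg.norm(b - a)
        k = max(int(round(length / spacing)), 1)
        for t in np.arange(k) / k:
            pts.append(a + t * (b - a))
    return pts


def _apex_of(tissue: Tissue) -> np.ndarray:
    """Highest wall node of the epidermal layer (or of the tissue)."""
    best = None
    for cell in tissue.cells.values():
        if cell.layer not in ("L1", "boundary_cell"):
            continue
        for nid in cell.wall_ring:
            p = tissue.nodes[nid].position
            if best is None or p[1] > best[1]:
                best = p
    if best is None:
        best = max((n.position for n in tissue.nodes.values()), key=lambda p: p[1])
    return best.copy()
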