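"""Cell-cycle progression, growth, polarization, and division.

Cells progress through a cycle whose length shortens with WUS; growth is
realised by inserting cytoplasm nodes (raising turgor) and by bisecting
over-stretched wall edges.  At initialization and after every division a
cell samples a growth-direction polarization: in the P3D variant it may
polarize out of the section plane with a zone/layer-specific probability
(measured frequencies of out-of-plane divisions), otherwise it expands
in-plane, anticlinally or periclinally with WUS/CK-weighted probability.
Division planes are layer specific: tunica cells divide anticlinally to
preserve the monolayers, apical-corpus cells divide perpendicular to the
principal direction of wall tension (a mechanical cue), and basal-corpus
cells sample anticlinal vs periclinal planes with WUS/CK weights.  An
out-of-plane division leaves the cross-section: the mother's footprint
shrinks and no new cell appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import rng as rngmod
from .tissue import (
    CYTOPLASM,
    TUNICA,
    WALL,
    Cell,
    Node,
    PotentialParams,
    Tissue,
    canonical_pair,
    polygon_centroid,
    signed_area,
)

# measured frequencies (%/100) of out-of-plane growth polarization by
# functional zone: {(zone, layer group): probability}
DEFAULT_PERICLINAL_TABLE: dict[tuple[str, str], float] = {
    ("central", "tunica"): 0.474,
    ("central", "apical_corpus"): 0.178,
    ("central", "basal_corpus"): 0.105,
    ("peripheral", "tunica"): 0.434,
    ("peripheral", "apical_corpus"): 0.290,
    ("peripheral", "basal_corpus"): 0.182,
}


@dataclass
class GrowthParams:
    """Growth, polarization and division parameters."""

    cycle_hours_max: float = 60.0  # cycle length at WUS = 0
    cycle_hours_min: float = 20.0
    cycle_wus_slope: float = 50.0  # hours removed per unit WUS
    nodes_per_cycle: int = 8  # cytoplasm nodes added over one full cycle
    wall_strain_threshold: float = 0.5  # relative edge extension triggering insertion
    inplane_terminal_area: float = 55.0  # µm²
    outplane_area_factor: float = 0.75  # out-of-plane section ≈25% smaller
    anticlinal_gain: float = 1.0  # in-plane bias weight ∝ gain·WUS
    periclinal_gain: float = 1.0  # ∝ gain·CK
    bias_floor: float = 0.05
    periclinal_table: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PERICLINAL_TABLE)
    )
    min_division_area: float = 6.0  # µm²; below this, division is deferred
    # wall material is added by growth, not elastic stretch: the driver
    # inserts wall nodes only while the cell is below this multiple of
    # its target area (prevents stretch-insertion feedback)
    wall_insertion_area_cap: float = 1.4
    max_wall_nodes: int = 96  # hard bound on ring size (driver policy)
    mechanical_cue_rule: str = "max_tension"  # or "shortest_axis"
    apical_depth_fraction: float = 0.5  # split of corpus into apical/basal
    central_zone_cell_radii: float = 4.0  # CZ half-width, in mean cell diameters

    def validate(self) -> None:
        if not 0.0 < self.outplane_area_factor < 1.0:
            raise ValueError("outplane_area_factor must lie in (0,1)")
        for key, p in self.periclinal_table.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"periclinal_table[{key}] must be a probability")
        if self.cycle_hours_min <= 0 or self.cycle_hours_max < self.cycle_hours_min:
            raise ValueError("cycle length bounds are inconsistent")

    def cycle_hours(self, wus: float) -> float:
        """WUS-dependent cycle length (monotone non-increasing, bounded)."""
        return float(
            np.clip(
                self.cycle_hours_max - self.cycle_wus_slope * wus,
                self.cycle_hours_min,
                self.cycle_hours_max,
            )
        )


def layer_group(layer: str) -> str:
    return "tunica" if layer in TUNICA else layer


# ----------------------------------------------------------------------
# cycle progression and node insertion
# ----------------------------------------------------------------------

def advance_cycle(
    cell: Cell,
    dt_hours: float,
    growth_params: GrowthParams,
    tissue: Tissue,
    seed: int = 0,
) -> bool:
    """Advance the cell's cycle by ``dt_hours``; returns True when division is due.

    Cytoplasm nodes are inserted near the centroid each time the progress
    crosses a multiple of 1/nodes_per_cycle, with a small deterministic
    jitter drawn from the cell's counter-based stream.  Insertion stops
    while the cell is at or beyond its target area.
    """
    if dt_hours <= 0:
        raise ValueError("dt must be positive")
    if cell.layer == "boundary_cell":
        return False
    length = growth_params.cycle_hours(cell.wus)
    before = cell.cycle_progress
    after = min(before + dt_hours / length, 1.0)
    cell.cycle_progress = after
    npc = growth_params.nodes_per_cycle
    crossed = int(np.floor(after * npc + 1e-12)) - int(np.floor(before * npc + 1e-12))
    if crossed > 0 and tissue.cell_area(cell.id) < cell.target_area:
        centroid = tissue.cell_centroid(cell.id)
        for _ in range(crossed):
            r = rngmod.stream(seed, rngmod.CYTOPLASM_JITTER, cell.id, cell.jitter_events)
            cell.jitter_events += 1
            jitter = r.uniform(-0.5, 0.5, size=2)
            nid = tissue.add_node(Node(centroid + jitter, CYTOPLASM, cell.id))
            cell.cytoplasm.add(nid)
            cell.cyt_nodes_added += 1
        tissue.bump()
    return after >= 1.0


def insert_wall_nodes(cell: Cell, tissue: Tissue, params: PotentialParams, threshold: float | None = None) -> int:
    """Bisect wall edges stretched beyond (1+threshold)·l_eq; returns count."""
    threshold = threshold if threshold is not None else 0.5
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    l_eq = params.extensibility.l_eq
    limit = (1.0 + threshold) * l_eq
    inserted = 0
    i = 0
    while i < len(cell.wall_ring):
        a = cell.wall_ring[i]
        b = cell.wall_ring[(i + 1) % len(cell.wall_ring)]
        pa, pb = tissue.nodes[a].position, tissue.nodes[b].position
        if np.linalg.norm(pb - pa) > limit:
            mid = 0.5 * (pa + pb)
            nid = tissue.add_node(Node(mid, WALL, cell.id))
            cell.wall_ring.insert(i + 1, nid)
            cell.edge_stiffness = np.insert(cell.edge_stiffness, i + 1, cell.edge_stiffness[i])
            inserted += 1
            i += 2  # skip the two half-edges just created
        else:
            i += 1
    if inserted:
        _renumber_ring(cell, tissue)
        tissue.bump()
    return inserted


def _renumber_ring(cell: Cell, tissue: Tissue) -> None:
    for k, nid in enumerate(cell.wall_ring):
        tissue.nodes[nid].ring_index = k


# ----------------------------------------------------------------------
# polarization
# ----------------------------------------------------------------------

def sample_polarization(
    cell: Cell,
    rng: np.random.Generator,
    growth_params: GrowthParams,
    variant: str = "p3d",
) -> str:
    """Draw a growth-direction polarization for the cell.

    In P3D mode the cell polarizes out of plane with the zone/layer
    probability from the measured frequency table; otherwise (and always
    in 2D mode) it expands in plane, anticlinally or periclinally with
    probabilities proportional to floor + gain·WUS and floor + gain·CK.
    The out-of-plane uniform draw is consumed in both variants so that a
    2D run is bit-identical to a P3D run with a zeroed table.
    """
    if cell.layer == "boundary_cell":
        rng.random()  # keep stream alignment with dividing cells
        rng.random()
        return cell.polarization
    key = (cell.zone, layer_group(cell.layer))
    if key not in growth_params.periclinal_table:
        raise ValueError(f"no out-of-plane probability for stratum {key}")
    p_out = growth_params.periclinal_table[key] if variant == "p3d" else 0.0
    u_out = rng.random()
    w_a = growth_params.bias_floor + growth_params.anticlinal_gain * cell.wus
    w_p = growth_params.bias_floor + growth_params.periclinal_gain * cell.ck
    u_dir = rng.random()
    if u_out < p_out:
        return "out_of_plane"
    return "in_plane_anticlinal" if u_dir < w_a / (w_a + w_p) else "in_plane_periclinal"


def surface_frame(cell_centroid: np.ndarray, tissue: Tissue) -> tuple[np.ndarray, np.ndarray]:
    """Local (radial, tangent) unit vectors of the dome at a point.

    The radial (anticlinal) axis points from the base-centre anchor of the
    dome through the centroid; the tangent (periclinal) axis is its
    perpendicular.
    """
    anchor = np.array([tissue.apex[0], tissue.base_y])
    radial = cell_centroid - anchor
    n = np.linalg.norm(radial)
    r_hat = np.array([0.0, 1.0]) if n == 0 else radial / n
    t_hat = np.array([-r_hat[1], r_hat[0]])
    return r_hat, t_hat


def apply_polarization(cell: Cell, tissue: Tissue, params: PotentialParams, growth_params: GrowthParams) -> Tissue:
    """Translate the polarization into per-edge wall stiffness and target area.

    Out-of-plane cells get uniform wall parameters and a section target
    area reduced by ``outplane_area_factor``.  In-plane cells get the
    extensibility of edges roughly parallel to the preferred expansion
    axis reduced by the anisotropy factor, so the cell elongates along
    that axis (anticlinal = radial, periclinal = tangential).
    """
    m = len(cell.wall_ring)
    if cell.polarization == "out_of_plane":
        cell.edge_stiffness = np.ones(m)
        cell.target_area = growth_params.outplane_area_factor * growth_params.inplane_terminal_area
        return tissue
    cell.target_area = growth_params.inplane_terminal_area
    centroid = tissue.cell_centroid(cell.id)
    r_hat, t_hat = surface_frame(centroid, tissue)
    axis = r_hat if cell.polarization == "in_plane_anticlinal" else t_hat
    stiff = np.ones(m)
    pts = tissue.ring_positions(cell)
    for e in range(m):
        edge = pts[(e + 1) % m] - pts[e]
        ln = np.linalg.norm(edge)
        if ln == 0:
            continue
        if abs(float(edge @ axis) / ln) > np.cos(np.pi / 4):
            stiff[e] = params.anisotropy_factor
    cell.edge_stiffness = stiff
    return tissue


# ----------------------------------------------------------------------
# division plane choice
# ----------------------------------------------------------------------

def wall_tension_tensor(cell: Cell, tissue: Tissue, params: PotentialParams) -> np.ndarray:
    """Σ over wall edges of tension·(direction ⊗ direction); tension ≥ 0."""
    pts = tissue.ring_positions(cell)
    m = len(pts)
    T = np.zeros((2, 2))
    l_eq = params.extensibility.l_eq
    for e in range(m):
        d = pts[(e + 1) % m] - pts[e]
        ln = float(np.linalg.norm(d))
        if ln == 0:
            continue
        tension = max(params.extensibility.k * cell.edge_stiffness[e] * (ln - l_eq), 0.0)
        u = d / ln
        T += tension * np.outer(u, u)
    return T


def choose_division_plane(
    cell: Cell,
    tissue: Tissue,
    params: PotentialParams,
    growth_params: GrowthParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Division plane (point on plane, unit normal), or None to defer.

    Tunica: anticlinal (plane normal along the local surface tangent).
    Apical corpus: through the centroid, perpendicular to the principal
    direction of wall tension (normal ∥ max-tension direction).
    Basal corpus: anticlinal or periclinal, sampled with WUS/CK weights.
    Boundary cells never divide.
    """
    if cell.layer == "boundary_cell":
        return None
    if tissue.cell_area(cell.id) < growth_params.min_division_area:
        warnings.warn(f"cell {cell.id}: area below minimum, division deferred")
        return None
    centroid = tissue.cell_centroid(cell.id)
    r_hat, t_hat = surface_frame(centroid, tissue)
    if cell.layer in TUNICA:
        return centroid, t_hat  # anticlinal: new wall along the radial axis
    if cell.layer == "apical_corpus":
        if growth_params.mechanical_cue_rule == "shortest_axis":
            normal = _major_axis(cell, tissue)
        else:
            T = wall_tension_tensor(cell, tissue, params)
            vals, vecs = np.linalg.eigh(T)
            if vals[-1] <= 1e-12:  # no tension signal: fall back to anticlinal
                normal = t_hat
            else:
                normal = vecs[:, -1]
        return centroid, normal / np.linalg.norm(normal)
    # basal corpus: stochastic, parametrized by WUS and CK
    w_a = growth_params.bias_floor + growth_params.anticlinal_gain * cell.wus
    w_p = growth_params.bias_floor + growth_params.periclinal_gain * cell.ck
    u = rng.random() if rng is not None else 0.0
    normal = t_hat if u < w_a / (w_a + w_p) else r_hat
    return centroid, normal


def _major_axis(cell: Cell, tissue: Tissue) -> np.ndarray:
    pts = tissue.ring_positions(cell)
    pts = pts - pts.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(pts.T))
    return vecs[:, -1]


def plane_angle_to_surface(normal: np.ndarray, centroid: np.ndarray, tissue: Tissue) -> float:
    """Angle (deg, in [0, 90]) between the plane normal and the surface normal.

    0° means the plane is parallel to the local surface (periclinal);
    90° means perpendicular (anticlinal).
    """
    r_hat, _ = surface_frame(centroid, tissue)
    c = abs(float(np.asarray(normal) @ r_hat)) / np.linalg.norm(normal)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ----------------------------------------------------------------------
# division execution
# ----------------------------------------------------------------------

class DivisionGeometryError(RuntimeError):
    pass


def execute_division(
    cell: Cell,
    plane: tuple[np.ndarray, np.ndarray],
    tissue: Tissue,
    params: PotentialParams,
) -> tuple[Cell, Cell]:
    """Split the cell in two along the plane (in-plane division).

    The wall ring is cut where the plane crosses it; each daughter gets
    its own straight chain of new wall nodes along the cut (the two
    chains are coincident and pairwise adhered, modelling the new shared
    wall).  Cytoplasm nodes are partitioned by side.  Daughters get fresh
    ids and a reset cycle; the mother id is retired.
    """
    p0, n = np.asarray(plane[0], dtype=float), np.asarray(plane[1], dtype=float)
    n = n / np.linalg.norm(n)
    ring = list(cell.wall_ring)
    pts = tissue.ring_positions(cell)
    d = (pts - p0) @ n
    d = np.where(d == 0.0, 1e-12, d)
    m = len(ring)
    crossings = [e for e in range(m) if d[e] * d[(e + 1) % m] < 0]
    if len(crossings) != 2:
        raise DivisionGeometryError(
            f"plane crosses the wall ring {len(crossings)} times; need exactly 2"
        )
    e1, e2 = crossings
    q = {}
    for e in (e1, e2):
        a, b = pts[e], pts[(e + 1) % m]
        denom = d[e] - d[(e + 1) % m]
        if denom == 0.0 or not np.isfinite(denom):
            raise DivisionGeometryError("degenerate ring: cut point undefined")
        t = d[e] / denom
        q[e] = a + t * (b - a)
        if not np.all(np.isfinite(q[e])):
            raise DivisionGeometryError("degenerate ring: non-finite cut point")

    # walk the ring, collecting each side's vertex index runs
    side_pos = [i for i in range(m) if d[i] > 0]
    side_neg = [i for i in range(m) if d[i] < 0]

    def arc(start_edge, end_edge):
        """ring indices strictly after start_edge up to and including end_edge."""
        out = []
        i = (start_edge + 1) % m
        while True:
            out.append(i)
            if i == end_edge:
                break
            i = (i + 1) % m
        return out

    arc_a = arc(e1, e2)  # vertices between the two cut points, one side
    arc_b = arc(e2, e1)  # the other side
    # which arc is on which side of the plane
    if d[arc_a[0]] < 0:
        arc_a, arc_b = arc_b, arc_a
        # ensure q endpoints ordered consistently below
    # endpoints of arcs: arc on + side runs from cut at one edge to cut at other
    # determine the cut points bounding each arc
    def bounding(arcv):
        first, last = arcv[0], arcv[-1]
        start_edge = (first - 1) % m
        end_edge = last
        return q[start_edge], q[end_edge]

    qa_start, qa_end = bounding(arc_a)
    qb_start, qb_end = bounding(arc_b)

    l_eq = params.extensibility.l_eq

    def chain_points(a, b):
        """new-wall node positions from a to b (exclusive), spaced ~l_eq."""
        length = np.linalg.norm(b - a)
        k = max(int(round(length / l_eq)), 1)
        ts = np.arange(0, k + 1) / k
        return [a + t * (b - a) for t in ts]

    id_a = tissue.new_cell_id()
    id_b = tissue.new_cell_id()

    def make_daughter(cid, arcv, q_start, q_end):
        ring_ids = [tissue.add_node(Node(q_start.copy(), WALL, cid))]
        for i in arcv:
            nid = ring[i]
            node = tissue.nodes[nid]
            node.cell_id = cid
            ring_ids.append(nid)
        ring_ids.append(tissue.add_node(Node(q_end.copy(), WALL, cid)))
        # new shared wall from q_end back to q_start
        wall_pts = chain_points(q_end, q_start)[1:-1]
        for pt in wall_pts:
            ring_ids.append(tissue.add_node(Node(pt.copy(), WALL, cid)))
        return ring_ids

    ring_a = make_daughter(id_a, arc_a, qa_start, qa_end)
    ring_b = make_daughter(id_b, arc_b, qb_start, qb_end)

    # partition cytoplasm by side of the plane
    cyt_a, cyt_b = set(), set()
    for nid in cell.cytoplasm:
        node = tissue.nodes[nid]
        side = float((node.position - p0) @ n)
        (cyt_a if side > 0 else cyt_b).add(nid)

    def finish(cid, ring_ids, cyt, other_ring):
        for nid in cyt:
            tissue.nodes[nid].cell_id = cid
        d_cell = Cell(
            id=cid,
            wall_ring=ring_ids,
            cytoplasm=cyt,
            layer=cell.layer,
            zone=cell.zone,
            polarization=cell.polarization,
            wus=cell.wus,
            ck=cell.ck if cell.layer not in TUNICA else 0.0,
            cycle_progress=0.0,
            damping=cell.damping,
            target_area=cell.target_area,
        )
        pts_d = np.array([tissue.nodes[i].position for i in ring_ids])
        if signed_area(pts_d) < 0:
            d_cell.wall_ring = ring_ids[::-1]
        d_cell.edge_stiffness = np.ones(len(ring_ids))
        if not d_cell.cytoplasm:
            c = polygon_centroid(np.array([tissue.nodes[i].position for i in d_cell.wall_ring]))
            nid = tissue.add_node(Node(c, CYTOPLASM, cid))
            d_cell.cytoplasm.add(nid)
        _renumber_ring(d_cell, tissue)
        return d_cell

    da = finish(id_a, ring_a, cyt_a, ring_b)
    db = finish(id_b, ring_b, cyt_b, ring_a)

    # adhere the two coincident new-wall chains pairwise (by proximity)
    created_a = [nid for nid in da.wall_ring if tissue.nodes[nid].cell_id == id_a and nid not in ring]
    created_b = [nid for nid in db.wall_ring if tissue.nodes[nid].cell_id == id_b and nid not in ring]
    pos_b = {nid: tissue.nodes[nid].position for nid in created_b}
    for nid in created_a:
        pa = tissue.nodes[nid].position
        best = min(created_b, key=lambda x: np.linalg.norm(pos_b[x] - pa))
        tissue.adhesion_pairs.add(canonical_pair(nid, best))

    del tissue.cells[cell.id]
    tissue.cells[id_a] = da
    tissue.cells[id_b] = db
    tissue.bump()
    return da, db


def execute_out_of_plane_division(cell: Cell, tissue: Tissue, growth_params: GrowthParams) -> Cell:
    """Out-of-plane division: the unseen daughter leaves the section.

    The mother's footprint is retained with its cytoplasm node count
    reduced to the out-of-plane area fraction; the cycle restarts.  The
    cell count is unchanged.
    """
    keep = max(int(round(growth_params.outplane_area_factor * len(cell.cytoplasm))), 1)
    cyt_sorted = sorted(cell.cytoplasm)
    centroid = tissue.cell_centroid(cell.id)
    # drop the cytoplasm nodes farthest from the centroid
    cyt_sorted.sort(key=lambda nid: float(np.linalg.norm(tissue.nodes[nid].position - centroid)))
    for nid in cyt_sorted[keep:]:
        cell.cytoplasm.discard(nid)
        del tissue.nodes[nid]
    cell.cycle_progress = 0.0
    tissue.bump()
    return cell


# ----------------------------------------------------------------------
# labels
# ----------------------------------------------------------------------

def relabel_zones(tissue: Tissue, growth_params: GrowthParams) -> None:
    """Central zone = centroid within N mean-cell-diameters of the apex axis."""
    diam = tissue.mean_cell_diameter()
    half_width = growth_params.central_zone_cell_radii * diam
    for cell in tissue.cells.values():
        cx = tissue.cell_centroid(cell.id)[0]
        cell.zone = "central" if abs(cx - tissue.apex[0]) <= half_width else "peripheral"


def relabel_corpus(tissue: Tissue, growth_params: GrowthParams) -> None:
    """Positional apical/basal split of corpus cells by centroid depth."""
    corpus = [c for c in tissue.cells.values() if c.layer in ("apical_corpus", "basal_corpus")]
    if not corpus:
        return
    ys = {c.id: tissue.cell_centroid(c.id)[1] for c in corpus}
    y_lo, y_hi = min(ys.values()), max(ys.values())
    cut = y_lo + growth_params.apical_depth_fraction * (y_hi - y_lo)
    for c in corpus:
        c.layer = "apical_corpus" if ys[c.id] >= cut else "basal_corpus"
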