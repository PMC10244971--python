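"""Domain types and topology bookkeeping for SCE tissues.

A tissue is a collection of cells, each represented by a closed ring of
wall nodes plus a set of interior cytoplasm nodes.  Wall rings of distinct
cells may be linked by adhesion pairs.  All coordinates are in µm, forces
in µN, energies in µN·µm; time is kept in hours on the tissue and in
seconds inside the integrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

WALL = "wall"
CYTOPLASM = "cytoplasm"

LAYERS = ("L1", "L2", "apical_corpus", "basal_corpus", "boundary_cell")
TUNICA = ("L1", "L2")
ZONES = ("central", "peripheral")
POLARIZATIONS = ("in_plane_anticlinal", "in_plane_periclinal", "out_of_plane")


class TopologyError(ValueError):
    """Raised when node/cell references or ring structure are inconsistent."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class Node:
    """A point mass: either a wall node on a cell's ring or a cytoplasm node."""

    position: np.ndarray  # shape (2,), µm
    role: str  # WALL or CYTOPLASM
    cell_id: int
    ring_index: int | None = None
    is_boundary: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (2,):
            raise TopologyError(f"node position must be 2D, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise TopologyError("node position must be finite")
        if self.role not in (WALL, CYTOPLASM):
            raise TopologyError(f"unknown node role {self.role!r}")
        if self.role == CYTOPLASM and self.ring_index is not None:
            raise TopologyError("cytoplasm nodes carry no ring index")


@dataclass
class Cell:
    """A cell: closed wall ring, cytoplasm nodes, labels and signal state."""

    id: int
    wall_ring: list[int]
    cytoplasm: set[int]
    layer: str = "apical_corpus"
    zone: str = "central"
    polarization: str = "in_plane_anticlinal"
    wus: float = 0.0
    ck: float = 0.0
    cycle_progress: float = 0.0
    damping: float = 50.0  # η, µN·s/µm
    target_area: float = 50.0  # µm²
    # per-ring-edge stiffness multipliers for the extensibility springs;
    # edge k connects wall_ring[k] -> wall_ring[k+1] (cyclic)
    edge_stiffness: np.ndarray | None = None
    # event counters for counter-based random streams
    polarization_events: int = 0
    division_events: int = 0
    jitter_events: int = 0
    cyt_nodes_added: int = 0

    def __post_init__(self):
        self.wall_ring = list(self.wall_ring)
        self.cytoplasm = set(self.cytoplasm)
        if self.layer not in LAYERS:
            raise TopologyError(f"unknown layer {self.layer!r}")
        if self.zone not in ZONES:
            raise TopologyError(f"unknown zone {self.zone!r}")
        if self.polarization not in POLARIZATIONS:
            raise TopologyError(f"unknown polarization {self.polarization!r}")
        if not 0.0 <= self.cycle_progress <= 1.0 + 1e-12:
            raise TopologyError("cycle_progress must lie in [0, 1]")
        if self.layer in TUNICA and self.ck != 0.0:
            raise TopologyError("tunica cells (L1/L2) carry no cytokinin")
        if self.edge_stiffness is None:
            self.edge_stiffness = np.ones(len(self.wall_ring))
        else:
            self.edge_stiffness = np.asarray(self.edge_stiffness, dtype=float)
            if self.edge_stiffness.shape != (len(self.wall_ring),):
                raise TopologyError("edge_stiffness must have one entry per ring edge")


@dataclass
class MorseParams:
    """Coefficients of a soft-core Morse potential U·e^{-r/ξ} − V·e^{-r/γ}."""

    U: float
    V: float
    xi: float
    gamma: float

    def validate(self, name: str = "morse") -> None:
        if min(self.U, self.V, self.xi, self.gamma) <= 0:
            raise ConfigError(f"{name}: Morse coefficients must be positive")
        if not np.isclose(self.U / self.xi, self.V / self.gamma, rtol=1e-9):
            warnings.warn(
                f"{name}: U/xi != V/gamma breaks force continuity at zero separation",
                stacklevel=3,
            )


@dataclass
class SpringParams:
    k: float  # µN/µm
    l_eq: float  # µm

    def validate(self, name: str = "spring") -> None:
        if self.k <= 0 or self.l_eq < 0:
            raise ConfigError(f"{name}: spring needs k>0, l_eq>=0")


@dataclass
class PotentialParams:
    """All mechanical coefficients: the six potentials plus damping.

    Defaults are package defaults chosen so a generated cell relaxes to a
    round shape 5–7 µm across (see docs/methods.md); they are not taken
    from any published calibration.
    """

    turgor: MorseParams = field(default_factory=lambda: MorseParams(U=6.0, V=2.4, xi=3.0, gamma=1.2))
    volume_exclusion: MorseParams = field(default_factory=lambda: MorseParams(U=12.0, V=4.8, xi=1.0, gamma=0.4))
    pressure: MorseParams = field(default_factory=lambda: MorseParams(U=5.0, V=2.0, xi=2.0, gamma=0.8))
    extensibility: SpringParams = field(default_factory=lambda: SpringParams(k=40.0, l_eq=1.2))
    adhesion: SpringParams = field(default_factory=lambda: SpringParams(k=20.0, l_eq=0.3))
    bending_k: float = 2.0  # µN·µm/rad²
    bending_theta_eq: float = np.pi  # rad
    eta_base: float = 50.0  # µN·s/µm
    eta_bottom_multiplier: float = 10.0
    cutoff_um: float | None = None  # volume-exclusion cutoff; default 3·max(ξ,γ)
    adhesion_cutoff_um: float = 1.0
    # existing bonds persist under load up to this separation (cell walls
    # are glued; releasing stretched bonds at refresh would unzip tissue)
    adhesion_detach_um: float = 3.0
    anisotropy_factor: float = 0.15  # stiffness multiplier on softened edges

    def validate(self) -> None:
        self.turgor.validate("turgor")
        self.volume_exclusion.validate("volume_exclusion")
        self.pressure.validate("pressure")
        self.extensibility.validate("extensibility")
        self.adhesion.validate("adhesion")
        if self.bending_k <= 0:
            raise ConfigError("bending_k must be positive")
        if self.eta_base <= 0:
            raise ConfigError("eta_base must be positive")

    @property
    def ve_cutoff(self) -> float:
        if self.cutoff_um is not None:
            return float(self.cutoff_um)
        return 3.0 * max(self.volume_exclusion.xi, self.volume_exclusion.gamma)


def canonical_pair(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class Tissue:
    """Cells, nodes, adhesion pairings, signal centres and the apex frame."""

    cells: dict[int, Cell] = field(default_factory=dict)
    nodes: dict[int, Node] = field(default_factory=dict)
    adhesion_pairs: set[tuple[int, int]] = field(default_factory=set)
    wus_centre: np.ndarray | None = None
    ck_centre: np.ndarray | None = None
    apex: np.ndarray = field(default_factory=lambda: np.zeros(2))
    base_y: float = 0.0
    time_hours: float = 0.0
    topology_version: int = 0
    _next_node_id: int = 0
    _next_cell_id: int = 0

    # -- id management -------------------------------------------------
    def new_node_id(self) -> int:
        nid = self._next_node_id
        self._next_node_id += 1
        return nid

    def new_cell_id(self) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        return cid

    def add_node(self, node: Node) -> int:
        nid = self.new_node_id()
        self.nodes[nid] = node
        return nid

    def bump(self) -> None:
        self.topology_version += 1

    # -- geometry helpers ----------------------------------------------
    def ring_positions(self, cell: Cell) -> np.ndarray:
        return np.array([self.nodes[i].position for i in cell.wall_ring])

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        """Polygon (area-weighted) centroid of the cell's wall ring."""
        pts = self.ring_positions(self.cells[cell_id])
        return polygon_centroid(pts)

    def cell_area(self, cell_id: int) -> float:
        return abs(signed_area(self.ring_positions(self.cells[cell_id])))

    def mean_cell_diameter(self, layers: tuple[str, ...] | None = None) -> float:
        """Mean equivalent-circle diameter 2·sqrt(A/π) over (a subset of) cells."""
        areas = [
            self.cell_area(cid)
            for cid, c in self.cells.items()
            if layers is None or c.layer in layers
        ]
        if not areas:
            raise TopologyError("no cells to measure")
        return float(np.mean(2.0 * np.sqrt(np.asarray(areas) / np.pi)))

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        for cid, cell in self.cells.items():
            if cell.id != cid:
                raise TopologyError(f"cell {cid} stored under wrong key")
            if len(cell.wall_ring) < 3:
                raise TopologyError(f"cell {cid}: wall ring needs >=3 nodes")
            if len(set(cell.wall_ring)) != len(cell.wall_ring):
                raise TopologyError(f"cell {cid}: wall ring repeats a node")
            for nid in cell.wall_ring:
                node = self.nodes.get(nid)
                if node is None:
                    raise TopologyError(f"cell {cid}: wall node {nid} missing")
                if node.role != WALL:
                    raise TopologyError(f"cell {cid}: node {nid} in ring is not a wall node")
                if node.cell_id != cid:
                    raise TopologyError(f"cell {cid}: wall node {nid} owned by {node.cell_id}")
            for nid in cell.cytoplasm:
                node = self.nodes.get(nid)
                if node is None:
                    raise TopologyError(f"cell {cid}: cytoplasm node {nid} missing")
                if node.role != CYTOPLASM:
                    raise TopologyError(f"cell {cid}: node {nid} is not cytoplasm")
                if node.cell_id != cid:
                    raise TopologyError(f"cell {cid}: cytoplasm node {nid} owned by {node.cell_id}")
        for a, b in self.adhesion_pairs:
            if a not in self.nodes or b not in self.nodes:
                raise TopologyError(f"adhesion pair ({a},{b}) references a missing node")
            if self.nodes[a].cell_id == self.nodes[b].cell_id:
                raise TopologyError(f"adhesion pair ({a},{b}) joins nodes of one cell")
            if (a, b) != canonical_pair(a, b):
                raise TopologyError("adhesion pairs must be stored canonically (a<b)")

    def copy(self) -> "Tissue":
        t = Tissue(
            cells={
                cid: replace(
                    c,
                    wall_ring=list(c.wall_ring),
                    cytoplasm=set(c.cytoplasm),
                    edge_stiffness=np.array(c.edge_stiffness),
                )
                for cid, c in self.cells.items()
            },
            nodes={
                nid: Node(n.position.copy(), n.role, n.cell_id, n.ring_index, n.is_boundary)
                for nid, n in self.nodes.items()
            },
            adhesion_pairs=set(self.adhesion_pairs),
            wus_centre=None if self.wus_centre is None else self.wus_centre.copy(),
            ck_centre=None if self.ck_centre is None else self.ck_centre.copy(),
            apex=self.apex.copy(),
            base_y=self.base_y,
            time_hours=self.time_hours,
            topology_version=self.topology_version,
            _next_node_id=self._next_node_id,
            _next_cell_id=self._next_cell_id,
        )
        return t


# -- free functions -----------------------------------------------------

def signed_area(pts: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given its vertices in order."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(pts: np.ndarray) -> np.ndarray:
    a = signed_area(pts)
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def ring_is_simple(pts: np.ndarray) -> bool:
    """True when the closed polygon does not self-intersect."""
    from shapely.geometry import LinearRing

    try:
        return LinearRing(pts).is_simple and LinearRing(pts).is_valid
    except Exception:
        return False


def build_tissue(
    cells: list[Cell],
    nodes: dict[int, Node],
    signal_centres: tuple[np.ndarray, np.ndarray] | None = None,
    adhesion_pairs: set[tuple[int, int]] | None = None,
    apex: np.ndarray | None = None,
    base_y: float | None = None,
) -> Tissue:
    """Assemble and validate a Tissue from explicit cells and nodes."""
    t = Tissue()
    t.nodes = dict(nodes)
    t.cells = {c.id: c for c in cells}
    if len(t.cells) != len(cells):
        raise TopologyError("duplicate cell ids")
    if adhesion_pairs:
        t.adhesion_pairs = {canonical_pair(a, b) for a, b in adhesion_pairs}
    if signal_centres is not None:
        t.wus_centre = np.asarray(signal_centres[0], dtype=float)
        t.ck_centre = np.asarray(signal_centres[1], dtype=float)
    all_pos = np.array([n.position for n in t.nodes.values()])
    t.apex = np.asarray(apex, dtype=float) if apex is not None else all_pos[np.argmax(all_pos[:, 1])].copy()
    t.base_y = float(base_y) if base_y is not None else float(all_pos[:, 1].min())
    t._next_node_id = max(t.nodes, default=-1) + 1
    t._next_cell_id = max(t.cells, default=-1) + 1
    t.validate()
    return t


def cell_polygon(cell: Cell, tissue: Tissue) -> tuple[np.ndarray, bool]:
    """Ordered, counter-clockwise vertex array of the cell's wall ring.

    Returns ``(vertices, self_intersecting)``; a self-intersecting ring is
    reported with a flag rather than an error because mechanics may
    transiently produce one.
    """
    pts = tissue.ring_positions(cell)
    if signed_area(pts) < 0:
        pts = pts[::-1]
    return pts, not ring_is_simple(pts)


def refresh_adhesion(
    tissue: Tissue,
    params: PotentialParams,
    cutoff: float | None = None,
    max_partners_per_cell: int = 1,
) -> Tissue:
    """Recompute wall-node adhesion pairs (in place; the tissue is returned).

    Wall nodes of distinct cells within ``cutoff`` may adhere.  Each node
    adheres to at most ``max_partners_per_cell`` partners per neighbouring
    cell, chosen greedily by ascending distance; the pairing is symmetric.
    Existing bonds are kept (they persist under load) until they exceed
    the detachment distance ``params.adhesion_detach_um``.
    """
    from scipy.spatial import cKDTree

    cutoff = float(cutoff if cutoff is not None else params.adhesion_cutoff_um)
    if cutoff <= 0:
        raise ConfigError("adhesion cutoff must be positive")
    detach = max(float(params.adhesion_detach_um), cutoff)
    kept = set()
    for a, b in tissue.adhesion_pairs:
        na, nb = tissue.nodes.get(a), tissue.nodes.get(b)
        if na is None or nb is None or na.cell_id == nb.cell_id:
            continue
        if np.linalg.norm(na.position - nb.position) <= detach:
            kept.add(canonical_pair(a, b))
    wall_ids = [nid for nid, n in tissue.nodes.items() if n.role == WALL]
    pos = np.array([tissue.nodes[i].position for i in wall_ids])
    tissue.adhesion_pairs = kept
    if len(wall_ids) < 2:
        return tissue
    tree = cKDTree(pos)
    candidates = tree.query_pairs(cutoff, output_type="ndarray")
    if len(candidates) == 0:
        return tissue
    ids = np.asarray(wall_ids)
    a_ids, b_ids = ids[candidates[:, 0]], ids[candidates[:, 1]]
    cell_a = np.array([tissue.nodes[i].cell_id for i in a_ids])
    cell_b = np.array([tissue.nodes[i].cell_id for i in b_ids])
    cross = cell_a != cell_b
    a_ids, b_ids = a_ids[cross], b_ids[cross]
    if len(a_ids) == 0:
        return tissue
    d = np.linalg.norm(
        np.array([tissue.nodes[i].position for i in a_ids])
        - np.array([tissue.nodes[i].position for i in b_ids]),
        axis=1,
    )
    order = np.argsort(d, kind="stable")
    used: dict[tuple[int, int], int] = {}  # (node, partner cell) -> count
    pairs = set(kept)
    for a, b in kept:
        ca, cb = tissue.nodes[a].cell_id, tissue.nodes[b].cell_id
        used[(a, cb)] = used.get((a, cb), 0) + 1
        used[(b, ca)] = used.get((b, ca), 0) + 1
    for k in order:
        a, b = int(a_ids[k]), int(b_ids[k])
        if canonical_pair(a, b) in pairs:
            continue
        ca, cb = tissue.nodes[a].cell_id, tissue.nodes[b].cell_id
        if used.get((a, cb), 0) >= max_partners_per_cell:
            continue
        if used.get((b, ca), 0) >= max_partners_per_cell:
            continue
        pairs.add(canonical_pair(a, b))
        used[(a, cb)] = used.get((a, cb), 0) + 1
        used[(b, ca)] = used.get((b, ca), 0) + 1
    tissue.adhesion_pairs = pairs
    return tissue
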