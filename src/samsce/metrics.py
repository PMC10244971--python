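"""Tissue-structure readouts.

* monolayer length — arc length along the chain of epidermal (L1) cells;
  discontinuities in its time evolution signal a break in the monolayer.
* relative curvature — curvature of the apical surface after rescaling
  the tissue to unit width (a semicircular cap gives 2.0).
* aspect ratio — cell length along its longest axis over the length in
  the perpendicular direction.
* percent periclinal — share of divisions whose plane is closer to
  parallel with the local surface than perpendicular (45° cut, ties
  anticlinal).
* adhesion graph — cell adjacency from a Voronoi tessellation of cell
  centroids, pruned to the tissue hull.
* centralities — PageRank plus randomized-shortest-path betweenness
  (RSPB) and net betweenness (RSPBN) at inverse temperature β.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

from .tissue import Tissue


# ----------------------------------------------------------------------
# monolayer length
# ----------------------------------------------------------------------

def _l1_cell_graph(tissue: Tissue) -> nx.Graph:
    l1 = [c.id for c in tissue.cells.values() if c.layer == "L1"]
    g = nx.Graph()
    g.add_nodes_from(l1)
    l1_set = set(l1)
    for a, b in tissue.adhesion_pairs:
        ca, cb = tissue.nodes[a].cell_id, tissue.nodes[b].cell_id
        if ca in l1_set and cb in l1_set and ca != cb:
            g.add_edge(ca, cb)
    return g


def monolayer_length(tissue: Tissue) -> tuple[float, bool]:
    """Length (µm) of the epidermal cell chain, plus a structural-break flag.

    L1 cells are chained from the left tissue edge to the right through
    the adhesion graph restricted to L1; the length is the sum of
    consecutive centroid distances.  ``break_detected`` is True when the
    L1 cells do not form one simple left-to-right chain (e.g. a cell was
    expelled and the chain reroutes); jump detection over time is done by
    :class:`MetricSeries`.
    """
    g = _l1_cell_graph(tissue)
    if g.number_of_nodes() < 2:
        raise ValueError("monolayer length needs at least two L1 cells")
    cx = {cid: tissue.cell_centroid(cid) for cid in g.nodes}
    left = min(g.nodes, key=lambda c: cx[c][0])
    right = max(g.nodes, key=lambda c: cx[c][0])
    broke = False
    if nx.has_path(g, left, right):
        chain = nx.shortest_path(g, left, right)
        if len(chain) != g.number_of_nodes():
            broke = True
    else:
        # fall back to the longest chain within the component structure
        comp = max(nx.connected_components(g), key=len)
        sub = g.subgraph(comp)
        ends = sorted(comp, key=lambda c: cx[c][0])
        chain = nx.shortest_path(sub, ends[0], ends[-1])
        broke = True
    length = float(
        sum(np.linalg.norm(cx[a] - cx[b]) for a, b in zip(chain[:-1], chain[1:]))
    )
    return length, broke


# ----------------------------------------------------------------------
# relative curvature
# ----------------------------------------------------------------------

def _fit_circle(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares (Kåsa) circle fit; returns (centre, radius)."""
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    return np.array([cx, cy]), float(np.sqrt(max(r2, 0.0)))


def apical_surface_nodes(tissue: Tissue, cap_height_fraction: float = 0.5) -> np.ndarray:
    """Positions of outward wall nodes of L1 cells in the apical cap."""
    pts = []
    all_y = [n.position[1] for n in tissue.nodes.values()]
    y_cut = min(all_y) + cap_height_fraction * (max(all_y) - min(all_y))
    anchor = np.array([tissue.apex[0], tissue.base_y])
    for cell in tissue.cells.values():
        if cell.layer != "L1":
            continue
        c = tissue.cell_centroid(cell.id)
        radial = c - anchor
        nr = np.linalg.norm(radial)
        r_hat = np.array([0.0, 1.0]) if nr == 0 else radial / nr
        for nid in cell.wall_ring:
            p = tissue.nodes[nid].position
            if float((p - c) @ r_hat) > 0 and p[1] >= y_cut:
                pts.append(p)
    return np.array(pts)


def relative_curvature(tissue: Tissue, cap_height_fraction: float = 0.5) -> float:
    """Curvature 1/R of the apical L1 surface after rescaling to width 1.

    Scale and translation invariant: a semicircular cap of any absolute
    size returns 2.0; a flat top returns ~0.
    """
    pts = apical_surface_nodes(tissue, cap_height_fraction)
    if len(pts) < 5:
        raise ValueError("too few apical surface nodes for a circle fit")
    width = pts[:, 0].max() - pts[:, 0].min()
    if width <= 0:
        raise ValueError("degenerate apical surface")
    scaled = pts / width
    # a (near-)flat surface has no meaningful circle fit: curvature -> 0
    coeffs = np.polyfit(scaled[:, 0], scaled[:, 1], 1)
    sagitta = np.abs(scaled[:, 1] - np.polyval(coeffs, scaled[:, 0])).max()
    if sagitta < 1e-9:
        return 0.0
    _, r = _fit_circle(scaled)
    return 1.0 / r


# ----------------------------------------------------------------------
# aspect ratio
# ----------------------------------------------------------------------

def aspect_ratio(cell, tissue: Tissue) -> float:
    """Extent along the major principal axis over the minor-axis extent (≥1)."""
    pts = tissue.ring_positions(cell)
    if len(pts) < 3:
        raise ValueError("aspect ratio needs at least 3 wall nodes")
    centred = pts - pts.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(centred.T))
    proj = centred @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    minor, major = np.sort(extents)
    if minor <= 1e-12:
        raise ValueError("degenerate cell: zero minor extent")
    return float(major / minor)


# ----------------------------------------------------------------------
# percent periclinal
# ----------------------------------------------------------------------

def percent_periclinal(division_log: pd.DataFrame, region: str | None = None) -> float:
    """Percent of logged in-plane divisions classified periclinal.

    A division is periclinal when the angle between its plane normal and
    the local surface normal is < 45° (plane closer to parallel with the
    surface); ties at exactly 45° count as anticlinal.
    """
    df = division_log
    if "kind" in df.columns:
        df = df[df["kind"] == "in_plane"]
    if region is not None:
        df = df[df["layer"] == region]
    if len(df) == 0:
        raise ValueError(f"no divisions logged for region {region!r}")
    periclinal = (df["angle_deg"] < 45.0).sum()
    return 100.0 * float(periclinal) / len(df)


# ----------------------------------------------------------------------
# adhesion graph and centralities
# ----------------------------------------------------------------------

def _tissue_hull(tissue: Tissue, buffer_um: float) -> Polygon:
    polys = []
    for cell in tissue.cells.values():
        pts = tissue.ring_positions(cell)
        try:
            poly = Polygon(pts).buffer(0)
        except Exception:
            continue
        if not poly.is_empty:
            polys.append(poly)
    return unary_union(polys).buffer(buffer_um)


def adjacency_from_centroids(
    points: np.ndarray,
    hull: Polygon | None = None,
    labels: list | None = None,
) -> nx.Graph:
    """Cell adjacency from a Voronoi tessellation of centroids.

    Two points are adjacent when they share a Voronoi ridge of non-zero
    length; when a hull is given, the segment between the two centroids
    must lie inside it (prunes spurious far-boundary adjacencies).
    """
    n = len(points)
    if n < 3:
        raise ValueError("adjacency needs at least 3 cells")
    labels = labels if labels is not None else list(range(n))
    scale = float(np.ptp(points, axis=0).max())
    try:
        vor = Voronoi(points)
    except Exception:
        warnings.warn("degenerate centroid configuration; jittering for Voronoi")
        jitter = np.random.default_rng(0).normal(scale=1e-9 * scale, size=points.shape)
        vor = Voronoi(points + jitter)
    g = nx.Graph()
    g.add_nodes_from(labels)
    tol = 1e-9 * scale
    for (i, j), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 not in verts:
            v = vor.vertices[verts]
            if np.linalg.norm(v[0] - v[1]) <= tol:
                continue  # degenerate ridge (e.g. lattice diagonals)
        if hull is not None:
            seg = LineString([points[i], points[j]])
            if not hull.covers(seg):
                continue
        g.add_edge(labels[i], labels[j])
    return g


def adhesion_graph(tissue: Tissue) -> nx.Graph:
    """Cell adjacency network from Voronoi tessellation of cell centroids."""
    ids = list(tissue.cells.keys())
    pts = np.array([tissue.cell_centroid(cid) for cid in ids])
    hull = _tissue_hull(tissue, buffer_um=0.5 * tissue.mean_cell_diameter())
    return adjacency_from_centroids(pts, hull=hull, labels=ids)


def _rsp_matrices(g: nx.Graph, beta: float, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    A = nx.to_numpy_array(g, nodelist=nodes)
    deg = A.sum(axis=1)
    P_ref = A / deg[:, None]
    W = P_ref * np.exp(-beta)  # unit edge costs
    return A, W


def centralities(graph: nx.Graph, beta: float = 1.0, damping: float = 0.85) -> pd.DataFrame:
    """PageRank, RSP betweenness, and RSP net betweenness per node.

    RSPB/RSPBN follow the randomized-shortest-path framework: walks from
    s to t interpolate between pure random walks (β→0) and shortest
    paths (β→∞); the betweenness of a node is its expected number of
    visits summed over all source–target pairs, and the net variant sums
    absolute net edge flows into the node.  PageRank is normalized to
    sum to 1.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(graph.nodes)
    pr = nx.pagerank(graph, alpha=damping)
    rspb = {v: 0.0 for v in nodes}
    rspbn = {v: 0.0 for v in nodes}
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        warnings.warn("graph is disconnected; centralities computed per component")
    for comp in components:
        comp_nodes = [v for v in nodes if v in comp]
        if len(comp_nodes) < 2:
            continue
        sub = graph.subgraph(comp_nodes)
        b, bn = _rsp_betweenness(sub, comp_nodes, beta)
        for k, v in enumerate(comp_nodes):
            rspb[v] = b[k]
            rspbn[v] = bn[k]
    return pd.DataFrame(
        {
            "node": nodes,
            "pagerank": [pr[v] for v in nodes],
            "rspb": [rspb[v] for v in nodes],
            "rspbn": [rspbn[v] for v in nodes],
        }
    ).set_index("node")


def _rsp_betweenness(g: nx.Graph, nodes: list, beta: float) -> tuple[np.ndarray, np.ndarray]:
    n = len(nodes)
    A, W = _rsp_matrices(g, beta, nodes)
    I = np.eye(n)
    bet = np.zeros(n)
    bet_net = np.zeros(n)
    edges = np.array(np.nonzero(A)).T  # directed (i, j) pairs
    for t in range(n):
        Wt = W.copy()
        Wt[t, :] = 0.0
        Z = np.linalg.solve(I - Wt, I)
        zt = Z[:, t]  # z_{jt}
        if np.any(Z[:, t] <= 0):
            continue
        # visits: n_j(s,t) = Z[s,j] * Z[j,t] / Z[s,t]
        inv_zst = 1.0 / zt  # per source s: 1/Z[s,t]
        # sum over sources s != t, excluding s == j and j == t
        S = Z * inv_zst[:, None]  # S[s, j] = Z[s,j]/Z[s,t]
        S[t, :] = 0.0  # exclude s == t
        col = S.sum(axis=0) - np.diag(Z) * inv_zst  # exclude s == j
        visits = col * zt
        visits[t] = 0.0  # exclude j == t
        bet += visits
        # net edge flows per source, summed over s
        # eta_s(i->j) = S[s,i] * W[i,j] * zt[j]
        for i, j in edges:
            if i >= j:
                continue
            f_ij = S[:, i] * Wt[i, j] * zt[j]
            f_ji = S[:, j] * Wt[j, i] * zt[i]
            net = np.abs(f_ij - f_ji)
            net[t] = 0.0
            # endpoint pairs (s==i/j or t==i/j) contribute trivially; keep
            # the interior interpretation by zeroing s at the two nodes
            total = net.sum() - net[i] - net[j]
            bet_net[i] += 0.5 * total
            bet_net[j] += 0.5 * total
    return bet, bet_net


# ----------------------------------------------------------------------
# metric series
# ----------------------------------------------------------------------

@dataclass
class MetricSeries:
    """Per-time tissue metrics collected during a run."""

    rows: list[dict] = field(default_factory=list)
    monolayer_jump_threshold: float | None = None  # µm; default 2× mean L1 diameter

    def record(self, tissue: Tissue, centrality_beta: float | None = None) -> None:
        t = tissue.time_hours
        length, broke = monolayer_length(tissue)
        diam = tissue.mean_cell_diameter(layers=("L1",))
        threshold = (
            self.monolayer_jump_threshold
            if self.monolayer_jump_threshold is not None
            else 2.0 * diam
        )
        prev = [r for r in self.rows if r["metric"] == "monolayer_length"]
        if prev and abs(length - prev[-1]["value"]) > threshold:
            broke = True
        self.rows.append(
            {"time_hours": t, "region": "L1", "metric": "monolayer_length", "value": length}
        )
        self.rows.append(
            {"time_hours": t, "region": "L1", "metric": "monolayer_break", "value": float(broke)}
        )
        try:
            rc = relative_curvature(tissue)
            self.rows.append(
                {"time_hours": t, "region": "tissue", "metric": "relative_curvature", "value": rc}
            )
        except ValueError:
            pass
        for layer in ("L1", "L2", "apical_corpus", "basal_corpus"):
            ars = [
                aspect_ratio(c, tissue)
                for c in tissue.cells.values()
                if c.layer == layer and len(c.wall_ring) >= 3
            ]
            if ars:
                self.rows.append(
                    {
                        "time_hours": t,
                        "region": layer,
                        "metric": "mean_aspect_ratio",
                        "value": float(np.mean(ars)),
                    }
                )
        self.rows.append(
            {
                "time_hours": t,
                "region": "tissue",
                "metric": "n_cells",
                "value": float(len(tissue.cells)),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["time_hours", "region", "metric", "value"])

    def any_break(self) -> bool:
        df = self.to_frame()
        sel = df[df["metric"] == "monolayer_break"]
        return bool((sel["value"] > 0).any()) if len(sel) else False
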