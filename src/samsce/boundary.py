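"""Tunica boundary tension.

The meristem epidermis behaves like a pressurized shell: the tension the
surrounding tissue exerts on the edge of the simulated section has total
magnitude |F| = (r_ex/2)·w·P0, where r_ex is the radius of curvature of a
sphere fit to the L1 surface (µm), w the mean out-of-plane cell width
(µm) and P0 the pressure (MPa); µm²·MPa = µN.  The calibrated endpoints
are 190 and 280 µN; named conditions free/low/average/high/2x map to
0/190/235/280/560 µN.  The total is split evenly over the flagged
outward-facing tunica nodes on the section edge, each pulled along a
direction that promotes the experimentally observed curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue import ConfigError, Tissue, TUNICA, WALL

CONDITION_MAGNITUDES_UN = {
    "free": 0.0,
    "low": 190.0,
    "average": 235.0,
    "high": 280.0,
    "2x": 560.0,
}

DEFAULT_R_EX_UM = 80.1
DEFAULT_W_UM = 7.09


def magnitude_from_pressure(r_ex: float, w: float, p0: float) -> float:
    """Total boundary-force magnitude (µN) from shell geometry and pressure.

    |F| = (r_ex/2)·w·P0 with r_ex, w in µm and P0 in MPa.
    """
    if r_ex <= 0 or w <= 0 or p0 < 0:
        raise ValueError("r_ex and w must be positive; p0 non-negative")
    return (r_ex / 2.0) * w * p0


def condition_magnitude(label: str) -> float:
    """Magnitude (µN) of a named force condition."""
    try:
        return CONDITION_MAGNITUDES_UN[label]
    except KeyError:
        raise ConfigError(
            f"unknown force condition {label!r}; expected one of {sorted(CONDITION_MAGNITUDES_UN)}"
        ) from None


@dataclass
class BoundaryForceSpec:
    """Boundary-tension specification for one simulation arm."""

    total_magnitude: float  # µN
    r_ex: float = DEFAULT_R_EX_UM  # target radius of curvature, µm
    w: float = DEFAULT_W_UM  # mean out-of-plane cell width, µm
    p0: float | None = None  # MPa, when derived from pressure
    condition_label: str | None = None
    direction_blend: float = 0.5  # weight of the radial correction term

    @classmethod
    def from_condition(cls, label: str, r_ex: float = DEFAULT_R_EX_UM, direction_blend: float = 0.5):
        return cls(
            total_magnitude=condition_magnitude(label),
            r_ex=r_ex,
            condition_label=label,
            direction_blend=direction_blend,
        )

    @classmethod
    def from_pressure(
        cls, p0: float, r_ex: float = DEFAULT_R_EX_UM, w: float = DEFAULT_W_UM, direction_blend: float = 0.5
    ):
        return cls(
            total_magnitude=magnitude_from_pressure(r_ex, w, p0),
            r_ex=r_ex,
            w=w,
            p0=p0,
            direction_blend=direction_blend,
        )


def identify_boundary_nodes(tissue: Tissue, edge_band_cells: int = 1) -> None:
    """Flag outward-facing wall nodes of edge tunica cells (in place).

    For each side of the section, the ``edge_band_cells`` outermost L1 and
    L2 cells are selected; their wall nodes lying outward of the cell
    centroid (toward the section edge) are flagged.  Must be re-run after
    divisions near the edge.
    """
    for node in tissue.nodes.values():
        node.is_boundary = False
    tunica = [c for c in tissue.cells.values() if c.layer in TUNICA]
    if not tunica:
        return
    for layer in TUNICA:
        layer_cells = [c for c in tunica if c.layer == layer]
        if not layer_cells:
            continue
        xs = {c.id: tissue.cell_centroid(c.id)[0] for c in layer_cells}
        ordered = sorted(layer_cells, key=lambda c: xs[c.id])
        for side, cells in (("left", ordered[:edge_band_cells]), ("right", ordered[-edge_band_cells:])):
            sign = -1.0 if side == "left" else 1.0
            for cell in cells:
                cx = xs[cell.id]
                for nid in cell.wall_ring:
                    node = tissue.nodes[nid]
                    if sign * (node.position[0] - cx) > 0:
                        node.is_boundary = True


def apply_boundary_force(tissue: Tissue, spec: BoundaryForceSpec) -> dict[int, np.ndarray]:
    """Per-node boundary forces: total magnitude split evenly over flags.

    Each flagged node is pulled along the unit vector blending (a) the
    tangent, at the node's angular position, of a circle of radius r_ex
    anchored below the apex, oriented away from the apex, with (b) a
    radial correction proportional to the node's signed distance from
    that circle.  The blend weight is ``spec.direction_blend``.  The sum
    of per-node magnitudes equals the total exactly.
    """
    flagged = [nid for nid, n in tissue.nodes.items() if n.is_boundary and n.role == WALL]
    if spec.total_magnitude == 0.0:
        return {nid: np.zeros(2) for nid in flagged}
    if not flagged:
        raise ValueError("boundary tension requested but no boundary nodes are flagged")
    centre = tissue.apex - np.array([0.0, spec.r_ex])
    per_node = spec.total_magnitude / len(flagged)
    out: dict[int, np.ndarray] = {}
    for nid in flagged:
        p = tissue.nodes[nid].position
        radial = p - centre
        rr = np.linalg.norm(radial)
        if rr == 0.0:
            out[nid] = np.zeros(2)
            continue
        r_hat = radial / rr
        # tangent oriented away from the apex: sign of the node's x offset
        t_hat = np.array([-r_hat[1], r_hat[0]])
        side = np.sign(p[0] - tissue.apex[0]) or 1.0
        if np.sign(t_hat[0]) != side:
            t_hat = -t_hat
        signed_dist = rr - spec.r_ex  # >0 outside the target circle
        direction = t_hat + spec.direction_blend * (-signed_dist) * r_hat
        norm = np.linalg.norm(direction)
        direction = t_hat if norm == 0.0 else direction / norm
        out[nid] = per_node * direction
    return out
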