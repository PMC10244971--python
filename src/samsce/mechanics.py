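"""Potentials, forces, and overdamped time integration.

Wall nodes feel: turgor (Morse, vs own cytoplasm), extensibility springs
(ring neighbours), microfibril bending (ring triplets), volume exclusion
(Morse, vs wall nodes of other cells within a cutoff), adhesion springs
(vs adhesion partners) and, on flagged nodes, the boundary-tension force.
Cytoplasm nodes feel cytoplasmic pressure (Morse, vs own cytoplasm) and
turgor (vs own wall).  Nodes move by explicit forward-Euler overdamped
dynamics  x += (F/η)·dt, with η multiplied tenfold in the bottom layer.

Potentials are soft-core: every force is finite at zero separation, and a
Morse term whose coefficients satisfy U/ξ = V/γ has a critical point at
zero separation, making the force continuous there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .tissue import (
    CYTOPLASM,
    WALL,
    ConfigError,
    MorseParams,
    PotentialParams,
    SpringParams,
    Tissue,
)

TERMS = ("turgor", "extensibility", "bending", "volume_exclusion", "adhesion", "pressure", "boundary")


class NumericalInstabilityError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# elementary potentials and forces
# ----------------------------------------------------------------------

def morse_energy(r, U, V, xi, gamma):
    """Soft-core Morse energy U·e^{-r/ξ} − V·e^{-r/γ} at separation r (µm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    return U * np.exp(-r / xi) - V * np.exp(-r / gamma)


def morse_force_scalar(r, U, V, xi, gamma):
    """−dE/dr for the Morse potential; positive values push nodes apart."""
    r = np.asarray(r, dtype=float)
    return (U / xi) * np.exp(-r / xi) - (V / gamma) * np.exp(-r / gamma)


def morse_force(x, y, params: MorseParams) -> np.ndarray:
    """Force on the node at ``x`` from its Morse interaction with ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    r = float(np.linalg.norm(d))
    if r == 0.0:
        if not np.isclose(params.U / params.xi, params.V / params.gamma, rtol=1e-9):
            warnings.warn("Morse force discontinuous at zero separation (U/xi != V/gamma)")
        return np.zeros(2)
    f = morse_force_scalar(r, params.U, params.V, params.xi, params.gamma)
    return f * d / r


def linear_spring_energy(r, k, l_eq):
    return 0.5 * k * (np.asarray(r, dtype=float) - l_eq) ** 2


def linear_spring_force(x, y, k, l_eq) -> np.ndarray:
    """Restoring spring force on ``x``; magnitude k·(r − l_eq)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    r = float(np.linalg.norm(d))
    if r == 0.0:
        if l_eq > 0:
            warnings.warn("spring direction undefined at zero separation")
        return np.zeros(2)
    return -k * (r - l_eq) * d / r


def bending_energy(y, x, z, k_bend, theta_eq):
    theta = _angle(np.asarray(y) - np.asarray(x), np.asarray(z) - np.asarray(x))
    return 0.5 * k_bend * (theta - theta_eq) ** 2


def _angle(u, v) -> float:
    c = u[0] * v[1] - u[1] * v[0]
    d = u[0] * v[0] + u[1] * v[1]
    return float(np.arctan2(abs(c), d))  # unsigned angle in [0, π]


def bending_force(y, x, z, k_bend, theta_eq):
    """Forces on (y, x, z) from the angle penalty ½k(θ∠yxz − θ_eq)².

    The three returned forces sum to zero and exert no net torque about x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    u, v = y - x, z - x
    lu, lv = np.linalg.norm(u), np.linalg.norm(v)
    if lu == 0.0 or lv == 0.0:
        raise ValueError("bending angle undefined: zero-length leg")
    c = u[0] * v[1] - u[1] * v[0]
    d = float(u @ v)
    theta = np.arctan2(abs(c), d)
    denom = c * c + d * d
    s = np.sign(c) if c != 0.0 else 0.0
    # ∂θ/∂u and ∂θ/∂v with θ = atan2(|c|, d)
    dth_du = (d * s * np.array([v[1], -v[0]]) - abs(c) * v) / denom
    dth_dv = (d * s * np.array([-u[1], u[0]]) - abs(c) * u) / denom
    g = -k_bend * (theta - theta_eq)
    fy = g * dth_du
    fz = g * dth_dv
    fx = -(fy + fz)
    return fy, fx, fz


# ----------------------------------------------------------------------
# compiled mechanical state
# ----------------------------------------------------------------------

@dataclass
class ForceAccumulator:
    """Per-node force field, with an optional per-term breakdown."""

    node_ids: list[int]
    total: np.ndarray  # (N, 2) µN
    breakdown: dict[str, np.ndarray] | None = None

    def force_on(self, node_id: int) -> np.ndarray:
        return self.total[self.node_ids.index(node_id)]


@dataclass
class MechanicalState:
    """Flat-array view of a tissue, rebuilt whenever topology changes.

    Holds node positions and precompiled interaction index lists so the
    per-step force assembly is fully vectorised.  Positions live here
    between syncs; :meth:`sync_to_tissue` writes them back to the Node
    objects.
    """

    tissue: Tissue
    params: PotentialParams
    node_ids: list[int] = field(default_factory=list)
    pos: np.ndarray | None = None
    eta: np.ndarray | None = None
    # interaction index arrays
    turg_w: np.ndarray | None = None
    turg_c: np.ndarray | None = None
    ext_i: np.ndarray | None = None
    ext_j: np.ndarray | None = None
    ext_k: np.ndarray | None = None
    bend_prev: np.ndarray | None = None
    bend_ctr: np.ndarray | None = None
    bend_next: np.ndarray | None = None
    pres_i: np.ndarray | None = None
    pres_j: np.ndarray | None = None
    ve_i: np.ndarray | None = None
    ve_j: np.ndarray | None = None
    adh_i: np.ndarray | None = None
    adh_j: np.ndarray | None = None
    wall_mask: np.ndarray | None = None
    boundary_idx: np.ndarray | None = None
    boundary_forces: np.ndarray | None = None  # (nb, 2) constant between refreshes
    version: int = -1

    def __post_init__(self):
        self.params.validate()
        self.rebuild()

    # -- construction --------------------------------------------------
    def rebuild(self) -> None:
        t = self.tissue
        self.node_ids = list(t.nodes.keys())
        index = {nid: k for k, nid in enumerate(self.node_ids)}
        self.index = index
        n = len(self.node_ids)
        self.pos = np.array([t.nodes[i].position for i in self.node_ids], dtype=float)
        eta = np.empty(n)
        bottom = _bottom_cells(t)
        for nid, k in index.items():
            cell = t.cells[t.nodes[nid].cell_id]
            mult = self.params.eta_bottom_multiplier if cell.id in bottom else 1.0
            eta[k] = cell.damping * mult
        self.eta = eta
        self.wall_mask = np.array([t.nodes[i].role == WALL for i in self.node_ids])

        turg_w, turg_c = [], []
        ext_i, ext_j, ext_k = [], [], []
        bp, bc, bn = [], [], []
        pres_i, pres_j = [], []
        for cell in t.cells.values():
            ring = [index[i] for i in cell.wall_ring]
            cyt = [index[i] for i in cell.cytoplasm]
            for wi in ring:
                for ci in cyt:
                    turg_w.append(wi)
                    turg_c.append(ci)
            m = len(ring)
            for e in range(m):
                ext_i.append(ring[e])
                ext_j.append(ring[(e + 1) % m])
                ext_k.append(self.params.extensibility.k * cell.edge_stiffness[e])
                bp.append(ring[(e - 1) % m])
                bc.append(ring[e])
                bn.append(ring[(e + 1) % m])
            for a in range(len(cyt)):
                for b in range(a + 1, len(cyt)):
                    pres_i.append(cyt[a])
                    pres_j.append(cyt[b])
        self.turg_w = np.asarray(turg_w, dtype=np.intp)
        self.turg_c = np.asarray(turg_c, dtype=np.intp)
        self.ext_i = np.asarray(ext_i, dtype=np.intp)
        self.ext_j = np.asarray(ext_j, dtype=np.intp)
        self.ext_k = np.asarray(ext_k, dtype=float)
        self.bend_prev = np.asarray(bp, dtype=np.intp)
        self.bend_ctr = np.asarray(bc, dtype=np.intp)
        self.bend_next = np.asarray(bn, dtype=np.intp)
        self.pres_i = np.asarray(pres_i, dtype=np.intp)
        self.pres_j = np.asarray(pres_j, dtype=np.intp)
        self.version = t.topology_version
        self.refresh_neighbors()

    def refresh_neighbors(self) -> None:
        """Rebuild volume-exclusion and adhesion pair lists from positions."""
        t = self.tissue
        index = self.index
        wall_idx = np.flatnonzero(self.wall_mask)
        cell_of = np.array(
            [t.nodes[self.node_ids[k]].cell_id for k in range(len(self.node_ids))]
        )
        if len(wall_idx) >= 2:
            tree = cKDTree(self.pos[wall_idx])
            cand = tree.query_pairs(self.params.ve_cutoff, output_type="ndarray")
            if len(cand):
                a = wall_idx[cand[:, 0]]
                b = wall_idx[cand[:, 1]]
                cross = cell_of[a] != cell_of[b]
                self.ve_i, self.ve_j = a[cross], b[cross]
            else:
                self.ve_i = self.ve_j = np.empty(0, dtype=np.intp)
        else:
            self.ve_i = self.ve_j = np.empty(0, dtype=np.intp)
        pairs = sorted(t.adhesion_pairs)
        self.adh_i = np.asarray([index[a] for a, _ in pairs], dtype=np.intp)
        self.adh_j = np.asarray([index[b] for _, b in pairs], dtype=np.intp)
        bnodes = [k for k, nid in enumerate(self.node_ids) if t.nodes[nid].is_boundary]
        self.boundary_idx = np.asarray(bnodes, dtype=np.intp)
        if self.boundary_forces is None or len(self.boundary_forces) != len(bnodes):
            self.boundary_forces = np.zeros((len(bnodes), 2))

    def set_boundary_forces(self, field_by_node: dict[int, np.ndarray]) -> None:
        self.boundary_forces = np.array(
            [field_by_node.get(self.node_ids[k], np.zeros(2)) for k in self.boundary_idx]
        ).reshape(len(self.boundary_idx), 2)

    def sync_to_tissue(self) -> None:
        for k, nid in enumerate(self.node_ids):
            self.tissue.nodes[nid].position = self.pos[k].copy()

    # -- force assembly -------------------------------------------------
    def _accumulate(self, F, i, j, f, out=None):
        n = F.shape[0]
        F[:, 0] += np.bincount(i, weights=f[:, 0], minlength=n)
        F[:, 1] += np.bincount(i, weights=f[:, 1], minlength=n)
        F[:, 0] -= np.bincount(j, weights=f[:, 0], minlength=n)
        F[:, 1] -= np.bincount(j, weights=f[:, 1], minlength=n)
        if out is not None:
            self._accumulate(out, i, j, f)

    def _pair_morse(self, F, i, j, mp: MorseParams, out=None):
        d = self.pos[i] - self.pos[j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        scale = morse_force_scalar(r, mp.U, mp.V, mp.xi, mp.gamma) / np.where(r == 0, 1.0, r)
        f = np.where(r[:, None] > 0, scale[:, None] * d, 0.0)
        self._accumulate(F, i, j, f, out)

    def _pair_spring(self, F, i, j, k, l_eq, out=None):
        d = self.pos[i] - self.pos[j]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        scale = -(np.asarray(k) * (r - l_eq)) / np.where(r == 0, 1.0, r)
        f = np.where(r[:, None] > 0, scale[:, None] * d, 0.0)
        self._accumulate(F, i, j, f, out)

    def _bending(self, F, out=None):
        kb = self.params.bending_k
        th_eq = self.params.bending_theta_eq
        u = self.pos[self.bend_prev] - self.pos[self.bend_ctr]
        v = self.pos[self.bend_next] - self.pos[self.bend_ctr]
        c = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        d = np.einsum("ij,ij->i", u, v)
        theta = np.arctan2(np.abs(c), d)
        denom = c * c + d * d
        denom = np.where(denom == 0, 1.0, denom)
        s = np.sign(c)
        rot_v = np.stack([v[:, 1], -v[:, 0]], axis=1)
        rot_u = np.stack([-u[:, 1], u[:, 0]], axis=1)
        dth_du = (d[:, None] * s[:, None] * rot_v - np.abs(c)[:, None] * v) / denom[:, None]
        dth_dv = (d[:, None] * s[:, None] * rot_u - np.abs(c)[:, None] * u) / denom[:, None]
        g = (-kb * (theta - th_eq))[:, None]
        fy = g * dth_du
        fz = g * dth_dv
        n = F.shape[0]
        for idx, f in ((self.bend_prev, fy), (self.bend_next, fz), (self.bend_ctr, -(fy + fz))):
            F[:, 0] += np.bincount(idx, weights=f[:, 0], minlength=n)
            F[:, 1] += np.bincount(idx, weights=f[:, 1], minlength=n)
            if out is not None:
                out[:, 0] += np.bincount(idx, weights=f[:, 0], minlength=n)
                out[:, 1] += np.bincount(idx, weights=f[:, 1], minlength=n)

    def forces(self, diagnostics: bool = False) -> ForceAccumulator:
        n = len(self.node_ids)
        F = np.zeros((n, 2))
        breakdown = {t: np.zeros((n, 2)) for t in TERMS} if diagnostics else None
        bd = (lambda t: breakdown[t]) if diagnostics else (lambda t: None)
        p = self.params
        if len(self.turg_w):
            self._pair_morse(F, self.turg_w, self.turg_c, p.turgor, bd("turgor"))
        if len(self.ext_i):
            self._pair_spring(F, self.ext_i, self.ext_j, self.ext_k, p.extensibility.l_eq, bd("extensibility"))
        if len(self.bend_ctr):
            self._bending(F, bd("bending"))
        if len(self.pres_i):
            self._pair_morse(F, self.pres_i, self.pres_j, p.pressure, bd("pressure"))
        if self.ve_i is not None and len(self.ve_i):
            self._pair_morse(F, self.ve_i, self.ve_j, p.volume_exclusion, bd("volume_exclusion"))
        if self.adh_i is not None and len(self.adh_i):
            self._pair_spring(F, self.adh_i, self.adh_j, p.adhesion.k, p.adhesion.l_eq, bd("adhesion"))
        if self.boundary_idx is not None and len(self.boundary_idx):
            F[self.boundary_idx] += self.boundary_forces
            if diagnostics:
                breakdown["boundary"][self.boundary_idx] += self.boundary_forces
        return ForceAccumulator(self.node_ids, F, breakdown)

    def energy(self) -> float:
        """Total potential energy of all interaction terms (µN·µm)."""
        p = self.params
        e = 0.0

        def pair_r(i, j):
            return np.linalg.norm(self.pos[i] - self.pos[j], axis=1)

        if len(self.turg_w):
            e += float(np.sum(morse_energy(pair_r(self.turg_w, self.turg_c), p.turgor.U, p.turgor.V, p.turgor.xi, p.turgor.gamma)))
        if len(self.pres_i):
            e += float(np.sum(morse_energy(pair_r(self.pres_i, self.pres_j), p.pressure.U, p.pressure.V, p.pressure.xi, p.pressure.gamma)))
        if self.ve_i is not None and len(self.ve_i):
            e += float(np.sum(morse_energy(pair_r(self.ve_i, self.ve_j), p.volume_exclusion.U, p.volume_exclusion.V, p.volume_exclusion.xi, p.volume_exclusion.gamma)))
        if len(self.ext_i):
            e += float(np.sum(0.5 * self.ext_k * (pair_r(self.ext_i, self.ext_j) - p.extensibility.l_eq) ** 2))
        if self.adh_i is not None and len(self.adh_i):
            e += float(np.sum(linear_spring_energy(pair_r(self.adh_i, self.adh_j), p.adhesion.k, p.adhesion.l_eq)))
        if len(self.bend_ctr):
            u = self.pos[self.bend_prev] - self.pos[self.bend_ctr]
            v = self.pos[self.bend_next] - self.pos[self.bend_ctr]
            c = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
            d = np.einsum("ij,ij->i", u, v)
            theta = np.arctan2(np.abs(c), d)
            e += float(np.sum(0.5 * p.bending_k * (theta - p.bending_theta_eq) ** 2))
        return e

    def relax(self, tol: float = 1e-5, max_iter: int = 20000) -> float:
        """Drive the tissue to a local energy minimum (quasi-Newton descent).

        Neighbour lists are frozen during the descent.  Returns the final
        maximum force component (µN).  Unlike :meth:`integrate`, this does
        not represent time passing; it is for preparing equilibria.
        """
        from scipy.optimize import minimize

        shape = self.pos.shape

        def fun(x):
            self.pos = x.reshape(shape)
            return self.energy()

        def jac(x):
            self.pos = x.reshape(shape)
            return -self.forces().total.ravel()

        res = minimize(
            fun,
            self.pos.ravel(),
            jac=jac,
            method="L-BFGS-B",
            options={"gtol": tol, "ftol": 1e-16, "maxiter": max_iter},
        )
        self.pos = res.x.reshape(shape)
        return float(np.abs(self.forces().total).max())

    # -- integration -----------------------------------------------------
    def integrate(
        self,
        dt: float,
        n_steps: int = 1,
        noise_amplitude: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        """Advance positions by ``n_steps`` forward-Euler steps of ``dt`` s.

        The printed equations of motion contain forces only, so the
        default dynamics are deterministic; ``noise_amplitude`` (µN)
        optionally adds a white thermal force for exploratory use.
        """
        if dt <= 0:
            raise ConfigError("dt must be positive")
        inv_eta = (dt / self.eta)[:, None]
        if noise_amplitude > 0.0 and rng is None:
            raise ConfigError("noisy integration requires an rng")
        for _ in range(n_steps):
            F = self.forces().total
            if noise_amplitude > 0.0:
                F = F + noise_amplitude * rng.standard_normal(F.shape)
            self.pos += F * inv_eta
        if not np.all(np.isfinite(self.pos)):
            bad = int(np.argmax(~np.isfinite(self.pos).all(axis=1)))
            raise NumericalInstabilityError(
                f"non-finite position at node {self.node_ids[bad]}"
            )
        self.tissue.time_hours += dt * n_steps / 3600.0


def _bottom_cells(t: Tissue) -> set[int]:
    """Cells in the bottom layer of the section (damping ×10)."""
    if not t.cells:
        return set()
    ys = {cid: t.cell_centroid(cid)[1] for cid in t.cells}
    diam = t.mean_cell_diameter()
    ymin = min(ys.values())
    return {cid for cid, y in ys.items() if y < ymin + 0.6 * diam}


# ----------------------------------------------------------------------
# convenience tissue-level API
# ----------------------------------------------------------------------

def assemble_forces(
    tissue: Tissue,
    params: PotentialParams,
    boundary_force_field: dict[int, np.ndarray] | None = None,
    diagnostics: bool = False,
) -> ForceAccumulator:
    """Compute the full force field on every node of a tissue."""
    if params is None:
        raise ConfigError("missing mechanical parameter block")
    state = MechanicalState(tissue, params)
    if boundary_force_field:
        state.set_boundary_forces(boundary_force_field)
    return state.forces(diagnostics=diagnostics)


def step(
    tissue: Tissue,
    params: PotentialParams,
    dt: float,
    n_steps: int = 1,
    boundary_force_field: dict[int, np.ndarray] | None = None,
) -> Tissue:
    """Advance a tissue by forward-Euler overdamped steps (in place)."""
    state = MechanicalState(tissue, params)
    if boundary_force_field:
        state.set_boundary_forces(boundary_force_field)
    state.integrate(dt, n_steps)
    state.sync_to_tissue()
    return tissue
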