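"""Simulation driver: configuration, main loop, and experiments.

The main loop couples the submodels at three cadences: forces are
integrated every mechanical step (Δt ≈ 0.4 s); adhesion, volume-exclusion
neighbours, boundary-node flags and growth/division bookkeeping are
refreshed every ``adhesion_refresh_steps`` steps (cycle-progress rates
are constant between signal refreshes, so batching the bookkeeping at
this cadence is exact); signal centres, concentrations, metrics and
snapshots are refreshed every ``snapshot_interval_hours``.

Identical (config, tissue, seed) gives identical outputs; all randomness
flows through counter-based streams keyed by the seed.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rng as rngmod
from .boundary import BoundaryForceSpec, apply_boundary_force, identify_boundary_nodes
from .generate import GeneratorParams, generate_initial_tissue, _apex_of
from .growth import (
    GrowthParams,
    advance_cycle,
    apply_polarization,
    choose_division_plane,
    execute_division,
    execute_out_of_plane_division,
    insert_wall_nodes,
    plane_angle_to_surface,
    relabel_corpus,
    relabel_zones,
    sample_polarization,
)
from .mechanics import MechanicalState, NumericalInstabilityError
from .metrics import MetricSeries
from .signaling import SignalParams, assign_concentrations, place_signal_centres
from .tissue import ConfigError, PotentialParams, Tissue

log = logging.getLogger("samsce")

VARIANTS = ("2d", "p3d")


@dataclass
class SimConfig:
    """Full configuration of one simulation run."""

    variant: str = "p3d"
    boundary_condition: str = "average"  # free|low|average|high|2x
    boundary_pressure_mpa: float | None = None  # overrides the named condition
    boundary_r_ex_um: float = 80.1
    boundary_w_um: float = 7.09
    boundary_direction_blend: float = 0.5
    # multiplier on the total boundary-force magnitude; scaled-down domes
    # use the shell formula |F| = (r_ex/2)·w·P0 with their smaller r_ex,
    # i.e. the same pressures produce proportionally less tension
    boundary_magnitude_scale: float = 1.0
    duration_hours: float = 40.0
    dt_seconds: float = 0.4
    snapshot_interval_hours: float = 0.5
    adhesion_refresh_steps: int = 25
    seed: int = 0
    centrality_beta: float = 1.0
    potentials: PotentialParams = field(default_factory=PotentialParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    signaling: SignalParams = field(default_factory=SignalParams)
    generator: GeneratorParams = field(default_factory=GeneratorParams)

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        if self.duration_hours < 0 or self.dt_seconds <= 0 or self.snapshot_interval_hours <= 0:
            raise ConfigError("duration, dt and snapshot interval must be positive")
        self.potentials.validate()
        self.growth.validate()
        self.signaling.validate()

    def boundary_spec(self) -> BoundaryForceSpec:
        if self.boundary_pressure_mpa is not None:
            spec = BoundaryForceSpec.from_pressure(
                self.boundary_pressure_mpa,
                r_ex=self.boundary_r_ex_um,
                w=self.boundary_w_um,
                direction_blend=self.boundary_direction_blend,
            )
        else:
            spec = BoundaryForceSpec.from_condition(
                self.boundary_condition,
                r_ex=self.boundary_r_ex_um,
                direction_blend=self.boundary_direction_blend,
            )
        spec.total_magnitude *= self.boundary_magnitude_scale
        return spec


@dataclass
class SimResult:
    tissue: Tissue
    metrics: MetricSeries
    division_log: pd.DataFrame
    config: SimConfig
    halted: bool = False

    @property
    def metric_frame(self) -> pd.DataFrame:
        return self.metrics.to_frame()


def run_simulation(config: SimConfig, tissue: Tissue | None = None) -> SimResult:
    """Run one simulation; returns the final tissue, metrics and division log."""
    config.validate()
    seed = config.seed
    if tissue is None:
        tissue = generate_initial_tissue(
            seed=seed,
            params=config.generator,
            potential_params=config.potentials,
            growth_params=config.growth,
            signal_params=config.signaling,
            variant=config.variant,
        )
    pp = config.potentials
    gp = config.growth
    spec = config.boundary_spec()

    series = MetricSeries()
    div_rows: list[dict] = []
    halted = False

    state = MechanicalState(tissue, pp)
    _refresh_boundary(tissue, state, spec)
    series.record(tissue)

    total_steps = int(round(config.duration_hours * 3600.0 / config.dt_seconds))
    K = max(int(config.adhesion_refresh_steps), 1)
    snap_interval_steps = max(
        int(round(config.snapshot_interval_hours * 3600.0 / config.dt_seconds)), 1
    )
    done = 0
    next_snapshot = snap_interval_steps
    while done < total_steps:
        k = min(K, total_steps - done, next_snapshot - done)
        try:
            state.integrate(config.dt_seconds, k)
        except NumericalInstabilityError as exc:
            warnings.warn(f"halting run: {exc}")
            halted = True
            state.pos = np.nan_to_num(state.pos, posinf=0.0, neginf=0.0)
            state.sync_to_tissue()
            break
        done += k
        state.sync_to_tissue()
        dt_hours = k * config.dt_seconds / 3600.0
        changed = _growth_phase(tissue, pp, gp, config.variant, seed, dt_hours, div_rows)
        tissue.apex = _apex_of(tissue)
        relabel_zones(tissue, gp)
        relabel_corpus(tissue, gp)
        identify_boundary_nodes(tissue)
        if changed or tissue.topology_version != state.version:
            from .tissue import refresh_adhesion

            refresh_adhesion(tissue, pp)
            state.rebuild()
        else:
            state.refresh_neighbors()
        _refresh_boundary(tissue, state, spec)
        if done >= next_snapshot:
            place_signal_centres(tissue, params=config.signaling)
            assign_concentrations(tissue, config.signaling)
            series.record(tissue)
            next_snapshot += snap_interval_steps

    div_log = pd.DataFrame(
        div_rows,
        columns=["time_hours", "cell_id", "layer", "zone", "kind", "angle_deg", "daughters"],
    )
    log.info(
        "run finished: t=%.2f h, %d cells, %d divisions, halted=%s",
        tissue.time_hours,
        len(tissue.cells),
        len(div_log),
        halted,
    )
    return SimResult(tissue=tissue, metrics=series, division_log=div_log, config=config, halted=halted)


def _refresh_boundary(tissue: Tissue, state: MechanicalState, spec: BoundaryForceSpec) -> None:
    if spec.total_magnitude == 0.0:
        return
    try:
        field_by_node = apply_boundary_force(tissue, spec)
    except ValueError as exc:
        warnings.warn(f"boundary force skipped this interval: {exc}")
        return
    state.set_boundary_forces(field_by_node)


def _growth_phase(tissue, pp, gp, variant, seed, dt_hours, div_rows) -> bool:
    """Advance cycles, insert nodes, and execute due divisions; True if topology changed."""
    v0 = tissue.topology_version
    for cell in list(tissue.cells.values()):
        if cell.id not in tissue.cells:
            continue
        due = advance_cycle(cell, dt_hours, gp, tissue, seed=seed)
        if not due:
            continue
        if cell.polarization == "out_of_plane":
            execute_out_of_plane_division(cell, tissue, gp)
            div_rows.append(
                {
                    "time_hours": tissue.time_hours,
                    "cell_id": cell.id,
                    "layer": cell.layer,
                    "zone": cell.zone,
                    "kind": "out_of_plane",
                    "angle_deg": np.nan,
                    "daughters": (cell.id,),
                }
            )
            _resample(cell, tissue, pp, gp, variant, seed)
            continue
        r_plane = rngmod.stream(seed, rngmod.DIVISION_PLANE, cell.id, cell.division_events)
        cell.division_events += 1
        plane = choose_division_plane(cell, tissue, pp, gp, rng=r_plane)
        if plane is None:
            cell.cycle_progress = 1.0  # deferred; retry next pass
            continue
        centroid = tissue.cell_centroid(cell.id)
        try:
            da, db = execute_division(cell, plane, tissue, pp)
        except Exception as exc:  # geometry failure: defer
            warnings.warn(f"division of cell {cell.id} failed ({exc}); deferred")
            cell.cycle_progress = 1.0
            continue
        angle = plane_angle_to_surface(plane[1], centroid, tissue)
        div_rows.append(
            {
                "time_hours": tissue.time_hours,
                "cell_id": cell.id,
                "layer": cell.layer,
                "zone": cell.zone,
                "kind": "in_plane",
                "angle_deg": angle,
                "daughters": (da.id, db.id),
            }
        )
        for d in (da, db):
            _resample(d, tissue, pp, gp, variant, seed)
    for cell in tissue.cells.values():
        if (
            len(cell.wall_ring) < gp.max_wall_nodes
            and tissue.cell_area(cell.id) < gp.wall_insertion_area_cap * cell.target_area
        ):
            insert_wall_nodes(cell, tissue, pp, gp.wall_strain_threshold)
    return tissue.topology_version != v0


def _resample(cell, tissue, pp, gp, variant, seed) -> None:
    r = rngmod.stream(seed, rngmod.POLARIZATION, cell.id, cell.polarization_events)
    cell.polarization_events += 1
    cell.polarization = sample_polarization(cell, r, gp, variant=variant)
    apply_polarization(cell, tissue, pp, gp)


def scaled_down_config(scale: float = 4.0, n_columns: int = 8, **overrides) -> SimConfig:
    """A coherent scaled-down version of the full 40 h study.

    All growth time scales (duration, cycle-length bounds, snapshot
    interval) are divided by ``scale`` and the mechanical clock (dt, η)
    is multiplied by it, which leaves the per-step displacement — and
    hence the trajectory per step — unchanged while preserving roughly
    one division per cell over the run.  Mechanical relaxation (τ ≈ η/k,
    a few represented seconds) stays many orders of magnitude faster
    than the cell cycle, so the separation of time scales that the full
    study relies on is intact.
    """
    cfg = SimConfig(**overrides)
    cfg.duration_hours = 40.0 / scale
    cfg.dt_seconds = 0.4 * scale
    cfg.snapshot_interval_hours = 0.5 / scale * 2
    cfg.potentials.eta_base = cfg.potentials.eta_base * scale
    cfg.growth.cycle_hours_max /= scale
    cfg.growth.cycle_hours_min /= scale
    cfg.growth.cycle_wus_slope /= scale
    cfg.generator.n_columns = n_columns
    # r_ex is the absolute curvature radius of a full-size meristem; a
    # smaller dome must target a proportionally smaller radius (the force
    # magnitudes are kept as the study conditions)
    full_width = (SimConfig().generator.n_columns + 2) * SimConfig().generator.cell_size
    width = (n_columns + 2) * cfg.generator.cell_size
    cfg.boundary_r_ex_um = cfg.boundary_r_ex_um * width / full_width
    cfg.boundary_magnitude_scale = width / full_width
    return cfg


# ----------------------------------------------------------------------
# experiments
# ----------------------------------------------------------------------

@dataclass
class ExperimentSpec:
    """A set of (variant, boundary condition) arms with replicates."""

    arms: list[tuple[str, str]]
    replicates: int = 3
    base_seed: int = 0
    config: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        for variant, cond in self.arms:
            if variant not in VARIANTS:
                raise ConfigError(f"unknown variant {variant!r}")


@dataclass
class ExperimentResult:
    summary: pd.DataFrame
    runs: list[SimResult | None]
    failures: list[tuple[int, int, str]]


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Run all arms × replicates with derived seeds; summarize per arm."""
    spec.validate()
    runs: list[SimResult | None] = []
    failures: list[tuple[int, int, str]] = []
    rows = []
    for arm_idx, (variant, cond) in enumerate(spec.arms):
        arm_results = []
        for rep in range(spec.replicates):
            cfg = copy.deepcopy(spec.config)
            cfg.variant = variant
            cfg.boundary_condition = cond
            cfg.seed = rngmod.replicate_seed(spec.base_seed, arm_idx, rep)
            try:
                res = run_simulation(cfg)
            except Exception as exc:
                failures.append((arm_idx, rep, str(exc)))
                runs.append(None)
                continue
            runs.append(res)
            arm_results.append(res)
        rows.append(_summarize_arm(variant, cond, arm_results))
    return ExperimentResult(summary=pd.DataFrame(rows), runs=runs, failures=failures)


def _summarize_arm(variant: str, cond: str, results: list[SimResult]) -> dict:
    row: dict = {"variant": variant, "condition": cond, "n": len(results)}
    if not results:
        return row
    row["disruption_fraction"] = float(np.mean([r.metrics.any_break() for r in results]))
    finals = []
    for r in results:
        df = r.metric_frame
        rc = df[df["metric"] == "relative_curvature"]
        if len(rc):
            finals.append(rc["value"].iloc[-1])
    if finals:
        row["relative_curvature_mean"] = float(np.mean(finals))
        row["relative_curvature_var"] = float(np.var(finals, ddof=1)) if len(finals) > 1 else 0.0
    div = pd.concat([r.division_log for r in results], ignore_index=True)
    apical = div[(div["kind"] == "in_plane") & (div["layer"] == "apical_corpus")]
    if len(apical):
        row["percent_periclinal_apical"] = 100.0 * float((apical["angle_deg"] < 45.0).mean())
        row["n_apical_divisions"] = int(len(apical))
    for layer in ("L1", "L2"):
        vals = []
        for r in results:
            df = r.metric_frame
            ar = df[(df["metric"] == "mean_aspect_ratio") & (df["region"] == layer)]
            if len(ar):
                vals.append(ar["value"].iloc[-1])
        if vals:
            row[f"aspect_ratio_{layer}"] = float(np.mean(vals))
    return row
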