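"""Turn-key scenario runners.

Four experiments, each a thin loop over the engine with scenario-specific
setup and observables:

- ``run_piston``: ideal-gas particles in the two compartments of a 0.5 µm
  box chamber drive a massless rigid piston plane (drift for unequal masses,
  1D random walk for equal).
- ``run_fluctuating_membrane``: a clamped flat membrane with one interior
  vertex stretched to a spike, relaxing under elastic energy and thermal
  fluctuations.
- ``run_cell_spreading``: a ruffled icosphere carrying mobile receptors
  spreads on a ligand-coated plane through distance-gated binding, adhesion
  feedback and pressure.
- ``run_cell_cell``: a deformable sphere pressed by a rigid one (reduced
  cell-cell contact demo with plastic deformation and optional
  pressure-induced spreading).

Every runner is bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import particles as pt
from . import surface_molecules as sm
from .energetics import (ElasticParams, BendingParams, PressureParams,
                         ThermoParams, isothermal_work)
from .mesh_core import (TriMesh, ParameterError, enclosed_volume,
                        generate_box, generate_flat_grid, generate_icosphere)
from .mc_engine import SimConfig, SimState, step_iteration
from .observables_io import (TrajectoryLog, contact_area,
                             contact_area_to_mesh, echo_config, logger,
                             peak_height)


def _scenario_config(cls, path_or_dict):
    if isinstance(path_or_dict, cls):
        return path_or_dict
    if isinstance(path_or_dict, dict):
        return cls(**path_or_dict)
    from .observables_io import load_config
    return cls(**load_config(path_or_dict))


# ---------------------------------------------------------------------------
# piston

@dataclass
class PistonConfig:
    """Fig-1-style piston chamber: a 0.5 µm cube split by a rigid plane."""
    chamber_side: float = 0.5          # µm
    n_bottom: int = 2000
    n_top: int = 2000
    mass_bottom: float = 0.1           # undefined mass units
    mass_top: float = 0.01
    speed_scale: float = 0.01          # per-axis velocity σ, µm/µs (both sides)
    speed_scale_top: float | None = None
    mobility: float = 0.02             # µm per unit net impulse
    min_gap: float = 0.02              # piston clamp margin, µm
    iterations: int = 5000
    timestep: float = 1.0              # µs
    seed: int = 0
    thermo: ThermoParams = field(default_factory=ThermoParams)
    piston_z0: float | None = None     # default: mid-chamber

    @classmethod
    def from_file(cls, path):
        return _scenario_config(cls, path)


def run_piston(config: PistonConfig | dict | str, seed: int | None = None) -> TrajectoryLog:
    """Run the piston scenario; logs piston z, collision counts, compartment
    volumes, and per-compartment isothermal work every iteration."""
    cfg = _scenario_config(PistonConfig, config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    echo_config(cfg, cfg.seed)
    L = cfg.chamber_side
    chamber = generate_box((0, 0, 0), (L, L, L))
    zp = L / 2.0 if cfg.piston_z0 is None else float(cfg.piston_z0)
    if not 0.0 < zp < L:
        raise ParameterError("piston initial position outside the chamber")
    piston = generate_flat_grid(2, 2, L)
    piston.rigid = True
    piston.translate((0.0, 0.0, zp))

    rng = np.random.default_rng(cfg.seed)
    sst = cfg.speed_scale_top if cfg.speed_scale_top is not None else cfg.speed_scale
    bottom = pt.release_particles(cfg.n_bottom, ((0, 0, 0), (L, L, zp)),
                                  cfg.mass_bottom, speed_scale=cfg.speed_scale,
                                  seed=rng, compartment=pt.BOTTOM)
    top = pt.release_particles(cfg.n_top, ((0, 0, zp), (L, L, L)),
                               cfg.mass_top, speed_scale=sst,
                               seed=rng, compartment=pt.TOP)
    ens = pt.merge(bottom, top)

    v_b0, v_t0 = pt.compartment_volumes(chamber, zp)
    log = TrajectoryLog()
    for it in range(1, cfg.iterations + 1):
        ens.resample_velocities(rng)
        ens, tally = pt.advance_and_collide(ens, chamber, piston, cfg.timestep)
        zp = pt.apply_momentum_kick(piston, tally, cfg.mobility,
                                    z_bounds=(0.0, L), min_gap=cfg.min_gap)
        pt.confine_to_compartments(ens, chamber, zp)
        v_b, v_t = pt.compartment_volumes(chamber, zp)
        log.add(it, piston_z=zp,
                collisions_bottom=tally.bottom_count,
                collisions_top=tally.top_count,
                v_bottom=v_b, v_top=v_t,
                w_bottom=isothermal_work(cfg.thermo, v_b0, v_b),
                w_top=isothermal_work(cfg.thermo, v_t0, v_t),
                n_particles=ens.n)
    return log


def calibrate_piston_mobility(config: PistonConfig, target_D_nm2_us: float,
                              n_seeds: int = 5) -> float:
    """Scale the piston mobility so the equal-mass random walk reproduces a
    target diffusion coefficient (nm²/µs).

    The piston displacement per iteration is proportional to the mobility, so
    D ∝ mobility²; one measurement fixes the scale factor exactly.
    """
    from .observables_io import estimate_diffusion_coefficient
    eq = replace(config, mass_top=config.mass_bottom, speed_scale_top=None)
    series = []
    for s in range(n_seeds):
        lg = run_piston(eq, seed=config.seed + 1000 + s)
        series.append(lg.series("piston_z"))
    fit = estimate_diffusion_coefficient(np.array(series), config.timestep)
    if fit.D <= 0:
        raise RuntimeError("measured diffusion coefficient is zero")
    return config.mobility * float(np.sqrt(target_D_nm2_us / fit.D))


# ---------------------------------------------------------------------------
# fluctuating membrane

@dataclass
class MembraneConfig:
    """Flat clamped membrane with a single stretched point (spike)."""
    nx: int = 20
    ny: int = 20
    side: float = 2.0                  # µm
    spike_height: float = 0.5          # µm
    spike_vertex: int | None = None    # default: vertex nearest the centre
    kappa1: float = 50.0
    kappa2: float = 2.0e6
    sigma: float = 0.01                # node step σ, µm
    iterations: int = 800
    timestep: float = 1.0
    seed: int = 0
    output_cadence: int = 100

    @classmethod
    def from_file(cls, path):
        return _scenario_config(cls, path)


def run_fluctuating_membrane(config: MembraneConfig | dict | str,
                             seed: int | None = None) -> TrajectoryLog:
    """Spike-relaxation scenario; logs peak membrane height per iteration."""
    cfg = _scenario_config(MembraneConfig, config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    echo_config(cfg, cfg.seed)
    mesh = generate_flat_grid(cfg.nx, cfg.ny, cfg.side)  # rest areas: flat
    if cfg.spike_vertex is None:
        centre = np.array([cfg.side / 2, cfg.side / 2, 0.0])
        spike = int(np.argmin(np.linalg.norm(mesh.vertices - centre, axis=1)))
    else:
        spike = int(cfg.spike_vertex)
    if mesh.boundary_vertex[spike]:
        raise ParameterError("spike vertex lies on the clamped boundary")
    mesh.vertices[spike, 2] += cfg.spike_height

    span = max(cfg.side, 4 * abs(cfg.spike_height) + cfg.side)
    sim = SimConfig(timestep=cfg.timestep, iterations=cfg.iterations,
                    box_lo=(0.0, 0.0, -span), box_hi=(cfg.side, cfg.side, span),
                    seed=cfg.seed, sigma=cfg.sigma,
                    elastic=ElasticParams(cfg.kappa1, cfg.kappa2),
                    output_cadence=cfg.output_cadence)
    log = TrajectoryLog()

    interior = ~mesh.boundary_vertex

    def observer(state):
        log.add(state.iteration,
                peak_height=peak_height(state.mesh, 0.0),
                mean_z=float(state.mesh.vertices[:, 2].mean()),
                roughness=float(state.mesh.vertices[interior, 2].std()),
                accepted=state.accepted_moves,
                n_vertices=state.mesh.n_vertices)
        if state.iteration % cfg.output_cadence == 0:
            log.snapshot(state.iteration, state.mesh)

    state = SimState(config=sim, rng=np.random.default_rng(cfg.seed),
                     mesh=mesh, observer=observer)
    log.snapshot(0, mesh)
    for _ in range(cfg.iterations):
        step_iteration(state)
    return log


# ---------------------------------------------------------------------------
# T cell spreading on an activating surface

@dataclass
class SpreadingConfig:
    """Ruffled cell over a ligand-coated plane at z = 0.

    Desk-scale defaults: a ~2500-vertex ruffled icosphere and 5000 molecules
    per surface stand in for the full-scale run (250K molecules, ~12000
    nodes), which remains reachable through these fields.
    """
    subdivisions: int = 4              # 2562 vertices, 5120 faces
    radius: float = 2.0                # µm
    ruffle_amplitude: float = 0.2      # µm, membrane protrusions
    clearance: float = 0.03            # lowest vertex above the plane, µm
    n_mobile: int = 5000               # receptors on the cell
    n_static: int = 5000               # ligands on the surface
    surface_side: float = 5.0          # ligand-coated plane extent, µm
    diffusion: float = 100.0           # receptor D, µm²/s (iteration-time scale)
    rate: float = 1.0e6                # on-rate within pairing distance, 1/s
    pairing_distance: float = 0.05     # µm
    kappa1: float = 20.0
    kappa2: float = 2.0e6
    sigma: float = 0.005
    per_bond_energy: float = 10.0      # kT
    bond_rest_length: float = 0.015    # µm
    pressure_c: float = 0.5
    pressure_inflation: float = 1.15   # target volume / initial volume
                                       # (implicit actin push toward the surface)
    pressure_max_step: float = 0.003   # µm per iteration
    contact_delta: float = 0.05        # µm
    iterations: int = 1000
    timestep: float = 1.0
    seed: int = 0
    output_cadence: int = 100

    @classmethod
    def from_file(cls, path):
        return _scenario_config(cls, path)


def run_cell_spreading(config: SpreadingConfig | dict | str,
                       seed: int | None = None) -> TrajectoryLog:
    """Spreading scenario; logs contact area, cumulative and per-iteration
    bond counts, and mesh snapshots at the configured cadence."""
    cfg = _scenario_config(SpreadingConfig, config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    echo_config(cfg, cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    cell = generate_icosphere(cfg.subdivisions, cfg.radius,
                              cfg.ruffle_amplitude, seed=cfg.seed)
    lift = cfg.clearance - cell.vertices[:, 2].min()
    cell.translate((0.0, 0.0, lift))
    if cell.vertices[:, 2].min() < 0:
        raise ParameterError("cell initially intersects the plane z = 0")

    half = cfg.surface_side / 2.0
    surface = generate_flat_grid(30, 30, cfg.surface_side)
    surface.translate((-half, -half, 0.0))
    surface.rigid = True

    mobile = sm.place_molecules(cell, cfg.n_mobile, "receptor",
                                diffusion_constant=cfg.diffusion, seed=rng)
    static = sm.place_molecules(surface, cfg.n_static, "ligand",
                                diffusion_constant=0.0, seed=rng)
    rule = sm.ReactionRule("receptor", "ligand", rate=cfg.rate,
                           pairing_distance=cfg.pairing_distance)

    v0 = enclosed_volume(cell)
    sim = SimConfig(
        timestep=cfg.timestep, iterations=cfg.iterations,
        box_lo=(-half, -half, 0.0),
        box_hi=(half, half, 2.0 * cfg.radius + 2.0),
        seed=cfg.seed, sigma=cfg.sigma,
        elastic=ElasticParams(cfg.kappa1, cfg.kappa2),
        pressure=PressureParams(c=cfg.pressure_c,
                                v_int=v0 * cfg.pressure_inflation,
                                max_step=cfg.pressure_max_step),
        per_bond_energy=cfg.per_bond_energy,
        bond_rest_length=cfg.bond_rest_length,
        rules=[rule], output_cadence=cfg.output_cadence)

    log = TrajectoryLog()

    def observer(state):
        log.add(state.iteration,
                contact_area=contact_area(state.mesh, 0.0, cfg.contact_delta),
                bonds_total=state.bonds.n,
                bonds_new=state.new_bonds,
                volume=enclosed_volume(state.mesh),
                n_mobile=state.mobile_molecules.n,
                n_static=state.static_molecules.n,
                accepted=state.accepted_moves)
        if state.iteration % cfg.output_cadence == 0:
            log.snapshot(state.iteration, state.mesh)

    state = SimState(config=sim, rng=rng, mesh=cell,
                     mobile_molecules=mobile, static_molecules=static,
                     observer=observer)
    log.snapshot(0, cell)
    for _ in range(cfg.iterations):
        step_iteration(state)
    return log


# ---------------------------------------------------------------------------
# reduced cell-cell contact

@dataclass
class CellCellConfig:
    """Two icospheres: a rigid 'APC' pressed against a deformable cell."""
    subdivisions: int = 2              # 162 vertices each
    radius: float = 1.0                # µm
    gap: float = 0.3                   # initial surface-to-surface gap, µm
    approach_step: float = 0.01        # rigid sphere advance per iteration, µm
    indentation: float = 0.2           # advance beyond first contact, µm
    axis: tuple = (1.0, 0.0, 0.0)
    kappa1: float = 20.0
    kappa2: float = 2.0e6
    sigma: float = 0.005
    pressure_enabled: bool = False
    pressure_c: float = 0.05
    pressure_inflation: float = 1.05
    pressure_max_step: float = 0.002
    contact_delta: float = 0.08        # µm (vertex-to-vertex proximity)
    iterations: int = 250
    timestep: float = 1.0
    seed: int = 0
    output_cadence: int = 50

    @classmethod
    def from_file(cls, path):
        return _scenario_config(cls, path)


def run_cell_cell(config: CellCellConfig | dict | str,
                  seed: int | None = None) -> TrajectoryLog:
    """Reduced cell-cell contact: plastic deformation of one sphere by the
    other, with optional pressure-induced spreading.

    The rigid 'APC' is an icosphere; for the contact push, the separation
    invariant and the contact-area readout it is treated as the analytic
    sphere it approximates (centre + radius), while the Metropolis sweep
    additionally rejects any node move whose incident faces would cross the
    rigid mesh (segment-triangle tests via the spatial index).
    """
    cfg = _scenario_config(CellCellConfig, config)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    echo_config(cfg, cfg.seed)
    axis = np.asarray(cfg.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    cell = generate_icosphere(cfg.subdivisions, cfg.radius, 0.0, seed=cfg.seed)
    rigid = generate_icosphere(cfg.subdivisions, cfg.radius, 0.0, seed=cfg.seed)
    rigid.rigid = True
    rigid_centre = axis * (2.0 * cfg.radius + cfg.gap)
    rigid.translate(rigid_centre)
    if cfg.gap <= 0:
        raise ParameterError("spheres initially overlap (gap must be > 0)")

    span = 4.0 * cfg.radius + cfg.gap
    sim = SimConfig(timestep=cfg.timestep, iterations=cfg.iterations,
                    box_lo=(-span, -span, -span), box_hi=(span, span, span),
                    seed=cfg.seed, sigma=cfg.sigma,
                    elastic=ElasticParams(cfg.kappa1, cfg.kappa2),
                    pressure=(PressureParams(
                        c=cfg.pressure_c,
                        v_int=enclosed_volume(cell) * cfg.pressure_inflation,
                        max_step=cfg.pressure_max_step)
                        if cfg.pressure_enabled else None))

    log = TrajectoryLog()
    approach_total = cfg.gap + cfg.indentation
    moved = 0.0

    def observer(state):
        d = np.linalg.norm(state.mesh.vertices - rigid_centre, axis=1)
        close = (d - cfg.radius) <= cfg.contact_delta
        face_close = close[state.mesh.faces].all(axis=1)
        from .mesh_core import triangle_areas
        area = (float(triangle_areas(state.mesh.vertices,
                                     state.mesh.faces[face_close]).sum())
                if face_close.any() else 0.0)
        log.add(state.iteration,
                contact_area=area,
                min_separation=float(d.min() - cfg.radius),
                rigid_x=float(rigid_centre @ axis),
                volume=enclosed_volume(state.mesh),
                n_vertices=state.mesh.n_vertices)
        if state.iteration % cfg.output_cadence == 0:
            log.snapshot(state.iteration, state.mesh)

    def expel(mesh):
        """Contact push: expel vertices the advancing sphere has overtaken."""
        rel = mesh.vertices - rigid_centre
        dist = np.linalg.norm(rel, axis=1)
        inside = dist < cfg.radius
        if inside.any():
            mesh.vertices[inside] = (
                rigid_centre + rel[inside]
                * ((cfg.radius + 1e-9) / dist[inside])[:, None])

    state = SimState(config=sim, rng=np.random.default_rng(cfg.seed),
                     mesh=cell, obstacles=[rigid], observer=observer)
    log.snapshot(0, cell)
    for _ in range(cfg.iterations):
        if moved < approach_total - 1e-12:
            step = min(cfg.approach_step, approach_total - moved)
            if step > 0:
                rigid.translate(-axis * step)
                rigid_centre = rigid_centre - axis * step
                moved += step
        expel(state.mesh)
        step_iteration(state)
    return log
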