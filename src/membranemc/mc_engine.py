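"""Per-iteration Metropolis Monte Carlo loop.

Every iteration advances the system in a fixed order:

1. particle moves with collision/impulse accumulation (piston scenarios),
2. surface-molecule diffusion,
3. pairing and binding,
4. one attempted Metropolis move per non-clamped mesh vertex, in a seeded
   random order (ΔE from the faces incident to the vertex: elastic +
   adhesion, optional bending),
5. pressure displacement,
6. observable recording.

Node moves are accepted with probability 1 if ΔE <= 0 and exp(-ΔE) otherwise
(energies in kT).  The hot sequential sweep is JIT-compiled with numba; a
pure-Python sweep with identical RNG consumption backs the API-level
operations, carries the mesh-crossing constraint against other meshes, and is
the path used whenever obstacles or bending are active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import TriMesh, ParameterError, enclosed_volume
from .energetics import (ElasticParams, BendingParams, PressureParams,
                         ThermoParams, bending_energy, pressure_displacement)
from . import surface_molecules as sm

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn
        return wrap


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    """Engine-level configuration shared by all scenarios.

    Lengths µm, time µs, energies kT.  ``box`` is the movement space: node
    moves that leave it are rejected outright.
    """
    timestep: float = 1.0
    iterations: int = 1000
    box_lo: tuple = (0.0, 0.0, 0.0)
    box_hi: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    sigma: float = 0.005            # node proposal step σ per axis, µm
    area_tol: float = 1e-9          # degenerate-face rejection threshold, µm²
    crossing_tol: float = 1e-9      # mesh-crossing tolerance, µm
    elastic: ElasticParams = field(default_factory=ElasticParams)
    bending: BendingParams = field(default_factory=BendingParams)
    pressure: PressureParams | None = None
    thermo: ThermoParams = field(default_factory=ThermoParams)
    per_bond_energy: float = 10.0   # adhesion energy per bond, kT
    bond_rest_length: float = 0.015  # µm (~receptor-ligand bond length)
    rules: list = field(default_factory=list)
    output_cadence: int = 100

    def __post_init__(self):
        if self.timestep <= 0:
            raise ParameterError("timestep must be positive")
        if self.sigma < 0:
            raise ParameterError("node step sigma must be non-negative")
        lo = np.asarray(self.box_lo, dtype=float)
        hi = np.asarray(self.box_hi, dtype=float)
        if (hi <= lo).any():
            raise ParameterError("box must have positive extent on every axis")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "elastic" in d and isinstance(d["elastic"], dict):
            d["elastic"] = ElasticParams(**d["elastic"])
        if "bending" in d and isinstance(d["bending"], dict):
            d["bending"] = BendingParams(**d["bending"])
        if "pressure" in d and isinstance(d["pressure"], dict):
            d["pressure"] = PressureParams(**d["pressure"])
        if "thermo" in d and isinstance(d["thermo"], dict):
            d["thermo"] = ThermoParams(**d["thermo"])
        if "rules" in d:
            d["rules"] = [r if isinstance(r, sm.ReactionRule)
                          else sm.ReactionRule.parse(**r) for r in d["rules"]]
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MoveProposal:
    vertex_id: int
    displacement: np.ndarray
    delta_E: float


# ---------------------------------------------------------------------------
# acceptance

def metropolis_probability(delta_E: float) -> float:
    """Analytic acceptance probability: 1 for ΔE <= 0, exp(-ΔE) otherwise."""
    if math.isnan(delta_E):
        raise ValueError("NaN energy change")
    return 1.0 if delta_E <= 0.0 else math.exp(-delta_E)


def metropolis_accept(delta_E: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion (kT units).  ΔE = 0 is always accepted."""
    if math.isnan(delta_E):
        raise ValueError("NaN energy change")
    if delta_E <= 0.0:
        return True
    return rng.random() < math.exp(-delta_E)


# ---------------------------------------------------------------------------
# simulation state

@dataclass
class SimState:
    """Everything step_iteration touches.  Scenario runners assemble one."""
    config: SimConfig
    rng: np.random.Generator
    mesh: TriMesh | None = None              # active deformable membrane
    obstacles: list = field(default_factory=list)   # meshes it must not cross
    particles: object = None
    chamber: object = None
    piston: TriMesh | None = None
    piston_mobility: float = 0.0
    mobile_molecules: sm.SurfaceMoleculeSet | None = None
    static_molecules: sm.SurfaceMoleculeSet | None = None
    bonds: sm.BondTable = field(default_factory=sm.BondTable)
    iteration: int = 0
    last_tally: object = None
    observer: object = None                  # callable(state) -> None
    initialized: bool = True
    new_bonds: int = 0
    accepted_moves: int = 0

    # vertex -> bond CSR, rebuilt whenever bonds change
    _vb_csr: tuple | None = field(default=None, init=False, repr=False)

    def vertex_bond_csr(self):
        if self._vb_csr is None:
            nv = self.mesh.n_vertices
            if self.bonds.n == 0:
                self._vb_csr = (np.zeros(nv + 1, dtype=np.int64),
                                np.empty(0, dtype=np.int64))
            else:
                verts = self.mesh.faces[self.bonds.face].ravel()     # (3B,)
                bond_ids = np.repeat(np.arange(self.bonds.n), 3)
                order = np.argsort(verts, kind="stable")
                ptr = np.zeros(nv + 1, dtype=np.int64)
                np.add.at(ptr, verts + 1, 1)
                self._vb_csr = (np.cumsum(ptr), bond_ids[order])
        return self._vb_csr

    def invalidate_bonds(self):
        self._vb_csr = None


# ---------------------------------------------------------------------------
# local energy change (Python reference path)

def _star_tris(mesh: TriMesh, vertex_id: int, position):
    """Incident face ids and their vertex coordinates with ``vertex_id``
    placed at ``position``."""
    ptr, fidx = mesh.vertex_face_incidence()
    inc = fidx[ptr[vertex_id]:ptr[vertex_id + 1]]
    tri = mesh.vertices[mesh.faces[inc]].copy()
    tri[mesh.faces[inc] == vertex_id] = position
    return inc, tri


def _local_energy(state: SimState, vertex_id: int, position) -> float:
    """Elastic + adhesion energy of the faces/bonds incident to a vertex,
    evaluated with the vertex at ``position`` (other vertices fixed)."""
    mesh = state.mesh
    inc, tri = _star_tris(mesh, vertex_id, position)
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0],
                                          tri[:, 2] - tri[:, 0]), axis=1)
    ar = mesh.rest_area[inc]
    kappa = state.config.elastic.kappa_eff
    e = float(np.sum(kappa / (2.0 * ar * ar) * (areas - ar) ** 2))
    bptr, bidx = state.vertex_bond_csr()
    bids = bidx[bptr[vertex_id]:bptr[vertex_id + 1]]
    if len(bids):
        bonds = state.bonds
        btri = mesh.vertices[mesh.faces[bonds.face[bids]]].copy()
        btri[mesh.faces[bonds.face[bids]] == vertex_id] = position
        anchor_m = np.einsum("ni,nij->nj", bonds.bary[bids], btri)
        d = np.linalg.norm(anchor_m - bonds.anchor[bids], axis=1)
        e += float(np.sum(0.5 * bonds.k[bids] * (d - bonds.rest[bids]) ** 2))
    return e


def _min_incident_area(state: SimState, vertex_id: int, position) -> float:
    _, tri = _star_tris(state.mesh, vertex_id, position)
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0],
                                          tri[:, 2] - tri[:, 0]), axis=1)
    return float(areas.min())


def propose_node_move(state: SimState, vertex_id: int,
                      rng: np.random.Generator) -> MoveProposal:
    """Isotropic Gaussian displacement proposal with local ΔE.

    ΔE is recomputed only over the faces (and bonds) incident to the vertex —
    all other face areas are untouched by construction.  Clamped (boundary)
    vertices yield a no-op proposal; rigid meshes are a precondition error.
    """
    mesh = state.mesh
    if mesh.rigid:
        raise ParameterError("cannot propose node moves on a rigid mesh")
    if mesh.boundary_vertex[vertex_id]:
        return MoveProposal(vertex_id, np.zeros(3), 0.0)
    disp = rng.normal(0.0, state.config.sigma, size=3)
    old = mesh.vertices[vertex_id]
    e_old = _local_energy(state, vertex_id, old)
    e_new = _local_energy(state, vertex_id, old + disp)
    dE = e_new - e_old
    if state.config.bending.enabled:
        # bending couples two rings; fall back to a full-mesh difference
        e0 = bending_energy(mesh, state.config.bending)
        mesh.vertices[vertex_id] = old + disp
        e1 = bending_energy(mesh, state.config.bending)
        mesh.vertices[vertex_id] = old
        dE += e1 - e0
    return MoveProposal(vertex_id, disp, dE)


# ---------------------------------------------------------------------------
# constraints

def segment_triangle_intersect(p0, p1, a, b, c, eps: float = 1e-12) -> bool:
    """Möller–Trumbore segment/triangle intersection test."""
    d = p1 - p0
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = e1 @ h
    if abs(det) < eps:
        return False
    inv = 1.0 / det
    s = p0 - a
    u = inv * (s @ h)
    if u < -eps or u > 1.0 + eps:
        return False
    q = np.cross(s, e1)
    v = inv * (d @ q)
    if v < -eps or u + v > 1.0 + eps:
        return False
    t = inv * (e2 @ q)
    return bool(-eps <= t <= 1.0 + eps)


def triangles_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Non-coplanar triangle/triangle intersection via mutual edge tests."""
    for i in range(3):
        if segment_triangle_intersect(t1[i], t1[(i + 1) % 3], *t2):
            return True
        if segment_triangle_intersect(t2[i], t2[(i + 1) % 3], *t1):
            return True
    return False


def _segments_cross_triangles(p0, p1, tri, eps: float = 1e-12) -> bool:
    """Any-intersection test of S segments against T triangles, batched
    Möller–Trumbore over the full S×T grid."""
    d = (p1 - p0)[:, None, :]                       # (S, 1, 3)
    e1 = (tri[:, 1] - tri[:, 0])[None, :, :]        # (1, T, 3)
    e2 = (tri[:, 2] - tri[:, 0])[None, :, :]
    h = np.cross(d, e2)
    det = np.einsum("stk,stk->st", np.broadcast_to(e1, h.shape), h)
    s = p0[:, None, :] - tri[None, :, 0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        u = inv * np.einsum("stk,stk->st", s, h)
        q = np.cross(s, np.broadcast_to(e1, s.shape))
        v = inv * np.einsum("stk,stk->st", np.broadcast_to(d, q.shape), q)
        t = inv * np.einsum("stk,stk->st", np.broadcast_to(e2, q.shape), q)
        hit = ((np.abs(det) >= eps) & (u >= -eps) & (u <= 1 + eps)
               & (v >= -eps) & (u + v <= 1 + eps)
               & (t >= -eps) & (t <= 1 + eps))
    return bool(hit.any())


def _star_crosses_obstacles(state: SimState, vertex_id: int,
                            new_pos: np.ndarray) -> bool:
    """Would the faces incident to ``vertex_id`` (with the vertex moved to
    ``new_pos``) intersect any obstacle mesh?"""
    mesh = state.mesh
    tol = state.config.crossing_tol
    ptr, fidx = mesh.vertex_face_incidence()
    inc = fidx[ptr[vertex_id]:ptr[vertex_id + 1]]
    star = mesh.vertices[mesh.faces[inc]].copy()
    star[mesh.faces[inc] == vertex_id] = new_pos
    local_r = float(np.linalg.norm(star.reshape(-1, 3) - new_pos,
                                   axis=1).max())
    for other in state.obstacles:
        tree, bound_c, bound_r, reach = _obstacle_index(other)
        if np.linalg.norm(new_pos - bound_c) - local_r > bound_r + tol:
            continue
        cand = tree.query_ball_point(new_pos, local_r + reach + tol)
        if not cand:
            continue
        obs = other.vertices[other.faces[np.asarray(cand)]]
        # star edges vs obstacle triangles
        p0 = star[:, [0, 1, 2], :].reshape(-1, 3)
        p1 = star[:, [1, 2, 0], :].reshape(-1, 3)
        if _segments_cross_triangles(p0, p1, obs):
            return True
        # obstacle edges vs star triangles
        q0 = obs[:, [0, 1, 2], :].reshape(-1, 3)
        q1 = obs[:, [1, 2, 0], :].reshape(-1, 3)
        if _segments_cross_triangles(q0, q1, star):
            return True
    return False


def constraint_check(state: SimState, proposal: MoveProposal) -> bool:
    """Movement-space, degeneracy and mesh-crossing checks for a proposal.

    False if the moved vertex leaves the box, any incident face would drop
    below the area tolerance, or any incident face would intersect a face of
    another mesh (nearby faces found with a k-d tree on face centroids).
    """
    cfg = state.config
    mesh = state.mesh
    new_pos = mesh.vertices[proposal.vertex_id] + proposal.displacement
    lo = np.asarray(cfg.box_lo)
    hi = np.asarray(cfg.box_hi)
    if (new_pos < lo).any() or (new_pos > hi).any():
        return False
    if _min_incident_area(state, proposal.vertex_id, new_pos) < cfg.area_tol:
        return False
    if state.obstacles and _star_crosses_obstacles(state, proposal.vertex_id,
                                                   new_pos):
        return False
    return True


_obstacle_cache: dict = {}


def _obstacle_index(other: TriMesh):
    """k-d tree over an obstacle mesh's face centroids plus a bounding
    sphere, cached per geometry (rebuilt when the mesh translates)."""
    key = (id(other), other.vertices[0, 0], other.vertices[-1, -1])
    hit = _obstacle_cache.get(id(other))
    if hit is not None and hit[0] == key:
        return hit[1], hit[2], hit[3], hit[4]
    tris = other.vertices[other.faces]
    centroids = tris.mean(axis=1)
    reach = float(np.linalg.norm(tris - centroids[:, None], axis=2).max())
    tree = cKDTree(centroids)
    bound_c = other.vertices.mean(axis=0)
    bound_r = float(np.linalg.norm(other.vertices - bound_c, axis=1).max())
    _obstacle_cache[id(other)] = (key, tree, bound_c, bound_r, reach)
    return tree, bound_c, bound_r, reach


# ---------------------------------------------------------------------------
# fast sequential sweep (numba)

@njit(cache=True)
def _sweep_kernel(pos, faces, rest, vf_ptr, vf_idx, clamped, order, disp,
                  urand, kappa, area_tol, lo0, lo1, lo2, hi0, hi1, hi2,
                  b_face, b_bary, b_anchor, b_k, b_rest, vb_ptr, vb_idx):
    accepted = 0
    for oi in range(order.shape[0]):
        v = order[oi]
        if clamped[v]:
            continue
        nx = pos[v, 0] + disp[v, 0]
        ny = pos[v, 1] + disp[v, 1]
        nz = pos[v, 2] + disp[v, 2]
        if nx < lo0 or nx > hi0 or ny < lo1 or ny > hi1 or nz < lo2 or nz > hi2:
            continue
        dE = 0.0
        ok = True
        for jj in range(vf_ptr[v], vf_ptr[v + 1]):
            f = vf_idx[jj]
            i0 = faces[f, 0]
            i1 = faces[f, 1]
            i2 = faces[f, 2]
            ax, ay, az = pos[i0, 0], pos[i0, 1], pos[i0, 2]
            bx, by, bz = pos[i1, 0], pos[i1, 1], pos[i1, 2]
            cx, cy, cz = pos[i2, 0], pos[i2, 1], pos[i2, 2]
            e1x, e1y, e1z = bx - ax, by - ay, bz - az
            e2x, e2y, e2z = cx - ax, cy - ay, cz - az
            crx = e1y * e2z - e1z * e2y
            cry = e1z * e2x - e1x * e2z
            crz = e1x * e2y - e1y * e2x
            a_old = 0.5 * math.sqrt(crx * crx + cry * cry + crz * crz)
            if i0 == v:
                ax, ay, az = nx, ny, nz
            elif i1 == v:
                bx, by, bz = nx, ny, nz
            else:
                cx, cy, cz = nx, ny, nz
            e1x, e1y, e1z = bx - ax, by - ay, bz - az
            e2x, e2y, e2z = cx - ax, cy - ay, cz - az
            crx = e1y * e2z - e1z * e2y
            cry = e1z * e2x - e1x * e2z
            crz = e1x * e2y - e1y * e2x
            a_new = 0.5 * math.sqrt(crx * crx + cry * cry + crz * crz)
            if a_new < area_tol:
                ok = False
                break
            ar = rest[f]
            da_new = a_new - ar
            da_old = a_old - ar
            dE += kappa / (2.0 * ar * ar) * (da_new * da_new - da_old * da_old)
        if not ok:
            continue
        for jj in range(vb_ptr[v], vb_ptr[v + 1]):
            b = vb_idx[jj]
            f = b_face[b]
            i0 = faces[f, 0]
            i1 = faces[f, 1]
            i2 = faces[f, 2]
            w0 = b_bary[b, 0]
            w1 = b_bary[b, 1]
            w2 = b_bary[b, 2]
            ox = w0 * pos[i0, 0] + w1 * pos[i1, 0] + w2 * pos[i2, 0]
            oy = w0 * pos[i0, 1] + w1 * pos[i1, 1] + w2 * pos[i2, 1]
            oz = w0 * pos[i0, 2] + w1 * pos[i1, 2] + w2 * pos[i2, 2]
            if i0 == v:
                nxp = ox + w0 * (nx - pos[v, 0])
                nyp = oy + w0 * (ny - pos[v, 1])
                nzp = oz + w0 * (nz - pos[v, 2])
            elif i1 == v:
                nxp = ox + w1 * (nx - pos[v, 0])
                nyp = oy + w1 * (ny - pos[v, 1])
                nzp = oz + w1 * (nz - pos[v, 2])
            else:
                nxp = ox + w2 * (nx - pos[v, 0])
                nyp = oy + w2 * (ny - pos[v, 1])
                nzp = oz + w2 * (nz - pos[v, 2])
            dx, dy, dz = ox - b_anchor[b, 0], oy - b_anchor[b, 1], oz - b_anchor[b, 2]
            d_old = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx, dy, dz = nxp - b_anchor[b, 0], nyp - b_anchor[b, 1], nzp - b_anchor[b, 2]
            d_new = math.sqrt(dx * dx + dy * dy + dz * dz)
            eo = d_old - b_rest[b]
            en = d_new - b_rest[b]
            dE += 0.5 * b_k[b] * (en * en - eo * eo)
        if dE <= 0.0 or urand[v] < math.exp(-dE):
            pos[v, 0] = nx
            pos[v, 1] = ny
            pos[v, 2] = nz
            accepted += 1
    return accepted


def sweep_nodes(state: SimState) -> int:
    """One attempted Metropolis move per non-clamped vertex, seeded random
    order.  Returns the number of accepted moves."""
    mesh = state.mesh
    if mesh is None or mesh.rigid:
        return 0
    cfg = state.config
    rng = state.rng
    nv = mesh.n_vertices
    order = rng.permutation(nv).astype(np.int64)
    disp = rng.normal(0.0, cfg.sigma, size=(nv, 3))
    urand = rng.random(nv)
    clamped = mesh.boundary_vertex
    use_kernel = (HAVE_NUMBA and not state.obstacles
                  and not cfg.bending.enabled)
    if use_kernel:
        ptr, fidx = mesh.vertex_face_incidence()
        bptr, bidx = state.vertex_bond_csr()
        b = state.bonds
        lo = np.asarray(cfg.box_lo, dtype=float)
        hi = np.asarray(cfg.box_hi, dtype=float)
        return int(_sweep_kernel(
            mesh.vertices, mesh.faces, mesh.rest_area, ptr, fidx,
            clamped, order, disp, urand,
            cfg.elastic.kappa_eff, cfg.area_tol,
            lo[0], lo[1], lo[2], hi[0], hi[1], hi[2],
            b.face, b.bary, b.anchor, b.k, b.rest, bptr, bidx))
    accepted = 0
    lo = np.asarray(cfg.box_lo)
    hi = np.asarray(cfg.box_hi)
    for v in order:
        if clamped[v]:
            continue
        proposal = MoveProposal(int(v), disp[v], 0.0)
        new_pos = mesh.vertices[v] + disp[v]
        if not constraint_check(state, proposal):
            continue
        e_old = _local_energy(state, int(v), mesh.vertices[v])
        e_new = _local_energy(state, int(v), new_pos)
        dE = e_new - e_old
        if cfg.bending.enabled:
            e0 = bending_energy(mesh, cfg.bending)
            old = mesh.vertices[v].copy()
            mesh.vertices[v] = new_pos
            e1 = bending_energy(mesh, cfg.bending)
            mesh.vertices[v] = old
            dE += e1 - e0
        if dE <= 0.0 or urand[v] < math.exp(-dE):
            mesh.vertices[v] = new_pos
            accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# pressure

def apply_pressure(state: SimState) -> float:
    """Deterministic volume-restoring displacement along vertex normals.

    Applied once per iteration after the Metropolis sweep.  Returns the
    displacement magnitude used (0 if pressure is off or the mesh is open).
    """
    cfg = state.config
    if cfg.pressure is None or state.mesh is None:
        return 0.0
    mesh = state.mesh
    if not mesh.is_closed():
        return 0.0
    vol = enclosed_volume(mesh)
    dv = vol - cfg.pressure.v_int
    mag = pressure_displacement(dv, cfg.pressure)
    mag = min(mag, cfg.pressure.max_step)
    if mag == 0.0:
        return 0.0
    direction = 1.0 if dv < 0 else -1.0   # inflate if shrunk, deflate if grown
    normals = mesh.vertex_normals()
    movable = ~mesh.boundary_vertex
    mesh.vertices[movable] += direction * mag * normals[movable]
    lo = np.asarray(cfg.box_lo)
    hi = np.asarray(cfg.box_hi)
    np.clip(mesh.vertices, lo, hi, out=mesh.vertices)
    return mag


# ---------------------------------------------------------------------------
# full iteration

def step_iteration(state: SimState) -> SimState:
    """One full sweep in fixed order (particles, molecules, reactions, nodes,
    pressure, recording).  Mutates and returns ``state``."""
    if not getattr(state, "initialized", False):
        raise ParameterError("state is not initialized")
    cfg = state.config
    rng = state.rng
    # 1. particles
    if state.particles is not None:
        from . import particles as pt
        state.particles.resample_velocities(rng)
        _, tally = pt.advance_and_collide(state.particles, state.chamber,
                                          state.piston, cfg.timestep)
        state.last_tally = tally
        if state.piston is not None and state.piston_mobility:
            lo, hi = pt._chamber_bounds(state.chamber)
            new_z = pt.apply_momentum_kick(state.piston, tally,
                                           state.piston_mobility,
                                           z_bounds=(lo[2], hi[2]))
            pt.confine_to_compartments(state.particles, state.chamber, new_z)
    # 2. surface-molecule diffusion
    if state.mobile_molecules is not None and state.mobile_molecules.diffusion:
        sm.diffuse_on_surface(state.mobile_molecules, state.mesh,
                              cfg.timestep, rng)
    # 3. pairing + binding
    state.new_bonds = 0
    if (state.mobile_molecules is not None and state.static_molecules is not None
            and cfg.rules):
        for rule in cfg.rules:
            pairs, _ = sm.pair_candidates(state.mobile_molecules,
                                          state.static_molecules,
                                          rule.pairing_distance)
            if len(pairs):
                k_bond = sm.bond_stiffness(cfg.per_bond_energy,
                                           rule.pairing_distance)
                n = sm.apply_binding(pairs, rule, cfg.timestep, rng,
                                     state.mobile_molecules,
                                     state.static_molecules,
                                     state.bonds, k_bond,
                                     cfg.bond_rest_length)
                if n:
                    state.new_bonds += n
                    state.invalidate_bonds()
    # 4. Metropolis node sweep
    state.accepted_moves = sweep_nodes(state)
    # 5. pressure
    apply_pressure(state)
    # 6. observables
    state.iteration += 1
    if state.observer is not None:
        state.observer(state)
    return state
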