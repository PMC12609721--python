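"""Energy and work terms of the membrane Hamiltonian.

The total energy driving Metropolis moves is H = H_int + H_el (+ H_bend if
enabled) plus the adhesion tethers handled in :mod:`membranemc.surface_molecules`.
Energies are expressed in units of kT (β = 1), so the Metropolis criterion is
exp(-ΔE) with no explicit temperature factor; temperature enters only through
this normalisation and the particle speed scales.

Terms
-----
- kinetic interaction  H_int = Σ ½ m v²       (piston particles)
- momentum             P_int = Σ m v          (collision impulses)
- elastic stretching   H_el  = Σ_faces κ/(2 a_i²) (Δa_i)², a_i the frozen rest
  area, Δa_i the deviation of the instantaneous face area from it
- Helfrich bending     H_bend = 2 κ_b M2, with M2 the discrete
  squared-mean-curvature moment (off by default)
- pressure             a deterministic restoring displacement
  D_P = c (ΔV)² / V_int applied along vertex normals, not a sampled energy
- isothermal work      W = nRT ln(V2/V1) per compartment
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import TriMesh, MeshError


@dataclass
class ElasticParams:
    """Membrane stretching rigidities, in kT.

    kappa1 is the deformable membrane's rigidity; kappa2 that of the opposing
    membrane or surface.  The effective rigidity is the series combination
    κ = κ1·κ2/(κ1+κ2), which tends to κ1 when the opposing surface is much
    stiffer (κ2 ≫ κ1, e.g. a glass coverslip).
    """
    kappa1: float = 20.0
    kappa2: float = 2.0e6

    def __post_init__(self):
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("rigidities must be non-negative")

    @property
    def kappa_eff(self) -> float:
        return effective_rigidity(self.kappa1, self.kappa2)


@dataclass
class BendingParams:
    """Helfrich bending constant (kT).  Disabled by default."""
    kappa_b: float = 20.0
    enabled: bool = False

    def __post_init__(self):
        if self.kappa_b < 0:
            raise ValueError("kappa_b must be non-negative")


@dataclass
class PressureParams:
    """Constant-pressure volume restoration.

    v_int is the target (initial) enclosed volume in µm³; c scales the
    displacement D_P = c·(ΔV)²/V_int applied along vertex normals toward
    restoring v_int.  max_step caps the per-iteration displacement (µm) so a
    large volume deficit cannot move nodes unphysically far in one step.
    """
    c: float = 0.05
    v_int: float = 1.0
    max_step: float = 0.01

    def __post_init__(self):
        if self.v_int <= 0:
            raise ValueError("v_int must be positive")
        if self.c < 0:
            raise ValueError("displacement constant c must be non-negative")


@dataclass
class ThermoParams:
    """Isothermal work prefactor W = nRT ln(V2/V1); components configurable."""
    n: float = 1.0
    R: float = 1.0
    T: float = 1.0

    def __post_init__(self):
        if self.nRT <= 0:
            raise ValueError("nRT must be positive")

    @property
    def nRT(self) -> float:
        return self.n * self.R * self.T


# ---------------------------------------------------------------------------

def kinetic_energy(masses, velocities) -> float:
    """Σ ½ m_i |v_i|² over the ensemble (kT units)."""
    m = np.asarray(masses, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(m) != len(v):
        raise ValueError("need equal-length masses and (n, 3) velocities")
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    return float(0.5 * np.sum(m * np.einsum("ij,ij->i", v, v)))


def momentum(masses, velocities) -> np.ndarray:
    """Total momentum Σ m_i v_i, componentwise."""
    m = np.asarray(masses, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(m) != len(v):
        raise ValueError("need equal-length masses and (n, 3) velocities")
    if (m <= 0).any():
        raise ValueError("masses must be positive")
    return (m[:, None] * v).sum(axis=0)


def effective_rigidity(kappa1: float, kappa2: float) -> float:
    """Series combination κ1·κ2/(κ1+κ2) of two membrane rigidities."""
    if kappa1 < 0 or kappa2 < 0:
        raise ValueError("rigidities must be non-negative")
    s = kappa1 + kappa2
    if s == 0:
        raise ValueError("at least one rigidity must be positive")
    return kappa1 * kappa2 / s


def elastic_energy(mesh: TriMesh, params: ElasticParams) -> float:
    """Stretching energy Σ_i κ/(2 a_i²) (Δa_i)² with a_i the rest areas."""
    if mesh.rest_area is None or len(mesh.rest_area) != mesh.n_faces:
        raise MeshError("mesh has no per-face rest areas")
    da = mesh.face_areas() - mesh.rest_area
    return float(np.sum(params.kappa_eff / (2.0 * mesh.rest_area ** 2) * da ** 2))


def pressure_displacement(delta_V: float, params: PressureParams) -> float:
    """Magnitude of the pressure-driven node displacement, D_P = c ΔV²/V_int.

    Even in ΔV; the engine chooses the direction (along vertex normals,
    restoring the enclosed volume toward v_int).
    """
    if params.v_int <= 0:
        raise ValueError("v_int must be positive")
    return params.c * delta_V * delta_V / params.v_int


def isothermal_work(params: ThermoParams, V1: float, V2: float) -> float:
    """Isothermal compartment work W = nRT ln(V2/V1) (V1 initial, V2 current)."""
    if V1 <= 0 or V2 <= 0:
        raise ValueError("volumes must be positive")
    return params.nRT * float(np.log(V2 / V1))


# ---------------------------------------------------------------------------
# Helfrich bending (optional term)

def cotangent_laplacian_coordinates(mesh: TriMesh) -> np.ndarray:
    """Integrated cotangent Laplacian of the coordinate field.

    Returns (V, 3): K x_v = ½ Σ_{u ∈ N(v)} (cot α_uv + cot β_uv)(x_u - x_v),
    the (unnormalised) discrete Laplace–Beltrami operator applied per vertex.
    Dividing by the barycentric vertex area gives the mean-curvature vector
    Δ_s x = 2 H n̂.
    """
    V = mesh.vertices
    F = mesh.faces
    K = np.zeros_like(V)
    # cotangent at each face corner
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        vi, vj, vk = V[F[:, i]], V[F[:, j]], V[F[:, k]]
        e1 = vj - vi
        e2 = vk - vi
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        # corner i faces edge (j, k): contributes cot/2 * (x_k - x_j) to j etc.
        w = 0.5 * cot[:, None]
        np.add.at(K, F[:, j], w * (vk - vj))
        np.add.at(K, F[:, k], w * (vj - vk))
    return K


def vertex_areas(mesh: TriMesh) -> np.ndarray:
    """Barycentric vertex areas: one third of the incident face areas."""
    fa = mesh.face_areas()
    va = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(va, mesh.faces[:, k], fa / 3.0)
    return va


def bending_energy(mesh: TriMesh, params: BendingParams) -> float:
    """Helfrich bending energy 2 κ_b M2.

    M2 = Σ_v A_v H_v² is the discrete squared-mean-curvature moment: the
    cotangent Laplace–Beltrami of the coordinate field gives the mean-curvature
    vector per vertex (|Δ_s x| = 2H), weighted by the barycentric one-ring area
    share A_v.  Normalised so that the smooth-sphere limit is 8π κ_b
    regardless of radius.  Boundary vertices of open meshes are excluded
    (treated as clamped).
    """
    if not params.enabled:
        raise ValueError(
            "bending term is disabled; set BendingParams.enabled = True")
    K = cotangent_laplacian_coordinates(mesh)
    A = vertex_areas(mesh)
    interior = ~mesh.boundary_vertex
    lap = K[interior] / A[interior, None]          # Δ_s x = 2 H n̂
    h2 = 0.25 * np.einsum("ij,ij->i", lap, lap)    # H²
    m2 = float(np.sum(A[interior] * h2))
    return 2.0 * params.kappa_b * m2
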