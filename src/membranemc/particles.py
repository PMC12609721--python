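"""Ideal-gas particle ensemble for the piston chamber.

Particles fly ballistically within their compartment of an axis-aligned box
chamber, reflecting specularly off the walls and off the rigid piston plane
that separates the top and bottom compartments.  Every piston reflection
transfers an impulse 2·m·|v_z| to the corresponding side of the piston; the
massless piston then translates along z overdamped, proportionally to the net
impulse (bottom − top) through a mobility constant.

Velocities may be drawn two ways:

- ``speed_scale``: the per-axis velocity standard deviation directly (µm/µs),
  independent of mass.  This is the mode the piston scenarios use: at equal
  speed scales a heavier compartment transfers more momentum per collision
  (impulse flux ∝ m·σ²) and the piston drifts toward the lighter side.
- ``kT``: Maxwell-like sampling with per-axis σ = sqrt(kT/m), so the mean
  kinetic energy per particle is (3/2)·kT regardless of mass.  At a common
  temperature the momentum fluxes of the two compartments balance exactly
  (ideal-gas pressure is mass-independent), so this mode produces no drift;
  it exists for thermodynamically consistent sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import TriMesh, ParameterError

BOTTOM, TOP = 0, 1


@dataclass
class CollisionTally:
    """Per-iteration piston collision bookkeeping (counts and z-impulses)."""
    top_count: int = 0
    bottom_count: int = 0
    top_impulse: float = 0.0     # mass·µm/µs transferred by top-side hits
    bottom_impulse: float = 0.0


@dataclass
class ParticleEnsemble:
    positions: np.ndarray            # (N, 3) µm
    masses: np.ndarray               # (N,)
    velocities: np.ndarray           # (N, 3) µm/µs
    compartment: np.ndarray          # (N,) int8, BOTTOM or TOP
    sigma_v: np.ndarray = field(default=None)  # per-particle per-axis speed σ

    @property
    def n(self) -> int:
        return len(self.masses)

    def resample_velocities(self, rng: np.random.Generator) -> None:
        """Draw fresh isotropic Gaussian velocities (per-axis σ = sigma_v).

        Re-sampling once per iteration makes the long-time particle motion
        diffusive while keeping well-defined collision momenta within the
        iteration.
        """
        self.velocities = rng.normal(0.0, 1.0, size=(self.n, 3)) * self.sigma_v[:, None]


def release_particles(n: int, region, mass: float, speed_scale: float | None = None,
                      kT: float | None = None, seed=None,
                      compartment: int = BOTTOM,
                      chamber=None) -> ParticleEnsemble:
    """Release ``n`` particles uniformly in ``region`` = (lo, hi) µm bounds.

    Exactly one of ``speed_scale`` (per-axis velocity σ, mass-independent) or
    ``kT`` (Maxwell-like, per-axis σ = sqrt(kT/m), mean KE = 1.5·kT) must be
    given.  ``seed`` may be an int or a Generator.
    """
    if n < 0:
        raise ParameterError("n must be non-negative")
    if mass <= 0:
        raise ParameterError("mass must be positive")
    if (speed_scale is None) == (kT is None):
        raise ParameterError("give exactly one of speed_scale or kT")
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if (hi <= lo).any():
        raise ParameterError("region must have positive extent")
    if chamber is not None:
        clo, chi = _chamber_bounds(chamber)
        if (lo < clo - 1e-12).any() or (hi > chi + 1e-12).any():
            raise ParameterError("release region lies outside the chamber")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = rng.uniform(lo, hi, size=(n, 3))
    masses = np.full(n, float(mass))
    sigma = float(speed_scale) if speed_scale is not None else float(np.sqrt(kT / mass))
    ens = ParticleEnsemble(positions=pos, masses=masses,
                           velocities=np.zeros((n, 3)),
                           compartment=np.full(n, compartment, dtype=np.int8),
                           sigma_v=np.full(n, sigma))
    ens.resample_velocities(rng)
    return ens


def merge(a: ParticleEnsemble, b: ParticleEnsemble) -> ParticleEnsemble:
    return ParticleEnsemble(
        positions=np.vstack([a.positions, b.positions]),
        masses=np.concatenate([a.masses, b.masses]),
        velocities=np.vstack([a.velocities, b.velocities]),
        compartment=np.concatenate([a.compartment, b.compartment]),
        sigma_v=np.concatenate([a.sigma_v, b.sigma_v]),
    )


def _chamber_bounds(chamber):
    """Accept a closed box TriMesh or a (lo, hi) pair; return AABB arrays."""
    if isinstance(chamber, TriMesh):
        return chamber.vertices.min(axis=0), chamber.vertices.max(axis=0)
    lo, hi = chamber
    return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)


def _piston_z(piston) -> float:
    if isinstance(piston, TriMesh):
        return float(piston.vertices[:, 2].mean())
    return float(piston)


def _fold(u: np.ndarray, h: float):
    """Fold unbounded 1D coordinates into [0, h] with reflective boundaries.

    Returns folded positions and the velocity sign (+1/-1) after the folds.
    """
    m = np.floor(u / h)
    r = u - m * h
    odd = (m.astype(np.int64) & 1).astype(bool)
    x = np.where(odd, h - r, r)
    sign = np.where(odd, -1.0, 1.0)
    return x, sign


def _count_crossings(a: np.ndarray, b: np.ndarray, parity: int) -> np.ndarray:
    """Number of integers of given parity (0 even, 1 odd) strictly between a and b."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    if parity == 1:
        return (np.floor((hi + 1) / 2) - np.floor((lo + 1) / 2)).astype(np.int64)
    return (np.floor(hi / 2) - np.floor(lo / 2)).astype(np.int64)


def advance_and_collide(ens: ParticleEnsemble, chamber, piston, dt: float):
    """Ballistic advance by v·dt with specular wall/piston reflections.

    The piston is a rigid horizontal plane spanning the chamber cross-section;
    crossings are intercepted analytically (trajectory unfolding), counted on
    the correct side, and each contributes 2·m·|v_z| to that side's impulse.
    Particles never change compartment and speeds are preserved.
    Returns (ens, CollisionTally); ens is modified in place.
    """
    lo, hi = _chamber_bounds(chamber)
    zp = _piston_z(piston)
    pos, vel = ens.positions, ens.velocities
    if ((pos < lo - 1e-9) | (pos > hi + 1e-9)).any():
        raise ParameterError("particle outside the chamber")

    # x and y: plain reflective folding off the four side walls
    for ax in range(2):
        span = hi[ax] - lo[ax]
        u = pos[:, ax] + vel[:, ax] * dt - lo[ax]
        x, sgn = _fold(u, span)
        pos[:, ax] = lo[ax] + x
        vel[:, ax] *= sgn

    tally = CollisionTally()
    for comp, (z0, z1) in ((BOTTOM, (lo[2], zp)), (TOP, (zp, hi[2]))):
        sel = ens.compartment == comp
        if not sel.any():
            continue
        h = z1 - z0
        a = (pos[sel, 2] - z0) / h
        u = a + vel[sel, 2] * dt / h
        x, sgn = _fold(u * h, h)
        pos[sel, 2] = z0 + x
        vel[sel, 2] *= sgn
        # piston plane images: odd multiples of h for the bottom compartment
        # (piston is the upper boundary), even multiples for the top.
        parity = 1 if comp == BOTTOM else 0
        hits = _count_crossings(a, u, parity)
        imp = 2.0 * ens.masses[sel] * np.abs(vel[sel, 2])
        if comp == BOTTOM:
            tally.bottom_count = int(hits.sum())
            tally.bottom_impulse = float(np.sum(hits * imp))
        else:
            tally.top_count = int(hits.sum())
            tally.top_impulse = float(np.sum(hits * imp))
    return ens, tally


def apply_momentum_kick(piston, tally: CollisionTally, mobility: float,
                        z_bounds=None, min_gap: float = 0.02) -> float:
    """Translate the overdamped piston: Δz = mobility · (bottom − top impulse).

    The piston is clamped to stay at least ``min_gap`` µm inside the chamber so
    both compartments keep positive volume.  Returns the new piston z; if
    ``piston`` is a TriMesh it is translated in place.
    """
    dz = mobility * (tally.bottom_impulse - tally.top_impulse)
    zp = _piston_z(piston)
    new_z = zp + dz
    if z_bounds is not None:
        new_z = float(np.clip(new_z, z_bounds[0] + min_gap, z_bounds[1] - min_gap))
    if isinstance(piston, TriMesh):
        piston.translate((0.0, 0.0, new_z - zp))
    return new_z


def confine_to_compartments(ens: ParticleEnsemble, chamber, piston_z: float,
                            eps: float = 1e-9) -> None:
    """Push particles a moved piston has overtaken back into their compartment."""
    lo, hi = _chamber_bounds(chamber)
    z = ens.positions[:, 2]
    bot = ens.compartment == BOTTOM
    z[bot] = np.clip(z[bot], lo[2] + eps, piston_z - eps)
    z[~bot] = np.clip(z[~bot], piston_z + eps, hi[2] - eps)


def compartment_volumes(chamber, piston_z: float):
    """(V_bottom, V_top) from the box cross-section and the piston plane."""
    lo, hi = _chamber_bounds(chamber)
    area = (hi[0] - lo[0]) * (hi[1] - lo[1])
    return area * (piston_z - lo[2]), area * (hi[2] - piston_z)
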