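"""Surface-bound molecular species: placement, 2D surface diffusion,
distance-gated pairing, binding, and the adhesion energy fed back to the
membrane dynamics.

Molecules (receptors such as TCRs or integrins on the cell; their ligands,
e.g. pMHC or activating antibody, on the coverslip) live on mesh faces with
barycentric coordinates, so they ride the membrane as it deforms.  Unbound
molecules take Gaussian in-plane steps, unfolding across face edges; a k-d
tree pairs diffusing molecules with static coverslip molecules within the
pairing distance, candidate pairs bind with probability 1 - exp(-k·dt), and
each bond contributes a quadratic tether energy to subsequent node moves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import TriMesh, MeshError, ParameterError

try:
    from numba import njit as _njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn
        return wrap

_RULE_RE = re.compile(
    r"^\s*(\w+)\s*\+\s*(\w+)\s*->\s*([\w.]+)\s*$")


@dataclass
class ReactionRule:
    """Bimolecular binding rule ``A + B -> A.B`` with a capture radius.

    rate: on-rate in 1/s, conditional on the pair being within
    ``pairing_distance`` (µm).  ``rate = inf`` binds every candidate pair
    instantly.  off_rate (1/s) defaults to 0: bonds never dissociate.
    """
    species_a: str
    species_b: str
    rate: float = 1.0e6
    pairing_distance: float = 0.05
    off_rate: float = 0.0
    product: str = ""

    def __post_init__(self):
        if self.rate < 0 or self.off_rate < 0:
            raise ParameterError("reaction rates must be non-negative")
        if self.pairing_distance <= 0:
            raise ParameterError("pairing distance must be positive")
        if not self.product:
            self.product = f"{self.species_a}.{self.species_b}"

    @classmethod
    def parse(cls, rule: str, rate: float = 1.0e6,
              pairing_distance: float = 0.05, off_rate: float = 0.0):
        """Parse the minimal grammar ``"A + B -> A.B"``."""
        m = _RULE_RE.match(rule)
        if m is None:
            raise ParameterError(f"cannot parse reaction rule {rule!r}")
        return cls(species_a=m.group(1), species_b=m.group(2),
                   product=m.group(3), rate=rate,
                   pairing_distance=pairing_distance, off_rate=off_rate)


UNBOUND = -1


@dataclass
class SurfaceMoleculeSet:
    """Molecules of one species bound to the faces of one host mesh."""
    species: str
    mesh: TriMesh
    face: np.ndarray                  # (N,) host face id
    bary: np.ndarray                  # (N, 3) barycentric coordinates
    diffusion: float = 0.0            # µm²/s
    bond_partner: np.ndarray = field(default=None)  # (N,) partner id or -1

    def __post_init__(self):
        if self.bond_partner is None:
            self.bond_partner = np.full(len(self.face), UNBOUND, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.face)

    @property
    def unbound(self) -> np.ndarray:
        return self.bond_partner == UNBOUND

    def positions(self) -> np.ndarray:
        """Embedded 3D positions from barycentric coordinates (N, 3)."""
        tri = self.mesh.vertices[self.mesh.faces[self.face]]  # (N, 3, 3)
        return np.einsum("ni,nij->nj", self.bary, tri)

    def to_table(self):
        """Plain columns for CSV export: id, species, x, y, z, bond."""
        import pandas as pd
        xyz = self.positions()
        return pd.DataFrame({
            "id": np.arange(self.n), "species": self.species,
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
            "bond": self.bond_partner,
        })


def place_molecules(mesh: TriMesh, n: int, species: str,
                    diffusion_constant: float = 0.0,
                    seed=None) -> SurfaceMoleculeSet:
    """Place ``n`` molecules uniformly by area on ``mesh``.

    The host face is chosen with probability proportional to its area and the
    position is uniform within the face (square-root barycentric sampling).
    """
    if mesh.n_faces == 0:
        raise MeshError("cannot place molecules on an empty mesh")
    if n < 0:
        raise ParameterError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = mesh.face_areas()
    faces = rng.choice(mesh.n_faces, size=n, p=areas / areas.sum())
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    bary = np.column_stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2])
    return SurfaceMoleculeSet(species=species, mesh=mesh,
                              face=faces.astype(np.int64), bary=bary,
                              diffusion=float(diffusion_constant))


# ---------------------------------------------------------------------------
# surface diffusion

def _barycentric(p, a, b, c):
    """Barycentric coordinates of p in triangle (a, b, c) (p in its plane)."""
    v0 = b - a
    v1 = c - a
    v2 = p - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.array([1.0 - v - w, v, w])


def _walk_on_surface(mesh: TriMesh, f: int, bary: np.ndarray,
                     disp: np.ndarray, max_hops: int = 32):
    """Propagate an in-plane displacement across face edges by unfolding.

    The step continues into the adjacent face by rotating the remaining
    displacement about the shared edge (computed edge-tangent/edge-normal
    decomposition, no trigonometry); boundary edges reflect.  Returns the
    final (face, barycentric) pair.
    """
    adj = mesh.face_adjacency()
    V = mesh.vertices
    tri = V[mesh.faces[f]]
    p = bary @ tri
    d = disp.copy()
    for _ in range(max_hops):
        tri = V[mesh.faces[f]]
        bt = _barycentric(p + d, tri[0], tri[1], tri[2])
        if (bt >= -1e-12).all():
            return f, np.clip(bt, 0.0, None) / np.clip(bt, 0.0, None).sum()
        bp = _barycentric(p, tri[0], tri[1], tri[2])
        # first barycentric coordinate to hit zero along p -> p+d
        alpha = np.inf
        exit_i = -1
        for i in range(3):
            if bt[i] < -1e-15 and bp[i] > bt[i]:
                ai = bp[i] / (bp[i] - bt[i])
                if 0.0 <= ai < alpha:
                    alpha = ai
                    exit_i = i
        if exit_i < 0:  # numerically stuck: clamp into the face
            bt = np.clip(bp, 1e-12, None)
            return f, bt / bt.sum()
        p_cross = p + alpha * d
        rem = (1.0 - alpha) * d
        # edge opposite vertex exit_i
        a = tri[(exit_i + 1) % 3]
        b = tri[(exit_i + 2) % 3]
        e = b - a
        e = e / np.linalg.norm(e)
        # in-plane outward normal of the edge in the current face
        opp = tri[exit_i]
        m_out = (a + b) / 2.0 - opp
        m_out = m_out - (m_out @ e) * e
        m_out = m_out / np.linalg.norm(m_out)
        g = adj[f, exit_i]
        if g < 0:
            # boundary: reflect the remaining displacement across the edge line
            d = (rem @ e) * e - (rem @ m_out) * m_out
        else:
            trig = V[mesh.faces[g]]
            # vertex of g not on the shared edge
            shared = {mesh.faces[f][(exit_i + 1) % 3], mesh.faces[f][(exit_i + 2) % 3]}
            opp_g = [vid for vid in mesh.faces[g] if vid not in shared][0]
            m_in = V[opp_g] - (a + b) / 2.0
            m_in = m_in - (m_in @ e) * e
            m_in = m_in / np.linalg.norm(m_in)
            d = (rem @ e) * e + (rem @ m_out) * m_in
            f = int(g)
            tri = trig
        p = p_cross + 1e-12 * (m_in if g >= 0 else -m_out)
    bt = _barycentric(p, tri[0], tri[1], tri[2])
    bt = np.clip(bt, 1e-12, None)
    return f, bt / bt.sum()


@_njit(cache=True)
def _walk_kernel(V, F, adj, faces_out, bary_out, start_face, start_bary, disp):
    """Edge-unfolding walk for a batch of molecules (numba fast path).

    Mirrors ``_walk_on_surface``: continue across shared edges by rotating the
    remaining in-plane displacement into the neighbour's plane, reflect at
    boundary edges, clamp into the face after 32 hops.
    """
    n = start_face.shape[0]
    for mi in range(n):
        f = start_face[mi]
        b0, b1, b2 = start_bary[mi, 0], start_bary[mi, 1], start_bary[mi, 2]
        px = b0 * V[F[f, 0], 0] + b1 * V[F[f, 1], 0] + b2 * V[F[f, 2], 0]
        py = b0 * V[F[f, 0], 1] + b1 * V[F[f, 1], 1] + b2 * V[F[f, 2], 1]
        pz = b0 * V[F[f, 0], 2] + b1 * V[F[f, 1], 2] + b2 * V[F[f, 2], 2]
        dx, dy, dz = disp[mi, 0], disp[mi, 1], disp[mi, 2]
        done = False
        for _hop in range(32):
            ax, ay, az = V[F[f, 0], 0], V[F[f, 0], 1], V[F[f, 0], 2]
            bx, by, bz = V[F[f, 1], 0], V[F[f, 1], 1], V[F[f, 1], 2]
            cx, cy, cz = V[F[f, 2], 0], V[F[f, 2], 1], V[F[f, 2], 2]
            v0x, v0y, v0z = bx - ax, by - ay, bz - az
            v1x, v1y, v1z = cx - ax, cy - ay, cz - az
            d00 = v0x * v0x + v0y * v0y + v0z * v0z
            d01 = v0x * v1x + v0y * v1y + v0z * v1z
            d11 = v1x * v1x + v1y * v1y + v1z * v1z
            denom = d00 * d11 - d01 * d01
            # barycentric of target point
            tx, ty, tz = px + dx - ax, py + dy - ay, pz + dz - az
            d20 = tx * v0x + ty * v0y + tz * v0z
            d21 = tx * v1x + ty * v1y + tz * v1z
            tv = (d11 * d20 - d01 * d21) / denom
            tw = (d00 * d21 - d01 * d20) / denom
            tu = 1.0 - tv - tw
            if tu >= -1e-12 and tv >= -1e-12 and tw >= -1e-12:
                tu = max(tu, 0.0)
                tv = max(tv, 0.0)
                tw = max(tw, 0.0)
                s = tu + tv + tw
                faces_out[mi] = f
                bary_out[mi, 0] = tu / s
                bary_out[mi, 1] = tv / s
                bary_out[mi, 2] = tw / s
                done = True
                break
            # barycentric of current point
            sx, sy, sz = px - ax, py - ay, pz - az
            e20 = sx * v0x + sy * v0y + sz * v0z
            e21 = sx * v1x + sy * v1y + sz * v1z
            pv = (d11 * e20 - d01 * e21) / denom
            pw = (d00 * e21 - d01 * e20) / denom
            pu = 1.0 - pv - pw
            alpha = 1.0e30
            exit_i = -1
            for i in range(3):
                bpi = pu if i == 0 else (pv if i == 1 else pw)
                bti = tu if i == 0 else (tv if i == 1 else tw)
                if bti < -1e-15 and bpi > bti:
                    ai = bpi / (bpi - bti)
                    if 0.0 <= ai < alpha:
                        alpha = ai
                        exit_i = i
            if exit_i < 0:
                pu = max(pu, 1e-12)
                pv = max(pv, 1e-12)
                pw = max(pw, 1e-12)
                s = pu + pv + pw
                faces_out[mi] = f
                bary_out[mi, 0] = pu / s
                bary_out[mi, 1] = pv / s
                bary_out[mi, 2] = pw / s
                done = True
                break
            # crossing point and remaining displacement
            px += alpha * dx
            py += alpha * dy
            pz += alpha * dz
            rx = (1.0 - alpha) * dx
            ry = (1.0 - alpha) * dy
            rz = (1.0 - alpha) * dz
            va = F[f, (exit_i + 1) % 3]
            vb = F[f, (exit_i + 2) % 3]
            vo = F[f, exit_i]
            ex, ey, ez = V[vb, 0] - V[va, 0], V[vb, 1] - V[va, 1], V[vb, 2] - V[va, 2]
            el = (ex * ex + ey * ey + ez * ez) ** 0.5
            ex, ey, ez = ex / el, ey / el, ez / el
            midx = 0.5 * (V[va, 0] + V[vb, 0])
            midy = 0.5 * (V[va, 1] + V[vb, 1])
            midz = 0.5 * (V[va, 2] + V[vb, 2])
            mx, my, mz = midx - V[vo, 0], midy - V[vo, 1], midz - V[vo, 2]
            dot = mx * ex + my * ey + mz * ez
            mx, my, mz = mx - dot * ex, my - dot * ey, mz - dot * ez
            ml = (mx * mx + my * my + mz * mz) ** 0.5
            mx, my, mz = mx / ml, my / ml, mz / ml
            rt = rx * ex + ry * ey + rz * ez      # tangential component
            rp = rx * mx + ry * my + rz * mz      # outward component
            g = adj[f, exit_i]
            if g < 0:
                # boundary edge: reflect within the plane
                dx = rt * ex - rp * mx
                dy = rt * ey - rp * my
                dz = rt * ez - rp * mz
                px -= 1e-12 * mx
                py -= 1e-12 * my
                pz -= 1e-12 * mz
            else:
                # inward in-plane normal of the shared edge within face g
                og = -1
                for k in range(3):
                    vg = F[g, k]
                    if vg != va and vg != vb:
                        og = vg
                        break
                nx, ny, nz = V[og, 0] - midx, V[og, 1] - midy, V[og, 2] - midz
                dot = nx * ex + ny * ey + nz * ez
                nx, ny, nz = nx - dot * ex, ny - dot * ey, nz - dot * ez
                nl = (nx * nx + ny * ny + nz * nz) ** 0.5
                nx, ny, nz = nx / nl, ny / nl, nz / nl
                dx = rt * ex + rp * nx
                dy = rt * ey + rp * ny
                dz = rt * ez + rp * nz
                px += 1e-12 * nx
                py += 1e-12 * ny
                pz += 1e-12 * nz
                f = g
        if not done:
            # out of hops: clamp to the current face at the crossing point
            ax, ay, az = V[F[f, 0], 0], V[F[f, 0], 1], V[F[f, 0], 2]
            v0x = V[F[f, 1], 0] - ax
            v0y = V[F[f, 1], 1] - ay
            v0z = V[F[f, 1], 2] - az
            v1x = V[F[f, 2], 0] - ax
            v1y = V[F[f, 2], 1] - ay
            v1z = V[F[f, 2], 2] - az
            d00 = v0x * v0x + v0y * v0y + v0z * v0z
            d01 = v0x * v1x + v0y * v1y + v0z * v1z
            d11 = v1x * v1x + v1y * v1y + v1z * v1z
            denom = d00 * d11 - d01 * d01
            sx, sy, sz = px - ax, py - ay, pz - az
            e20 = sx * v0x + sy * v0y + sz * v0z
            e21 = sx * v1x + sy * v1y + sz * v1z
            pv = (d11 * e20 - d01 * e21) / denom
            pw = (d00 * e21 - d01 * e20) / denom
            pu = 1.0 - pv - pw
            pu = max(pu, 1e-12)
            pv = max(pv, 1e-12)
            pw = max(pw, 1e-12)
            s = pu + pv + pw
            faces_out[mi] = f
            bary_out[mi, 0] = pu / s
            bary_out[mi, 1] = pv / s
            bary_out[mi, 2] = pw / s


def diffuse_on_surface(mset: SurfaceMoleculeSet, mesh: TriMesh, dt: float,
                       rng: np.random.Generator) -> SurfaceMoleculeSet:
    """One Gaussian in-plane diffusion step of per-axis variance 2·D·dt.

    D is in µm²/s and dt in µs.  Bound molecules do not move.  Steps that
    leave the host face continue into the adjacent face by unfolding across
    the shared edge; molecules never leave the surface.  Modifies ``mset`` in
    place and returns it.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if mset.diffusion == 0.0 or mset.n == 0:
        return mset
    sigma = np.sqrt(2.0 * mset.diffusion * dt * 1e-6)  # µm; D µm²/s, dt µs
    steps = rng.normal(0.0, sigma, size=(mset.n, 2))
    mobile = mset.unbound
    if not mobile.any():
        return mset
    idx = np.nonzero(mobile)[0]
    faces = mset.face[idx]
    tri = mesh.vertices[mesh.faces[faces]]               # (M, 3, 3)
    e1 = tri[:, 1] - tri[:, 0]
    e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    e2 = np.cross(nrm, e1)
    disp = steps[idx, 0:1] * e1 + steps[idx, 1:2] * e2   # (M, 3) in-plane
    p_new = np.einsum("ni,nij->nj", mset.bary[idx], tri) + disp
    # vectorised in-face update; walkers handle the minority that cross edges
    v2 = p_new - tri[:, 0]
    d00 = np.einsum("ij,ij->i", tri[:, 1] - tri[:, 0], tri[:, 1] - tri[:, 0])
    d01 = np.einsum("ij,ij->i", tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    d11 = np.einsum("ij,ij->i", tri[:, 2] - tri[:, 0], tri[:, 2] - tri[:, 0])
    d20 = np.einsum("ij,ij->i", v2, tri[:, 1] - tri[:, 0])
    d21 = np.einsum("ij,ij->i", v2, tri[:, 2] - tri[:, 0])
    denom = d00 * d11 - d01 * d01
    bv = (d11 * d20 - d01 * d21) / denom
    bw = (d00 * d21 - d01 * d20) / denom
    bu = 1.0 - bv - bw
    inside = (bu >= -1e-12) & (bv >= -1e-12) & (bw >= -1e-12)
    ins = idx[inside]
    bary_in = np.column_stack([bu[inside], bv[inside], bw[inside]])
    bary_in = np.clip(bary_in, 0.0, None)
    mset.bary[ins] = bary_in / bary_in.sum(axis=1, keepdims=True)
    crossers = np.nonzero(~inside)[0]
    if len(crossers):
        ids = idx[crossers]
        if HAVE_NUMBA:
            faces_out = np.empty(len(ids), dtype=np.int64)
            bary_out = np.empty((len(ids), 3))
            _walk_kernel(mesh.vertices, mesh.faces, mesh.face_adjacency(),
                         faces_out, bary_out,
                         mset.face[ids].copy(), mset.bary[ids].copy(),
                         disp[crossers])
            mset.face[ids] = faces_out
            mset.bary[ids] = bary_out
        else:
            for loc, i in zip(crossers, ids):
                f, b = _walk_on_surface(mesh, int(mset.face[i]),
                                        mset.bary[i], disp[loc])
                mset.face[i] = f
                mset.bary[i] = b
    return mset


# ---------------------------------------------------------------------------
# pairing and binding

def pair_candidates(mobile: SurfaceMoleculeSet, static: SurfaceMoleculeSet,
                    pairing_distance: float, match: bool = True):
    """(mobile, static) pairs within the pairing distance, both unbound.

    With ``match=True`` (default), conflicts are resolved greedily
    nearest-first — each molecule appears in at most one pair, ties broken by
    lower mobile then static id.  With ``match=False`` the full candidate set
    is returned (for oracle comparison).  Returns an (k, 2) int array of
    (mobile_id, static_id) and the matching (k,) distances.
    """
    mob_ids = np.nonzero(mobile.unbound)[0]
    sta_ids = np.nonzero(static.unbound)[0]
    empty = (np.empty((0, 2), dtype=np.int64), np.empty(0))
    if len(mob_ids) == 0 or len(sta_ids) == 0 or pairing_distance <= 0:
        return empty
    mp = mobile.positions()[mob_ids]
    sp = static.positions()[sta_ids]
    tree = cKDTree(sp)
    neigh = tree.query_ball_point(mp, r=pairing_distance)
    pairs = [(mob_ids[i], sta_ids[j]) for i, js in enumerate(neigh) for j in js]
    if not pairs:
        return empty
    pairs = np.array(pairs, dtype=np.int64)
    d = np.linalg.norm(mobile.positions()[pairs[:, 0]]
                       - static.positions()[pairs[:, 1]], axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0], d))
    pairs, d = pairs[order], d[order]
    if not match:
        return pairs, d
    used_m, used_s = set(), set()
    keep = []
    for k, (i, j) in enumerate(pairs):
        if i in used_m or j in used_s:
            continue
        used_m.add(int(i))
        used_s.add(int(j))
        keep.append(k)
    return pairs[keep], d[keep]


@dataclass
class BondTable:
    """Bond registry between a mobile set (on the cell) and a static set.

    Each bond stores the mobile anchor as (host face, barycentric) so the
    anchor follows the membrane, plus the fixed static anchor position, the
    tether stiffness k (kT/µm²) and rest length (µm).
    """
    mobile_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    static_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    face: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    bary: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    anchor: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    k: np.ndarray = field(default_factory=lambda: np.empty(0))
    rest: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> int:
        return len(self.mobile_idx)

    def append(self, mobile: SurfaceMoleculeSet, static: SurfaceMoleculeSet,
               pairs: np.ndarray, k_bond: float, rest_length: float) -> None:
        if len(pairs) == 0:
            return
        self.mobile_idx = np.concatenate([self.mobile_idx, pairs[:, 0]])
        self.static_idx = np.concatenate([self.static_idx, pairs[:, 1]])
        self.face = np.concatenate([self.face, mobile.face[pairs[:, 0]]])
        self.bary = np.vstack([self.bary, mobile.bary[pairs[:, 0]]])
        self.anchor = np.vstack([self.anchor, static.positions()[pairs[:, 1]]])
        self.k = np.concatenate([self.k, np.full(len(pairs), k_bond)])
        self.rest = np.concatenate([self.rest, np.full(len(pairs), rest_length)])

    def mobile_anchor_positions(self, mesh: TriMesh) -> np.ndarray:
        tri = mesh.vertices[mesh.faces[self.face]]
        return np.einsum("ni,nij->nj", self.bary, tri)


def bond_stiffness(per_bond_energy: float, reference_extension: float) -> float:
    """Tether stiffness such that ½·k·x_ref² = per_bond_energy (kT, µm)."""
    if reference_extension <= 0:
        raise ParameterError("reference extension must be positive")
    return 2.0 * per_bond_energy / reference_extension ** 2


def apply_binding(pairs, rule: ReactionRule, dt: float,
                  rng: np.random.Generator,
                  mobile: SurfaceMoleculeSet, static: SurfaceMoleculeSet,
                  bonds: BondTable, k_bond: float, rest_length: float) -> int:
    """Bind each candidate pair with probability 1 - exp(-k·dt).

    k is the rule's on-rate (1/s); dt is in µs.  Bound partners are flagged,
    immobilised, and excluded from future pairing.  Returns the number of new
    bonds.
    """
    if rule.rate < 0:
        raise ParameterError("negative rate")
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) == 0:
        return 0
    p = 1.0 if np.isinf(rule.rate) else -np.expm1(-rule.rate * dt * 1e-6)
    hit = rng.random(len(pairs)) < p
    new = pairs[hit]
    if len(new) == 0:
        return 0
    mobile.bond_partner[new[:, 0]] = new[:, 1]
    static.bond_partner[new[:, 1]] = new[:, 0]
    bonds.append(mobile, static, new, k_bond, rest_length)
    return len(new)


def adhesion_energy(bonds: BondTable, mesh: TriMesh) -> float:
    """Total tether energy Σ ½ k (d - rest)² over all bonds (kT)."""
    if bonds.n == 0:
        return 0.0
    d = np.linalg.norm(bonds.mobile_anchor_positions(mesh) - bonds.anchor, axis=1)
    return float(np.sum(0.5 * bonds.k * (d - bonds.rest) ** 2))
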