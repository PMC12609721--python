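"""Triangulated membrane meshes: representation, generators, geometry, OBJ I/O.

All lengths are in micrometres (µm), areas in µm², volumes in µm³.  A mesh is a
plain vertex/face container with per-face *rest areas* — the relaxed reference
areas that the elastic energy is measured against.  Rest areas are frozen at
construction and never touched by the dynamics.
"""

from __future__ import annotations

import numpy as np
import trimesh as _trimesh


class MeshError(ValueError):
    """Invalid or degenerate mesh geometry/topology."""


class ParameterError(ValueError):
    """Invalid generator or scenario parameter."""


class UnsupportedFormatError(MeshError):
    """File contains records this reader does not support (e.g. quad faces)."""


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Areas of all triangles ``faces`` over ``vertices``, vectorised."""
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


class TriMesh:
    """A triangulated membrane.

    Parameters
    ----------
    vertices : (V, 3) float array, µm
    faces : (F, 3) int array
        Consistent counterclockwise winding; outward normals for closed meshes.
    rest_area : (F,) float array, optional
        Relaxed reference area per face.  Defaults to the areas of the supplied
        geometry.  Frozen (read-only) after construction.
    boundary_vertex : (V,) bool array, optional
        Defaults to the vertices on edges that belong to exactly one face.
    rigid : bool
        Rigid meshes (e.g. the piston plane) translate as a unit and are never
        deformed by Metropolis moves.
    """

    __slots__ = ("vertices", "faces", "rest_area", "boundary_vertex", "rigid",
                 "_vf_csr", "_face_adjacency", "_is_closed")

    def __init__(self, vertices, faces, rest_area=None, boundary_vertex=None,
                 rigid: bool = False, validate: bool = True):
        self.vertices = np.array(vertices, dtype=np.float64)
        self.faces = np.array(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (F, 3) array of vertex triplets")
        if validate:
            if self.faces.size and (self.faces.min() < 0
                                    or self.faces.max() >= len(self.vertices)):
                raise MeshError("face index out of range")
            if ((self.faces[:, 0] == self.faces[:, 1])
                    | (self.faces[:, 1] == self.faces[:, 2])
                    | (self.faces[:, 0] == self.faces[:, 2])).any():
                raise MeshError("face repeats a vertex")
            areas = self.face_areas()
            if (areas <= 0.0).any():
                raise MeshError("degenerate face with zero area")
        if rest_area is None:
            rest_area = self.face_areas()
        self.rest_area = np.array(rest_area, dtype=np.float64)
        if validate and (self.rest_area <= 0.0).any():
            raise MeshError("rest areas must be strictly positive")
        self.rest_area.setflags(write=False)
        if boundary_vertex is None:
            boundary_vertex = self._detect_boundary()
        self.boundary_vertex = np.array(boundary_vertex, dtype=bool)
        self.rigid = bool(rigid)
        # topology caches (faces never change after construction)
        self._vf_csr = None
        self._face_adjacency = None
        self._is_closed = None

    # -- geometry ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.faces)

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        v0 = self.vertices[self.faces[:, 0]]
        n = np.cross(self.vertices[self.faces[:, 1]] - v0,
                     self.vertices[self.faces[:, 2]] - v0)
        if normalize:
            n = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalize=False)  # length = 2 * area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        return vn / np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-300)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, sorted pairs, shape (E, 2)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces (cached:
        topology is immutable after construction)."""
        if self._is_closed is None:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            _, counts = np.unique(np.sort(e, axis=1), axis=0,
                                  return_counts=True)
            self._is_closed = bool(len(counts) and (counts == 2).all())
        return self._is_closed

    def _detect_boundary(self) -> np.ndarray:
        flags = np.zeros(len(self.vertices), dtype=bool)
        if not len(self.faces):
            return flags
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        uniq, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        for a, b in uniq[counts == 1]:
            flags[a] = flags[b] = True
        return flags

    # -- topology caches --------------------------------------------------

    def vertex_face_incidence(self):
        """CSR arrays (ptr, idx): faces incident to each vertex."""
        if self._vf_csr is None:
            order = np.argsort(self.faces.ravel(), kind="stable")
            face_of = order // 3
            verts = self.faces.ravel()[order]
            ptr = np.zeros(self.n_vertices + 1, dtype=np.int64)
            np.add.at(ptr, verts + 1, 1)
            ptr = np.cumsum(ptr)
            self._vf_csr = (ptr, face_of.astype(np.int64))
        return self._vf_csr

    def face_adjacency(self) -> np.ndarray:
        """(F, 3) array: adjacency[f, i] is the face across the edge opposite
        vertex i of face f, or -1 on a boundary edge."""
        if self._face_adjacency is None:
            edge_map = {}
            adj = -np.ones((self.n_faces, 3), dtype=np.int64)
            for f, (a, b, c) in enumerate(self.faces):
                for i, (u, v) in enumerate(((b, c), (c, a), (a, b))):
                    key = (u, v) if u < v else (v, u)
                    if key in edge_map:
                        g, j = edge_map.pop(key)
                        adj[f, i] = g
                        adj[g, j] = f
                    else:
                        edge_map[key] = (f, i)
            self._face_adjacency = adj
        return self._face_adjacency

    # -- misc --------------------------------------------------------------

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces,
                       rest_area=self.rest_area,
                       boundary_vertex=self.boundary_vertex,
                       rigid=self.rigid, validate=False)

    def translate(self, offset) -> "TriMesh":
        """In-place rigid translation (allowed for any mesh)."""
        self.vertices += np.asarray(offset, dtype=np.float64)
        return self


# ---------------------------------------------------------------------------
# operations

def face_area(mesh: TriMesh, face_id: int) -> float:
    """Area of one face: half the cross-product magnitude of two edges."""
    if not 0 <= face_id < mesh.n_faces:
        raise IndexError(f"face index {face_id} out of range")
    i, j, k = mesh.faces[face_id]
    a = 0.5 * np.linalg.norm(np.cross(mesh.vertices[j] - mesh.vertices[i],
                                      mesh.vertices[k] - mesh.vertices[i]))
    if a <= 0.0:
        raise MeshError(f"face {face_id} is degenerate (collinear vertices)")
    return float(a)


def enclosed_volume(mesh: TriMesh) -> float:
    """Signed-tetrahedron volume of a closed mesh (positive for outward winding)."""
    if not mesh.is_closed():
        raise MeshError("enclosed_volume requires a closed (watertight) mesh")
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def generate_icosphere(subdivisions: int, radius: float,
                       ruffle_amplitude: float = 0.0,
                       seed: int | None = None) -> TriMesh:
    """Icosphere with optional seeded radial ruffles.

    Each vertex is displaced radially by a uniform random amount in
    [-ruffle_amplitude, +ruffle_amplitude]; rest areas are those of the
    generated (ruffled) geometry.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if ruffle_amplitude < 0 or ruffle_amplitude >= radius:
        raise ParameterError("ruffle amplitude must satisfy 0 <= a < radius")
    if subdivisions < 0:
        raise ParameterError("subdivisions must be non-negative")
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.asarray(ico.vertices, dtype=np.float64)
    faces = np.asarray(ico.faces, dtype=np.int64)
    if ruffle_amplitude > 0:
        rng = np.random.default_rng(seed)
        r = np.linalg.norm(verts, axis=1, keepdims=True)
        bump = rng.uniform(-ruffle_amplitude, ruffle_amplitude,
                           size=(len(verts), 1))
        verts = verts * (1.0 + bump / r)
    return TriMesh(verts, faces)


def generate_flat_grid(nx: int, ny: int, side: float) -> TriMesh:
    """Open rectangular grid of 2(nx-1)(ny-1) triangles spanning side × side
    in the xy-plane at z = 0; perimeter vertices flagged as boundary."""
    if nx < 2 or ny < 2:
        raise ParameterError("nx and ny must both be >= 2")
    if side <= 0:
        raise ParameterError("side must be positive")
    xs = np.linspace(0.0, side, nx)
    ys = np.linspace(0.0, side, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = (i + 1) * ny + j + 1
            d = i * ny + j + 1
            faces.append((a, b, c))  # CCW seen from +z
            faces.append((a, c, d))
    return TriMesh(verts, np.array(faces, dtype=np.int64))


def generate_box(lo, hi, rigid: bool = True) -> TriMesh:
    """Closed axis-aligned box chamber with outward winding."""
    lo = np.asarray(lo, dtype=np.float64)
    hi = np.asarray(hi, dtype=np.float64)
    if (hi <= lo).any():
        raise ParameterError("box must have positive extent on every axis")
    box = _trimesh.creation.box(bounds=np.vstack([lo, hi]))
    return TriMesh(np.asarray(box.vertices), np.asarray(box.faces), rigid=rigid)


# ---------------------------------------------------------------------------
# OBJ / OFF I/O
#
# Deliberately minimal readers: v/f records, triangles only.  Quad or polygon
# faces are a hard error rather than being silently triangulated.

def load_obj(path) -> TriMesh:
    verts, faces = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if tok[0] == "v":
                if len(tok) < 4:
                    raise UnsupportedFormatError(
                        f"{path}:{lineno}: vertex record needs 3 coordinates")
                verts.append([float(t) for t in tok[1:4]])
            elif tok[0] == "f":
                idx = [int(t.split("/")[0]) for t in tok[1:]]
                if len(idx) != 3:
                    raise UnsupportedFormatError(
                        f"{path}:{lineno}: only triangular faces are supported "
                        f"(got {len(idx)} vertices)")
                if any(i <= 0 for i in idx):
                    raise UnsupportedFormatError(
                        f"{path}:{lineno}: only positive 1-based indices supported")
                faces.append([i - 1 for i in idx])
    if not verts or not faces:
        raise MeshError(f"{path}: no usable v/f records found")
    return TriMesh(np.array(verts), np.array(faces))


def save_obj(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.10g} {y:.10g} {z:.10g}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def load_off(path) -> TriMesh:
    """Minimal OFF reader (triangles only)."""
    with open(path) as fh:
        tokens = [t for line in fh
                  for t in line.split("#")[0].split()]
    if not tokens or tokens[0] != "OFF":
        raise UnsupportedFormatError(f"{path}: missing OFF header")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise UnsupportedFormatError(f"{path}: only triangular faces supported")
        faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
        pos += 4
    return TriMesh(verts, np.array(faces))
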