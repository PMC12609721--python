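"""Metropolis acceptance, node-move proposals, constraints and the iteration
sweep."""

import numpy as np
import pytest

import membranemc as m
from membranemc import mc_engine as eng
from membranemc.mesh_core import ParameterError

from conftest import make_grid_state


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(m.metropolis_accept(-1.0, rng) for _ in range(100))

    def test_zero_change_accepted(self, rng):
        assert all(m.metropolis_accept(0.0, rng) for _ in range(100))

    def test_probability_formula(self):
        assert m.metropolis_probability(-3.0) == 1.0
        assert m.metropolis_probability(0.0) == 1.0
        assert m.metropolis_probability(np.log(2)) == pytest.approx(0.5)

    def test_nan_rejected(self, rng):
        with pytest.raises(ValueError):
            m.metropolis_accept(float("nan"), rng)
        with pytest.raises(ValueError):
            m.metropolis_probability(float("nan"))

    def test_detailed_balance_analytic(self, rng):
        """P(a->b)/P(b->a) = exp(-ΔE) for the acceptance rule itself."""
        for dE in rng.normal(0, 2.0, 100):
            ratio = (m.metropolis_probability(dE)
                     / m.metropolis_probability(-dE))
            assert ratio == pytest.approx(np.exp(-dE), rel=1e-12)


class TestProposeNodeMove:
    def test_clamped_vertex_is_noop(self):
        state = make_grid_state()
        boundary = int(np.nonzero(state.mesh.boundary_vertex)[0][0])
        prop = eng.propose_node_move(state, boundary, state.rng)
        assert prop.delta_E == 0.0 and np.allclose(prop.displacement, 0.0)

    def test_rigid_mesh_rejected_at_precondition(self):
        state = make_grid_state()
        state.mesh.rigid = True
        interior = int(np.nonzero(~state.mesh.boundary_vertex)[0][0])
        with pytest.raises(ParameterError):
            eng.propose_node_move(state, interior, state.rng)

    def test_sigma_zero_limit_gives_zero_delta(self):
        state = make_grid_state()
        state.config.sigma = 0.0
        interior = int(np.nonzero(~state.mesh.boundary_vertex)[0][0])
        prop = eng.propose_node_move(state, interior, state.rng)
        assert prop.delta_E == 0.0

    def test_delta_matches_full_recompute_on_3x3_grid(self, rng):
        """Locality: ΔE from the incident faces equals a brute-force
        full-mesh energy difference."""
        state = make_grid_state(nx=3, ny=3)
        state.mesh.vertices[4, 2] += 0.2  # centre vertex of the 3x3 grid
        for _ in range(20):
            prop = eng.propose_node_move(state, 4, rng)
            e0 = m.elastic_energy(state.mesh, state.config.elastic)
            old = state.mesh.vertices[4].copy()
            state.mesh.vertices[4] = old + prop.displacement
            e1 = m.elastic_energy(state.mesh, state.config.elastic)
            state.mesh.vertices[4] = old
            assert prop.delta_E == pytest.approx(e1 - e0, rel=1e-9, abs=1e-12)

    def test_nonincident_faces_untouched(self, rng):
        state = make_grid_state()
        interior = int(np.nonzero(~state.mesh.boundary_vertex)[0][0])
        ptr, fidx = state.mesh.vertex_face_incidence()
        incident = set(fidx[ptr[interior]:ptr[interior + 1]])
        areas0 = state.mesh.face_areas()
        prop = eng.propose_node_move(state, interior, rng)
        state.mesh.vertices[interior] += prop.displacement
        areas1 = state.mesh.face_areas()
        others = [f for f in range(state.mesh.n_faces) if f not in incident]
        assert np.array_equal(areas0[others], areas1[others])


class TestConstraintCheck:
    def test_leaving_movement_space_rejected(self):
        state = make_grid_state()
        state.config.box_lo = (-1.0, -1.0, 0.0)  # coverslip floor at z = 0
        interior = int(np.nonzero(~state.mesh.boundary_vertex)[0][0])
        below = eng.MoveProposal(interior, np.array([0.0, 0.0, -0.5]), 0.0)
        assert eng.constraint_check(state, below) is False

    def test_small_jiggle_accepted(self):
        state = make_grid_state()
        interior = int(np.nonzero(~state.mesh.boundary_vertex)[0][0])
        prop = eng.MoveProposal(interior, np.array([1e-4, 1e-4, 1e-4]), 0.0)
        assert eng.constraint_check(state, prop) is True

    def test_degenerate_face_rejected(self):
        state = make_grid_state(nx=3, ny=3)
        # move the centre vertex exactly onto a neighbour: zero-area faces
        disp = state.mesh.vertices[1] - state.mesh.vertices[4]
        prop = eng.MoveProposal(4, disp, 0.0)
        assert eng.constraint_check(state, prop) is False

    def test_piercing_opposing_surface_rejected(self):
        state = make_grid_state(nx=4, ny=4)
        other = m.generate_flat_grid(4, 4, 1.0)
        other.translate((0.0, 0.0, 0.05))
        state.obstacles = [other]
        interior = int(np.nonzero(~state.mesh.boundary_vertex)[0][0])
        prop = eng.MoveProposal(interior, np.array([0.0, 0.0, 0.2]), 0.0)
        assert eng.constraint_check(state, prop) is False
        down = eng.MoveProposal(interior, np.array([0.0, 0.0, -0.2]), 0.0)
        assert eng.constraint_check(state, down) is True

    def test_crossing_matches_all_pairs_oracle(self, rng):
        """Spatial-index crossing detection agrees with a brute-force
        O(n²) all-pairs triangle-intersection oracle on small meshes."""
        state = make_grid_state(nx=5, ny=5)
        other = m.generate_icosphere(1, 0.3)  # 80 faces
        other.translate((0.5, 0.5, 0.25))
        state.obstacles = [other]
        checked = 0
        for _ in range(60):
            vid = int(rng.integers(state.mesh.n_vertices))
            if state.mesh.boundary_vertex[vid]:
                continue
            disp = rng.normal(0, 0.15, 3)
            new_pos = state.mesh.vertices[vid] + disp
            fast = eng._star_crosses_obstacles(state, vid, new_pos)
            # oracle: every moved star face against every obstacle face
            ptr, fidx = state.mesh.vertex_face_incidence()
            inc = fidx[ptr[vid]:ptr[vid + 1]]
            star = state.mesh.vertices[state.mesh.faces[inc]].copy()
            star[state.mesh.faces[inc] == vid] = new_pos
            brute = any(
                eng.triangles_intersect(tri, other.vertices[of])
                for tri in star for of in other.faces)
            assert fast == brute
            checked += 1
        assert checked > 20


class TestSegmentTriangle:
    """Hand-constructed cases for the intersection primitive."""

    tri = (np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))

    @pytest.mark.parametrize("p0, p1, hits", [
        ((0.2, 0.2, -1.0), (0.2, 0.2, 1.0), True),    # through the interior
        ((0.2, 0.2, 0.5), (0.2, 0.2, 1.0), False),    # stops short
        ((2.0, 2.0, -1.0), (2.0, 2.0, 1.0), False),   # outside the triangle
        ((0.5, 0.0, -1.0), (0.5, 0.0, 1.0), True),    # through an edge
        ((0.2, 0.2, 1.0), (0.2, 0.2, -1.0), True),    # direction-reversed
    ])
    def test_cases(self, p0, p1, hits):
        assert eng.segment_triangle_intersect(
            np.array(p0, dtype=float), np.array(p1, dtype=float),
            *self.tri) is hits

    def test_batched_matches_scalar(self, rng):
        tris = rng.normal(0, 1, (30, 3, 3))
        p0 = rng.normal(0, 1, (20, 3))
        p1 = rng.normal(0, 1, (20, 3))
        scalar = any(
            eng.segment_triangle_intersect(p0[i], p1[i], *tris[j])
            for i in range(20) for j in range(30))
        assert eng._segments_cross_triangles(p0, p1, tris) == scalar


class TestStepIteration:
    def test_frozen_state_bitwise_unchanged(self):
        state = make_grid_state()
        state.config.sigma = 0.0
        before = state.mesh.vertices.copy()
        eng.step_iteration(state)
        assert np.array_equal(state.mesh.vertices, before)

    def test_uninitialized_state_rejected(self):
        state = make_grid_state()
        state.initialized = False
        with pytest.raises(ParameterError):
            eng.step_iteration(state)

    def test_iteration_counter_and_observer(self):
        state = make_grid_state()
        seen = []
        state.observer = lambda s: seen.append(s.iteration)
        for _ in range(3):
            eng.step_iteration(state)
        assert seen == [1, 2, 3]

    def test_kernel_and_python_sweeps_agree(self):
        """The numba fast path and the reference Python sweep consume the
        RNG identically and move the same vertices to the same places."""
        if not eng.HAVE_NUMBA:
            pytest.xfail("numba unavailable; only one sweep path exists")
        sA = make_grid_state(seed=3)
        sB = make_grid_state(seed=3)
        sA.mesh.vertices[14, 2] += 0.3
        sB.mesh.vertices[14, 2] += 0.3
        for _ in range(25):
            eng.sweep_nodes(sA)
        eng.HAVE_NUMBA = False
        try:
            for _ in range(25):
                eng.sweep_nodes(sB)
        finally:
            eng.HAVE_NUMBA = True
        assert np.array_equal(sA.mesh.vertices, sB.mesh.vertices)

    def test_seeded_determinism(self):
        runs = []
        for _ in range(2):
            state = make_grid_state(seed=11)
            state.mesh.vertices[14, 2] += 0.2
            for _ in range(10):
                eng.step_iteration(state)
            runs.append(state.mesh.vertices.copy())
        assert np.array_equal(runs[0], runs[1])


class TestBoltzmannSampling:
    def test_single_vertex_variance_matches_quadrature(self):
        """A free vertex tethered by the area-elastic energy samples the
        Boltzmann distribution: displacement variance within 10% of the
        3D quadrature of exp(-E)."""
        mesh, state = _hexagon_state(kappa=200.0, sigma=0.03)
        expected = _quadrature_msd(_hexagon_state(kappa=200.0, sigma=0.03)[1])
        centre0 = mesh.vertices[0].copy()
        rng = np.random.default_rng(99)
        samples = np.empty((30000, 3))
        for i in range(len(samples)):
            disp = rng.normal(0.0, state.config.sigma, 3)
            new = mesh.vertices[0] + disp
            dE = (eng._local_energy(state, 0, new)
                  - eng._local_energy(state, 0, mesh.vertices[0]))
            if dE <= 0 or rng.random() < np.exp(-dE):
                mesh.vertices[0] = new
            samples[i] = mesh.vertices[0] - centre0
        emp = (samples[2000:] ** 2).sum(axis=1).mean()
        assert emp == pytest.approx(expected, rel=0.10)


def _hexagon_state(kappa, sigma):
    """Centre vertex surrounded by a clamped hexagon (one-ring fan)."""
    angles = np.linspace(0, 2 * np.pi, 7)[:-1]
    ring = np.column_stack([0.3 * np.cos(angles), 0.3 * np.sin(angles),
                            np.zeros(6)])
    verts = np.vstack([[0.0, 0.0, 0.0], ring])
    faces = [[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)]
    boundary = np.ones(7, dtype=bool)
    boundary[0] = False
    mesh = m.TriMesh(verts, np.array(faces), boundary_vertex=boundary)
    cfg = eng.SimConfig(box_lo=(-2, -2, -2), box_hi=(2, 2, 2), sigma=sigma,
                        elastic=m.ElasticParams(kappa, 1e9))
    state = eng.SimState(config=cfg, rng=np.random.default_rng(0), mesh=mesh)
    return mesh, state


def _quadrature_msd(state):
    """E[|Δr|²] under exp(-E(Δr)) by trapezoidal quadrature on a 3D grid."""
    mesh = state.mesh
    span = 0.12
    n = 61
    ax = np.linspace(-span, span, n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tri_ids = mesh.faces
    kappa = state.config.elastic.kappa_eff
    E = np.zeros(len(pts))
    for f in range(mesh.n_faces):
        i, j, k = tri_ids[f]
        assert i == 0  # vertex 0 is the moving one in the fan construction
        p = pts + mesh.vertices[0]
        area = 0.5 * np.linalg.norm(
            np.cross(mesh.vertices[j] - p, mesh.vertices[k] - p), axis=1)
        ar = mesh.rest_area[f]
        E += kappa / (2 * ar * ar) * (area - ar) ** 2
    w = np.exp(-(E - E.min()))
    r2 = (pts ** 2).sum(axis=1)
    return float((w * r2).sum() / w.sum())
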