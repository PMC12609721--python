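"""Placement, surface diffusion, pairing, binding and adhesion energy."""

import numpy as np
import pytest
from scipy import stats

import membranemc as m
from membranemc import surface_molecules as sm
from membranemc.mesh_core import MeshError, ParameterError


def _two_face_mesh():
    """Two coplanar triangles with areas 1 and 3."""
    verts = [[0, 0, 0], [2, 0, 0], [0, 1, 0], [2, 3, 0]]
    faces = [[0, 1, 2], [1, 3, 2]]
    return m.TriMesh(verts, faces)


def _one_tri_set(points, species="S", diffusion=0.0):
    """Molecules at exact positions inside the triangle (0,0)-(4,0)-(0,4)."""
    mesh = m.TriMesh([[0, 0, 0], [4, 0, 0], [0, 4, 0]], [[0, 1, 2]])
    pts = np.asarray(points, dtype=float)
    bary = np.column_stack([1 - pts[:, 0] / 4 - pts[:, 1] / 4,
                            pts[:, 0] / 4, pts[:, 1] / 4])
    return sm.SurfaceMoleculeSet(species=species, mesh=mesh,
                                 face=np.zeros(len(pts), dtype=np.int64),
                                 bary=bary, diffusion=diffusion)


class TestPlacement:
    def test_zero_molecules(self, icosphere2):
        ms = m.place_molecules(icosphere2, 0, "TCR", seed=1)
        assert ms.n == 0

    def test_empty_mesh_rejected(self):
        tri = m.TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            m.place_molecules(tri, 5, "TCR", seed=1)

    def test_barycentric_simplex(self, icosphere2):
        ms = m.place_molecules(icosphere2, 1000, "TCR", seed=2)
        assert np.abs(ms.bary.sum(axis=1) - 1).max() < 1e-12
        assert (ms.bary >= 0).all()

    def test_area_proportional_occupancy(self):
        """Faces with areas 1:3 receive molecules 25%/75% (chi-square)."""
        ms = m.place_molecules(_two_face_mesh(), 10_000, "TCR", seed=3)
        counts = np.bincount(ms.face, minlength=2)
        res = stats.chisquare(counts, f_exp=[2500, 7500])
        assert res.pvalue > 0.01

    def test_positions_on_mesh(self, icosphere2):
        ms = m.place_molecules(icosphere2, 500, "TCR", seed=4)
        r = np.linalg.norm(ms.positions(), axis=1)
        assert (r <= 1.0 + 1e-9).all() and (r >= 0.9).all()


class TestDiffusion:
    def test_zero_diffusion_frozen(self, rng):
        grid = m.generate_flat_grid(5, 5, 2.0)
        ms = m.place_molecules(grid, 100, "A", diffusion_constant=0.0, seed=5)
        p0 = ms.positions()
        m.diffuse_on_surface(ms, grid, 1.0, rng)
        assert np.array_equal(ms.positions(), p0)

    def test_bound_molecules_do_not_move(self, rng):
        grid = m.generate_flat_grid(5, 5, 2.0)
        ms = m.place_molecules(grid, 50, "A", diffusion_constant=10.0, seed=6)
        ms.bond_partner[:] = 1  # all bound
        p0 = ms.positions()
        m.diffuse_on_surface(ms, grid, 1.0, rng)
        assert np.array_equal(ms.positions(), p0)

    def test_msd_matches_planar_law(self, rng):
        """Ensemble MSD slope within 10% of 4·D·t on a large flat grid."""
        grid = m.generate_flat_grid(30, 30, 20.0)
        D, dt, steps = 5.0, 1000.0, 50  # var = 2·D·dt·1e-6 per axis per step
        ms = m.place_molecules(grid, 2000, "A", diffusion_constant=D, seed=7)
        p0 = ms.positions()
        for _ in range(steps):
            m.diffuse_on_surface(ms, grid, dt, rng)
        msd = np.mean(((ms.positions() - p0) ** 2).sum(axis=1))
        assert msd == pytest.approx(4 * D * steps * dt * 1e-6, rel=0.10)

    def test_molecules_never_leave_surface(self, rng):
        sphere = m.generate_icosphere(2, 1.0)
        ms = m.place_molecules(sphere, 300, "A", diffusion_constant=50.0,
                               seed=8)
        for _ in range(30):
            m.diffuse_on_surface(ms, sphere, 1000.0, rng)
        # every position must lie exactly on its host face (bary in simplex)
        assert np.abs(ms.bary.sum(axis=1) - 1).max() < 1e-9
        assert (ms.bary >= -1e-12).all()
        assert ms.n == 300

    def test_dt_positive_required(self, rng):
        grid = m.generate_flat_grid(3, 3, 1.0)
        ms = m.place_molecules(grid, 5, "A", diffusion_constant=1.0, seed=9)
        with pytest.raises(ParameterError):
            m.diffuse_on_surface(ms, grid, 0.0, rng)


class TestPairing:
    def test_all_far_apart_empty(self):
        mob = _one_tri_set([(0.1, 0.1)])
        sta = _one_tri_set([(3.0, 0.5)])
        pairs, _ = m.pair_candidates(mob, sta, 0.5)
        assert len(pairs) == 0

    def test_candidates_match_brute_force(self, rng):
        grid = m.generate_flat_grid(20, 20, 10.0)
        mob = m.place_molecules(grid, 400, "A", seed=10)
        sta = m.place_molecules(grid, 400, "B", seed=11)
        pairs, _ = m.pair_candidates(mob, sta, 0.4, match=False)
        dd = np.linalg.norm(mob.positions()[:, None] - sta.positions()[None],
                            axis=2)
        brute = set(zip(*np.nonzero(dd <= 0.4)))
        assert set(map(tuple, pairs)) == brute

    def test_equidistant_tie_goes_to_lower_id(self):
        mob = _one_tri_set([(1.0, 1.0)])
        sta = _one_tri_set([(1.2, 1.0), (0.8, 1.0)])
        pairs, _ = m.pair_candidates(mob, sta, 0.5)
        assert pairs.tolist() == [[0, 0]]

    def test_one_to_one_matching(self):
        # two mobiles both nearest the same static; second-best must be used
        mob = _one_tri_set([(1.0, 1.0), (1.1, 1.0)])
        sta = _one_tri_set([(1.05, 1.0), (2.0, 2.0)])
        pairs, _ = m.pair_candidates(mob, sta, 2.5)
        matched_m = pairs[:, 0].tolist()
        matched_s = pairs[:, 1].tolist()
        assert sorted(matched_m) == [0, 1] and sorted(matched_s) == [0, 1]

    def test_bound_molecules_excluded(self):
        mob = _one_tri_set([(1.0, 1.0)])
        sta = _one_tri_set([(1.1, 1.0)])
        mob.bond_partner[0] = 0
        sta.bond_partner[0] = 0
        pairs, _ = m.pair_candidates(mob, sta, 1.0)
        assert len(pairs) == 0

    def test_invariant_under_input_ordering(self, rng):
        grid = m.generate_flat_grid(10, 10, 5.0)
        mob = m.place_molecules(grid, 100, "A", seed=12)
        sta = m.place_molecules(grid, 100, "B", seed=13)
        pairs, _ = m.pair_candidates(mob, sta, 0.3)
        # permute the static molecules and map ids back
        perm = rng.permutation(100)
        inv = np.argsort(perm)
        sta2 = sm.SurfaceMoleculeSet("B", grid, sta.face[perm].copy(),
                                     sta.bary[perm].copy(), 0.0)
        pairs2, _ = m.pair_candidates(mob, sta2, 0.3)
        undone = {(a, perm[b]) for a, b in pairs2.tolist()}
        assert undone == set(map(tuple, pairs.tolist()))


class TestBinding:
    def test_zero_rate_no_bonds(self, rng):
        mob = _one_tri_set([(1.0, 1.0)])
        sta = _one_tri_set([(1.1, 1.0)])
        rule = m.ReactionRule("A", "B", rate=0.0, pairing_distance=0.5)
        bonds = sm.BondTable()
        n = m.apply_binding(np.array([[0, 0]]), rule, 1.0, rng, mob, sta,
                            bonds, k_bond=100.0, rest_length=0.01)
        assert n == 0 and bonds.n == 0

    def test_infinite_rate_binds_all(self, rng):
        mob = _one_tri_set([(1.0, 1.0), (2.0, 1.0)])
        sta = _one_tri_set([(1.1, 1.0), (2.1, 1.0)])
        rule = m.ReactionRule("A", "B", rate=np.inf, pairing_distance=0.5)
        bonds = sm.BondTable()
        n = m.apply_binding(np.array([[0, 0], [1, 1]]), rule, 1.0, rng,
                            mob, sta, bonds, 100.0, 0.01)
        assert n == 2
        assert (mob.bond_partner == [0, 1]).all()
        assert (sta.bond_partner == [0, 1]).all()

    def test_empirical_fraction_matches_rate(self, rng):
        """Bind fraction over many candidate trials within 3 binomial SE of
        1 - exp(-k·dt)."""
        n = 20_000
        k, dt = 5e5, 1.0  # p = 1 - exp(-0.5)
        p = 1 - np.exp(-k * dt * 1e-6)
        xy = np.column_stack([np.linspace(0.1, 3.0, n),
                              np.full(n, 0.1)])
        mob = _one_tri_set(xy)
        sta = _one_tri_set(xy + [0.0, 0.01])
        rule = m.ReactionRule("A", "B", rate=k, pairing_distance=0.5)
        bonds = sm.BondTable()
        pairs = np.column_stack([np.arange(n), np.arange(n)])
        got = m.apply_binding(pairs, rule, dt, rng, mob, sta, bonds, 10.0, 0.01)
        se = np.sqrt(n * p * (1 - p))
        assert abs(got - n * p) <= 3 * se

    def test_rule_parsing(self):
        rule = m.ReactionRule.parse("TCR + pMHC -> TCR.pMHC", rate=2e5,
                                    pairing_distance=0.03)
        assert (rule.species_a, rule.species_b) == ("TCR", "pMHC")
        assert rule.product == "TCR.pMHC"
        with pytest.raises(ParameterError):
            m.ReactionRule.parse("TCR pMHC")
        with pytest.raises(ParameterError):
            m.ReactionRule("A", "B", rate=-1.0)


class TestAdhesionEnergy:
    def test_zero_bonds_zero_energy(self, icosphere2):
        assert m.adhesion_energy(sm.BondTable(), icosphere2) == 0.0

    def test_additive_and_quadratic(self):
        mesh = m.TriMesh([[0, 0, 0], [4, 0, 0], [0, 4, 0]], [[0, 1, 2]])
        bonds = sm.BondTable(
            mobile_idx=np.array([0, 1]), static_idx=np.array([0, 1]),
            face=np.array([0, 0]),
            bary=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
            anchor=np.array([[0, 0, -0.1], [4, 0, -0.1]]),
            k=np.array([100.0, 100.0]), rest=np.array([0.0, 0.0]))
        e2 = m.adhesion_energy(bonds, mesh)
        one = sm.BondTable(
            mobile_idx=bonds.mobile_idx[:1], static_idx=bonds.static_idx[:1],
            face=bonds.face[:1], bary=bonds.bary[:1], anchor=bonds.anchor[:1],
            k=bonds.k[:1], rest=bonds.rest[:1])
        assert e2 == pytest.approx(2 * m.adhesion_energy(one, mesh))
        # doubling every extension (rest = 0) quadruples the energy
        lifted = m.TriMesh(mesh.vertices + [0, 0, 0.1], mesh.faces,
                           rest_area=mesh.rest_area)
        assert m.adhesion_energy(bonds, lifted) == pytest.approx(4 * e2)

    def test_bond_stiffness_reference(self):
        # ½·k·x_ref² = E_b
        k = m.bond_stiffness(10.0, 0.05)
        assert 0.5 * k * 0.05 ** 2 == pytest.approx(10.0)
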