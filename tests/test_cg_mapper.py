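import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from sbcg2 import cg_mapper
from sbcg2.model import CGModel
from sbcg2.structure import AtomisticStructure
from sbcg2.synthetic_fixtures import (FixtureSpec, make_assembly,
                                      make_structure, rotation_about_axis)


def _simple_structure(positions, **kw):
    n = len(positions)
    defaults = dict(masses=np.full(n, 12.0), charges=np.zeros(n),
                    vdw_radii=np.full(n, 1.7),
                    hydrophobic=np.zeros(n, dtype=bool))
    defaults.update(kw)
    return AtomisticStructure(positions=np.asarray(positions, float), **defaults)


class TestAssignCells:
    def test_single_bead_takes_all(self, small_blob):
        assign = cg_mapper.assign_cells(small_blob, [[0.0, 0.0, 0.0]])
        assert (assign == 0).all()

    def test_nearer_bead_wins(self):
        s = _simple_structure([[3.0, 0.0, 0.0]])
        assign = cg_mapper.assign_cells(s, [[0, 0, 0], [10, 0, 0]])
        assert assign[0] == 0

    def test_matches_exhaustive_oracle(self, blob300):
        rng = np.random.default_rng(0)
        beads = rng.uniform(-15, 15, size=(8, 3))
        assign = cg_mapper.assign_cells(blob300, beads)
        # brute force over every atom-bead pair
        for i in range(blob300.n_atoms):
            d = np.linalg.norm(beads - blob300.positions[i], axis=1)
            assert assign[i] == d.argmin()

    def test_tie_goes_to_lowest_index(self):
        s = _simple_structure([[5.0, 0.0, 0.0]])
        assign = cg_mapper.assign_cells(s, [[0, 0, 0], [10, 0, 0]])
        assert assign[0] == 0


class TestSASA:
    def test_isolated_atom_full_sphere(self):
        s = _simple_structure([[0.0, 0.0, 0.0]])
        area = cg_mapper.compute_sasa(s, probe_radius=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)

    def test_overlap_occludes(self):
        s = _simple_structure([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        area = cg_mapper.compute_sasa(s)
        full = 4 * np.pi * 3.1**2
        assert area.sum() < 2 * full
        # fully coincident spheres: sampling points are on both surfaces,
        # strictly inside neither beyond rounding
        s2 = _simple_structure([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        a2 = cg_mapper.compute_sasa(s2)
        assert np.all(a2 < full)

    def test_against_high_density_oracle(self):
        rng = np.random.default_rng(1)
        s = _simple_structure(rng.uniform(0, 4, size=(5, 3)))
        coarse = cg_mapper.compute_sasa(s, n_points=960)
        fine = cg_mapper.compute_sasa(s, n_points=10_000)
        total = 4 * np.pi * 3.1**2
        np.testing.assert_allclose(coarse, fine, atol=0.01 * total)

    def test_biotite_cross_check(self):
        """Independent Shrake-Rupley implementation agrees within 2%."""
        import biotite.structure as struc
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 6, size=(8, 3))
        s = _simple_structure(pos)
        arr = struc.AtomArray(8)
        arr.coord = pos.astype(np.float32)
        arr.atom_name = np.full(8, "CA")
        arr.res_name = np.full(8, "ALA")
        arr.res_id = np.arange(8) + 1
        arr.chain_id = np.full(8, "A")
        arr.element = np.full(8, "C")
        ref = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                         vdw_radii="Single")
        mine = cg_mapper.compute_sasa(s, n_points=1000)
        # biotite "Single" uses r_C = 1.7 A, same as our table
        np.testing.assert_allclose(mine, ref, rtol=0.02, atol=1.0)

    def test_negative_probe_rejected(self, small_blob):
        with pytest.raises(ValueError):
            cg_mapper.compute_sasa(small_blob, probe_radius=-0.1)


class TestMapProperties:
    def test_mass_charge_conservation(self, blob300):
        rng = np.random.default_rng(3)
        beads_pos = blob300.positions[rng.choice(300, 12, replace=False)]
        assign = cg_mapper.assign_cells(blob300, beads_pos)
        beads = cg_mapper.map_properties(blob300, assign, eps_max=0.5)
        assert sum(b.mass for b in beads) == pytest.approx(
            blob300.total_mass, rel=1e-12)
        assert sum(b.charge for b in beads) == pytest.approx(
            blob300.total_charge, abs=1e-9)
        # partition: domains disjoint and exhaustive
        all_ids = np.concatenate([b.domain for b in beads])
        assert len(all_ids) == blob300.n_atoms
        assert len(np.unique(all_ids)) == blob300.n_atoms

    def test_epsilon_extremes(self):
        # all-hydrophobic exposed domain -> eps = eps_max; none -> 0
        s = _simple_structure([[0, 0, 0], [40, 0, 0]],
                              hydrophobic=np.array([True, False]))
        assign = cg_mapper.assign_cells(s, [[0, 0, 0], [40, 0, 0]])
        beads = cg_mapper.map_properties(s, assign, eps_max=0.7)
        assert beads[0].lj_epsilon == pytest.approx(0.7)
        assert beads[1].lj_epsilon == 0.0
        assert 0.0 <= beads[0].lj_epsilon <= 0.7

    def test_positions_are_mass_weighted_com(self):
        s = _simple_structure([[0, 0, 0], [3, 0, 0]],
                              masses=np.array([10.0, 30.0]))
        beads = cg_mapper.map_properties(
            s, np.zeros(2, dtype=int), sasa=np.array([1.0, 1.0]))
        np.testing.assert_allclose(beads[0].position, [2.25, 0, 0])
        # r_gyr about the COM, mass-weighted
        expect = np.sqrt((10 * 2.25**2 + 30 * 0.75**2) / 40)
        assert beads[0].radius == pytest.approx(expect)

    def test_empty_cell_errors(self, small_blob):
        assign = np.zeros(small_blob.n_atoms, dtype=int)
        assign[0] = 2  # cell 1 empty
        with pytest.raises(ValueError, match="empty"):
            cg_mapper.map_properties(small_blob, assign,
                                     sasa=np.ones(small_blob.n_atoms))


class TestBuildTopology:
    def _beads(self, n):
        s = _simple_structure(np.diag(np.arange(1.0, n + 1)) @ np.ones((n, 3)))
        return cg_mapper.map_properties(s, np.arange(n), sasa=np.ones(n))

    def test_chain_single_angle(self):
        model = cg_mapper.build_topology([(0, 1), (1, 2)], self._beads(3))
        assert model.bonds == [(0, 1), (1, 2)]
        assert model.angles == [(0, 1, 2)]

    def test_star_angles(self):
        model = cg_mapper.build_topology([(0, 1), (0, 2), (0, 3)], self._beads(4))
        assert len(model.angles) == 3  # C(3,2) at the hub
        assert all(a[1] == 0 for a in model.angles)

    def test_four_bead_cycle_matches_enumeration_oracle(self):
        # 4 beads / 4 bonds with a cycle, as in a shared-edge CG cluster
        edges = [(0, 1), (1, 2), (2, 3), (1, 3)]
        model = cg_mapper.build_topology(edges, self._beads(4))
        # oracle: brute-force scan over all (i, j, k) triples
        bond_set = {tuple(sorted(e)) for e in edges}
        expected = set()
        for j in range(4):
            for i in range(4):
                for k in range(i + 1, 4):
                    if i != j != k and \
                       tuple(sorted((i, j))) in bond_set and \
                       tuple(sorted((j, k))) in bond_set:
                        expected.add((i, j, k))
        assert set(model.angles) == expected


class TestTransferMap:
    def _monomer(self):
        s = make_structure(FixtureSpec(n_atoms=60, seed=6))
        rng = np.random.default_rng(4)
        pos = s.positions[rng.choice(60, 6, replace=False)]
        assign = cg_mapper.assign_cells(s, pos)
        beads = cg_mapper.map_properties(s, assign, sasa=np.ones(60))
        edges = [(i, i + 1) for i in range(5)]
        return s, cg_mapper.build_topology(edges, beads)

    def test_identity_transfer(self):
        s, model = self._monomer()
        out = cg_mapper.transfer_map(model, s, s)
        assert out.n_beads == model.n_beads
        np.testing.assert_allclose(out.positions, model.positions)
        assert out.bonds == model.bonds and out.angles == model.angles

    def test_three_copy_rigidity_and_counts(self):
        s, model = self._monomer()
        R = rotation_about_axis([0.0, 0.0, 1.0], 2.0)
        asm = make_assembly(s, [(np.eye(3), np.zeros(3)),
                                (R, [50.0, 0, 0]),
                                (np.eye(3), [0, 50.0, 0])])
        out = cg_mapper.transfer_map(model, s, asm)
        assert out.n_beads == 3 * model.n_beads
        assert len(out.bonds) == 3 * len(model.bonds)
        assert len(out.angles) == 3 * len(model.angles)
        # no inter-subunit bonds
        nb = model.n_beads
        assert all(i // nb == j // nb for i, j in out.bonds)
        # per-subunit internal bead distances preserved
        for c in range(3):
            sub = out.positions[c * nb:(c + 1) * nb]
            np.testing.assert_allclose(pdist(sub), pdist(model.positions),
                                       atol=1e-9)
        # conservation across the assembly
        assert out.total_mass == pytest.approx(asm.total_mass, rel=1e-12)
        assert out.total_charge == pytest.approx(asm.total_charge, abs=1e-9)

    def test_shuffled_subunit_errors(self):
        s, model = self._monomer()
        asm = make_assembly(s, [(np.eye(3), np.zeros(3))])
        asm.names = asm.names.copy()
        asm.names[3], asm.names[7] = asm.names[7], asm.names[3]
        with pytest.raises(ValueError, match="mismatch at atom 3"):
            cg_mapper.transfer_map(model, s, asm)

    def test_non_multiple_count_errors(self):
        s, model = self._monomer()
        trimmed = AtomisticStructure(
            positions=s.positions[:-1], masses=s.masses[:-1],
            charges=s.charges[:-1], vdw_radii=s.vdw_radii[:-1],
            hydrophobic=s.hydrophobic[:-1], names=s.names[:-1],
            residue_ids=s.residue_ids[:-1], chain_ids=s.chain_ids[:-1],
            elements=s.elements[:-1])
        with pytest.raises(ValueError, match="multiple"):
            cg_mapper.transfer_map(model, s, trimmed)


class TestSiteBeads:
    def test_ip6_like_bead(self):
        s = _simple_structure([[0, 0, 0]])
        beads = cg_mapper.map_properties(s, np.zeros(1, dtype=int),
                                         sasa=np.ones(1))
        model = CGModel(beads=beads)
        q0 = model.total_charge
        out = cg_mapper.add_site_beads(model, [[10.0, 0, 0]], charge=-12.0,
                                       radius=5.0, mass=660.0)
        assert out.total_charge == pytest.approx(q0 - 12.0)
        assert out.beads[-1].radius == 5.0
        assert len(out.bonds) == len(model.bonds)  # unbonded

    def test_ion_clump_and_empty_positions(self):
        q, m = cg_mapper.make_ion_clump_properties(unit_charge=1.0,
                                                   clump_size=5, ion_mass=23.0)
        assert q == 5.0 and m == 115.0
        s = _simple_structure([[0, 0, 0]])
        beads = cg_mapper.map_properties(s, np.zeros(1, dtype=int),
                                         sasa=np.ones(1))
        model = CGModel(beads=beads)
        out = cg_mapper.add_site_beads(model, np.empty((0, 3)), charge=q,
                                       radius=3.0, mass=m)
        assert out is model  # unchanged
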