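import numpy as np
import pytest

from sbcg2 import parameterize
from sbcg2.constants import KB
from sbcg2.model import AngleParam, BondParam, CGBead, CGModel, ParameterSet
from sbcg2.structure import Trajectory
from sbcg2.synthetic_fixtures import make_chain_model, make_harmonic_trajectory


def _structure_for(model):
    from sbcg2.structure import AtomisticStructure
    n = model.n_beads
    return AtomisticStructure(
        positions=model.positions, masses=np.full(n, 50.0),
        charges=np.zeros(n), vdw_radii=np.full(n, 1.7),
        hydrophobic=np.zeros(n, dtype=bool))


class TestMapTrajectoryToCG:
    def test_static_and_translation(self, chain5):
        model, _ = chain5
        s = _structure_for(model)
        static = Trajectory(xyz=np.repeat(model.positions[None], 3, axis=0))
        cg = parameterize.map_trajectory_to_cg(static, model, s)
        np.testing.assert_allclose(cg.xyz[0], model.positions)
        shift = Trajectory(xyz=static.xyz + np.array([1.0, -2.0, 3.0]))
        cg2 = parameterize.map_trajectory_to_cg(shift, model, s)
        expect = np.broadcast_to([1.0, -2.0, 3.0], cg.xyz.shape)
        np.testing.assert_allclose(cg2.xyz - cg.xyz, expect, atol=1e-12)

    def test_single_atom_domains_track_exactly(self, chain5):
        model, _ = chain5
        s = _structure_for(model)
        rng = np.random.default_rng(0)
        traj = Trajectory(xyz=rng.normal(size=(4, 5, 3)))
        cg = parameterize.map_trajectory_to_cg(traj, model, s)
        np.testing.assert_allclose(cg.xyz, traj.xyz)


class TestBoltzmannInvert:
    def test_closed_form_recovery(self, one_bond):
        """Normal(5.0, 0.2) bond at 298 K -> K ~ 7.40 kcal/mol/A^2."""
        model, _ = one_bond
        rng = np.random.default_rng(1)
        n = 100_000
        lengths = rng.normal(5.0, 0.2, size=n)
        xyz = np.zeros((n, 2, 3))
        xyz[:, 1, 0] = lengths
        params = parameterize.boltzmann_invert(Trajectory(xyz=xyz), model, T=298.0)
        k_expect = KB * 298.0 / (2.0 * 0.04)   # = 7.402...
        assert params.bonds[(0, 1)].k == pytest.approx(k_expect, rel=0.02)
        assert params.bonds[(0, 1)].b0 == pytest.approx(5.0, abs=1e-2)

    def test_recovers_generator_constants(self, chain5):
        model, true_params = chain5
        traj = make_harmonic_trajectory(model, true_params, T=298.0,
                                        n_frames=100_000, seed=2)
        inv = parameterize.boltzmann_invert(traj, model, T=298.0)
        for key, p in true_params.bonds.items():
            assert inv.bonds[key].k == pytest.approx(p.k, rel=0.05)
        for key, p in true_params.angles.items():
            assert inv.angles[key].k == pytest.approx(p.k, rel=0.05)

    def test_temperature_linearity_exact(self, one_bond):
        model, _ = one_bond
        rng = np.random.default_rng(3)
        xyz = np.zeros((1000, 2, 3))
        xyz[:, 1, 0] = rng.normal(5.0, 0.2, size=1000)
        traj = Trajectory(xyz=xyz)
        p1 = parameterize.boltzmann_invert(traj, model, T=298.0)
        p2 = parameterize.boltzmann_invert(traj, model, T=596.0)
        assert p2.bonds[(0, 1)].k == 2.0 * p1.bonds[(0, 1)].k

    def test_frozen_term_errors(self, one_bond):
        model, _ = one_bond
        xyz = np.zeros((10, 2, 3))
        xyz[:, 1, 0] = 5.0
        with pytest.raises(ValueError, match="degenerate"):
            parameterize.boltzmann_invert(Trajectory(xyz=xyz), model, T=298.0)
        with pytest.raises(ValueError, match="temperature"):
            parameterize.boltzmann_invert(Trajectory(xyz=xyz), model, T=-1.0)


class TestRefineStep:
    def _state(self, k_applied, k_measured, k_ref, m=0.5):
        applied = ParameterSet(bonds={(0, 1): BondParam(k=k_applied, b0=5.0)})
        ref = ParameterSet(bonds={(0, 1): BondParam(k=k_ref, b0=5.0)})
        st = parameterize.RefinementState(applied=applied, reference=ref,
                                          m=m, n=m)
        st.measured = ParameterSet(bonds={(0, 1): BondParam(k=k_measured, b0=5.0)})
        return st

    def test_fixed_point_when_measured_equals_reference(self):
        st = self._state(8.0, 10.0, 10.0, m=0.5)
        nxt = parameterize.refine_step(st)
        assert nxt.applied.bonds[(0, 1)].k == 8.0  # unchanged, exactly

    def test_zero_scaling_is_identity(self):
        st = self._state(8.0, 7.0, 10.0, m=0.0)
        nxt = parameterize.refine_step(st)
        assert nxt.applied.bonds[(0, 1)].k == 8.0

    def test_corrective_moves_toward_reference(self):
        st = self._state(8.0, 8.0, 10.0, m=0.5)
        nxt = parameterize.refine_step(st)
        assert nxt.applied.bonds[(0, 1)].k == pytest.approx(9.0)

    def test_verbatim_form_moves_away(self):
        st = self._state(8.0, 8.0, 10.0, m=0.5)
        nxt = parameterize.refine_step(st, verbatim=True)
        # K_{i+1} = K_i - m (K_ref - K_i) = 8 - 0.5*2 = 7: away from 10
        assert nxt.applied.bonds[(0, 1)].k == pytest.approx(7.0)

    def test_missing_measured_errors(self):
        st = self._state(8.0, 8.0, 10.0)
        st.measured = ParameterSet(bonds={})
        with pytest.raises(ValueError, match="missing measured"):
            parameterize.refine_step(st)


class TestPruneAngles:
    def _model_with_angles(self, edges, n):
        from sbcg2.cg_mapper import build_topology
        beads = [CGBead(position=[7.0 * i, float(i % 2), 0.0], mass=50.0,
                        charge=0.0) for i in range(n)]
        return build_topology(edges, beads)

    def _params(self, model, k_by_angle):
        return ParameterSet(
            bonds={b: BondParam(k=1.0, b0=5.0) for b in model.bonds},
            angles={a: AngleParam(k=k_by_angle[a], theta0=2.0)
                    for a in model.angles})

    def test_chain_single_angle_retained(self):
        model = self._model_with_angles([(0, 1), (1, 2)], 3)
        params = self._params(model, {(0, 1, 2): 4.0})
        pruned = parameterize.prune_angles(model, params)
        assert pruned.angles == [(0, 1, 2)]

    def test_star_keeps_per_bead_argmax_union(self):
        model = self._model_with_angles([(0, 1), (0, 2), (0, 3)], 4)
        ks = {(1, 0, 2): 2.0, (1, 0, 3): 5.0, (2, 0, 3): 3.0}
        pruned = parameterize.prune_angles(model, self._params(model, ks))
        # hub keeps (1,0,3); leaf 1 keeps max(2.0, 5.0) -> (1,0,3);
        # leaf 2 keeps max(2.0, 3.0) -> (2,0,3); leaf 3 keeps (1,0,3)
        assert set(pruned.angles) == {(1, 0, 3), (2, 0, 3)}

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = 7
            all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            chosen = rng.choice(len(all_pairs), size=9, replace=False)
            edges = [all_pairs[c] for c in chosen]
            model = self._model_with_angles(edges, n)
            if not model.angles:
                continue
            ks = {a: float(rng.uniform(1, 10)) for a in model.angles}
            pruned = parameterize.prune_angles(model, self._params(model, ks))
            # oracle: exhaustive per-bead argmax union
            expected = set()
            for bead in range(n):
                incident = [a for a in model.angles if bead in a]
                if incident:
                    expected.add(max(incident, key=lambda a: ks[a]))
            assert set(pruned.angles) == expected
            assert len(pruned.angles) <= n
            # every bead that had an incident angle still has one
            for bead in range(n):
                had = any(bead in a for a in model.angles)
                has = any(bead in a for a in pruned.angles)
                assert has == had or (had and has)

    def test_all_equal_ties_lexicographic(self):
        model = self._model_with_angles([(0, 1), (0, 2), (0, 3)], 4)
        ks = {a: 3.0 for a in model.angles}
        pruned = parameterize.prune_angles(model, self._params(model, ks))
        # deterministic: each bead keeps its lexicographically smallest
        # incident angle; (1,0,2) covers beads 0/1/2 and (1,0,3) bead 3
        assert set(pruned.angles) == {(1, 0, 2), (1, 0, 3)}

    def test_missing_reference_errors(self):
        model = self._model_with_angles([(0, 1), (1, 2)], 3)
        params = ParameterSet(bonds={b: BondParam(k=1.0, b0=5.0)
                                     for b in model.bonds})
        with pytest.raises(ValueError, match="reference"):
            parameterize.prune_angles(model, params)


class TestRMSE:
    def test_identical_sets_zero(self, chain5):
        _, params = chain5
        assert parameterize.rmse(params, params) == (0.0, 0.0)

    def test_single_term_difference(self):
        a = ParameterSet(bonds={(0, 1): BondParam(k=5.0, b0=5.0)})
        b = ParameterSet(bonds={(0, 1): BondParam(k=7.0, b0=5.0)})
        assert parameterize.rmse(a, b)[0] == pytest.approx(2.0)

    def test_random_sets_match_direct_formula(self):
        rng = np.random.default_rng(6)
        ka, kb = rng.uniform(1, 10, size=(2, 6))
        a = ParameterSet(bonds={(i, i + 1): BondParam(k=ka[i], b0=5.0)
                                for i in range(6)})
        b = ParameterSet(bonds={(i, i + 1): BondParam(k=kb[i], b0=5.0)
                                for i in range(6)})
        expect = float(np.sqrt(np.mean((ka - kb) ** 2)))
        assert parameterize.rmse(a, b)[0] == pytest.approx(expect, rel=1e-12)


class TestSweep:
    def test_grid_cardinality(self):
        assert len(parameterize.mn_grid()) == 81
        assert len(parameterize.mn_grid(0.5, 0.5, 0.1)) == 1

    def test_sweep_argmin_definition(self, one_bond):
        model, ref = one_bond

        def noisy_measure(applied):
            # deterministic stand-in for a CG simulation + inversion
            k = applied.bonds[(0, 1)].k
            return ParameterSet(bonds={(0, 1): BondParam(k=0.9 * k + 0.3,
                                                         b0=5.0)})

        table, best = parameterize.sweep_mn(model, ref, noisy_measure,
                                            grid=parameterize.mn_grid(0.1, 0.5, 0.2))
        rmses = [row["rmse"] for row in table]
        best_row = [r for r in table if (r["m"], r["n"]) == best][0]
        assert best_row["rmse"] == min(rmses)
        assert len(table) == 9

    def test_empty_grid_errors(self, one_bond):
        model, ref = one_bond
        with pytest.raises(ValueError, match="empty"):
            parameterize.sweep_mn(model, ref, lambda p: p, grid=[])
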