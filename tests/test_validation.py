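"""Kabsch RMSD, displacement filter, reaction bookkeeping, fixture generators."""

import numpy as np
import pytest

from tbforge.structure import Structure, from_angstrom
from tbforge.validation import (
    AssociationReaction,
    displacement_filter,
    kabsch_rmsd,
    mad,
    max_abs,
    reaction_energy,
)


def _random_rotation(rng):
    from tbforge.rotations import rotation_to_z

    return rotation_to_z(rng.normal(size=3))


class TestKabsch:
    def test_rigid_copy_has_zero_rmsd(self, rng):
        pos = rng.normal(size=(7, 3))
        A = Structure(["C"] * 7, pos * 3 + np.arange(7)[:, None])
        R = _random_rotation(rng)
        B = Structure(list(A.symbols), A.positions @ R.T + [1.0, -2.0, 0.5])
        rep = kabsch_rmsd(A, B)
        assert rep.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_two_point_closed_form(self):
        # two-atom sets of lengths L1, L2: optimal superposition leaves
        # rmsd = |L1 - L2| / 2
        L1, L2 = 2.0, 2.6
        A = Structure(["O", "O"], [[0, 0, 0], [L1, 0, 0]])
        B = Structure(["O", "O"], [[0, 0, 0], [0, L2, 0]])
        rep = kabsch_rmsd(A, B)
        assert rep.rmsd == pytest.approx(abs(L1 - L2) / 2.0, abs=1e-12)

    def test_reflected_structure_keeps_positive_rmsd(self):
        # a chiral 4-point set and its mirror image cannot be superposed by
        # proper rotations
        pos = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 2.5]])
        A = Structure(["C", "H", "H", "H"], pos)
        B = Structure(["C", "H", "H", "H"], pos * np.array([1, 1, -1]))
        rep = kabsch_rmsd(A, B)
        assert rep.rmsd > 0.1
        assert np.linalg.det(rep.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_hydrogen_exclusion(self, rng):
        pos = rng.normal(size=(5, 3)) * 2 + np.arange(5)[:, None]
        A = Structure(["O", "H", "H", "C", "N"], pos)
        moved = pos.copy()
        moved[1] += 5.0  # move only hydrogens
        moved[2] -= 4.0
        B = Structure(list(A.symbols), moved)
        rep = kabsch_rmsd(A, B, exclude=("H",))
        assert rep.rmsd == pytest.approx(0.0, abs=1e-10)
        assert rep.n_atoms == 3

    def test_all_excluded_raises(self):
        A = Structure(["H", "H"], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="excluded"):
            kabsch_rmsd(A, A, exclude=("H",))


class TestDisplacementFilter:
    def test_identical_structures_pass(self, water):
        assert displacement_filter(water, water, 1.0)

    def test_single_large_move_fails(self, water):
        moved = water.copy()
        moved.positions[2] += [0.0, 0.0, 1.5 * 1.889726]  # 1.5 Angstrom
        assert not displacement_filter(water, moved, 1.0 * 1.889726)

    def test_matches_brute_force_loop(self, rng, water):
        threshold = 0.8
        for _ in range(20):
            moved = water.copy()
            moved.positions = water.positions + rng.normal(0, 0.5, (3, 3))
            verdict = displacement_filter(water, moved, threshold)
            ref = True
            for a in range(len(water)):
                if np.linalg.norm(moved.positions[a] - water.positions[a]) > threshold:
                    ref = False
            assert verdict == ref


class TestReactions:
    def test_balance_checks(self, water):
        h = from_angstrom(["H"], [[0, 0, 0]])
        with pytest.raises(ValueError, match="element balance"):
            AssociationReaction(reactants=[(1.0, water)], products=[(1.0, h)])
        charged = water.copy()
        charged.charge = 1
        with pytest.raises(ValueError, match="charge balance"):
            AssociationReaction(reactants=[(1.0, water)],
                                products=[(1.0, charged)])

    def test_identity_reaction_is_zero(self, toy_params, water):
        rxn = AssociationReaction(reactants=[(1.0, water)],
                                  products=[(1.0, water)])
        assert reaction_energy(rxn, toy_params) == pytest.approx(0.0, abs=1e-12)

    def test_reverse_reaction_is_antisymmetric(self, toy_params, water):
        oh = from_angstrom(["O", "H"], [[0, 0, 0], [0.97, 0, 0]], charge=-1)
        hp = from_angstrom(["H"], [[0, 0, 0]], charge=1)
        rxn = AssociationReaction(
            reactants=[(1.0, oh), (1.0, hp)], products=[(1.0, water)],
        )
        fwd = reaction_energy(rxn, toy_params)
        rev = reaction_energy(rxn.reversed(), toy_params)
        assert fwd == pytest.approx(-rev, abs=1e-10)

    def test_hess_cycle_consistency(self, toy_params):
        # (O + H -> OH) + (OH + H -> H2O) must equal (O + 2H -> H2O)
        o = from_angstrom(["O"], [[0, 0, 0]])
        h = from_angstrom(["H"], [[0, 0, 0]])
        oh = from_angstrom(["O", "H"], [[0, 0, 0], [0.97, 0, 0]])
        h2o = from_angstrom(
            ["O", "H", "H"], [[0, 0, 0], [0.9572, 0, 0], [-0.2399, 0.9266, 0]]
        )
        r1 = AssociationReaction([(1.0, o), (1.0, h)], [(1.0, oh)])
        r2 = AssociationReaction([(1.0, oh), (1.0, h)], [(1.0, h2o)])
        r3 = AssociationReaction([(1.0, o), (2.0, h)], [(1.0, h2o)])
        e = [reaction_energy(r, toy_params) for r in (r1, r2, r3)]
        assert e[0] + e[1] == pytest.approx(e[2], abs=1e-8)


def test_mad_and_max_match_brute_force(rng):
    devs = rng.normal(0, 5, 40)
    assert mad(devs) == pytest.approx(sum(abs(d) for d in devs) / 40)
    assert max_abs(devs) == pytest.approx(max(abs(d) for d in devs))


class TestToyParameterGenerator:
    def test_same_seed_gives_identical_skf_files(self, tmp_path):
        from tbforge.toyparams import generate_toy_parameter_set

        a, b = tmp_path / "a", tmp_path / "b"
        generate_toy_parameter_set(("H",), seed=3, directory=a, step=0.2)
        generate_toy_parameter_set(("H",), seed=3, directory=b, step=0.2)
        fa = (a / "H-H.skf").read_bytes()
        fb = (b / "H-H.skf").read_bytes()
        assert fa == fb

    def test_set_is_closed_and_roundtrips(self, toy_params, tmp_path):
        from tbforge.skf import read_skf, write_skf

        toy_params.check_closed(["H", "O"])
        for pair, t in toy_params.tables.items():
            path = tmp_path / f"{pair[0]}-{pair[1]}.skf"
            write_skf(t, path)
            back = read_skf(path)
            for ch, v in t.h.items():
                np.testing.assert_allclose(back.h[ch], v, atol=1e-12)

    def test_water_scc_is_finite_and_convergent(self, toy_params, water):
        from tbforge.engine import scc_solve

        res = scc_solve(water, toy_params)
        assert np.isfinite(res.e_total)
        assert res.history[-1] < 1e-8


class TestSyntheticReferenceCurves:
    def test_zero_truth_zero_noise_gives_zero_residual(self, toy_params):
        from tbforge.repulsive import residual_curve
        from tbforge.toyparams import synthetic_reference_curves

        dists = np.linspace(1.6, 2.6, 5)
        structures = [
            Structure(["O", "H"], [[0, 0, 0], [d, 0, 0]]) for d in dists
        ]
        curve = synthetic_reference_curves(
            ("O", "H"), toy_params, structures, dists,
            truth=lambda d: 0.0, noise=0.0,
        )
        _, v = residual_curve(curve)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_fixed_seed_reproducible(self, toy_params):
        from tbforge.toyparams import synthetic_reference_curves

        dists = np.linspace(1.6, 2.2, 4)
        structures = [
            Structure(["O", "H"], [[0, 0, 0], [d, 0, 0]]) for d in dists
        ]
        kw = dict(truth=lambda d: np.exp(-d), noise=1e-4, seed=11)
        c1 = synthetic_reference_curves(("O", "H"), toy_params, structures,
                                        dists, **kw)
        c2 = synthetic_reference_curves(("O", "H"), toy_params, structures,
                                        dists, **kw)
        np.testing.assert_array_equal(c1.e_ref, c2.e_ref)


class TestBenchmarkHarness:
    def test_build_complex_geometry(self):
        from tbforge.benchmark import build_complex

        c = build_complex("Zr", "H2O", 8, 4)
        assert c.symbols.count("Zr") == 1
        assert c.symbols.count("O") == 8
        assert c.charge == 4
        d = c.distance_matrix()[0]
        # eight donor oxygens at the requested bond length
        assert sorted(d)[1] == pytest.approx(2.3 * 1.8897259886, rel=1e-6)

    def test_run_benchmark_collects_failures(self):
        from tbforge.validation import BenchmarkRow, run_benchmark

        rows = [BenchmarkRow("good", 1.0), BenchmarkRow("bad", 2.0)]

        def ev(row):
            if row.label == "bad":
                raise RuntimeError("species failed")
            return 1.5

        rep = run_benchmark(rows, ev)
        assert rep["mad"] == pytest.approx(0.5)
        assert "error" in rep["rows"][1]
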