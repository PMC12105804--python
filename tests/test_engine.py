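"""SCC-DFTB3 engine: brute-force oracle equivalence and physical invariants."""

import numpy as np
import pytest

from oracles import dftb3_scc_oracle
from tbforge.engine import (
    SCCError,
    dispersion_energy,
    numerical_forces,
    optimize_geometry,
    repulsive_energy,
    scc_solve,
)
from tbforge.structure import Structure, from_angstrom


def _rotate(structure, R, shift):
    new = structure.copy()
    new.positions = structure.positions @ R.T + shift
    return new


class TestOracleEquivalence:
    def test_water_matches_plain_loop_transcription(self, toy_params, water):
        res = scc_solve(water, toy_params, tol=1e-12)
        e_ref, dq_ref = dftb3_scc_oracle(water, toy_params)
        assert res.e_total == pytest.approx(e_ref, abs=1e-10)
        np.testing.assert_allclose(res.charges, dq_ref, atol=1e-8)

    @pytest.mark.parametrize("geom", [
        ("OH-", [["O", 0, 0, 0], ["H", 0.98, 0, 0]], -1),
        ("H2", [["H", 0, 0, 0], ["H", 0.75, 0, 0]], 0),
        ("H2O2", [["O", 0, 0, 0], ["O", 1.48, 0, 0],
                  ["H", -0.33, 0.90, 0], ["H", 1.81, 0.39, 0.82]], 0),
        ("H3O+", [["O", 0, 0, 0], ["H", 0.98, 0, 0],
                  ["H", -0.40, 0.90, 0], ["H", -0.40, -0.45, 0.80]], 1),
        ("O2", [["O", 0, 0, 0], ["O", 1.21, 0, 0]], 0),
    ])
    def test_fixture_molecules_match_oracle(self, toy_params, geom):
        name, atoms, charge = geom
        s = from_angstrom([a[0] for a in atoms],
                          [a[1:] for a in atoms], charge=charge)
        res = scc_solve(s, toy_params, tol=1e-12)
        e_ref, _ = dftb3_scc_oracle(s, toy_params)
        assert res.e_total == pytest.approx(e_ref, abs=1e-10), name


class TestSCCInvariants:
    def test_symmetric_dimer_has_no_charge_transfer(self, toy_params):
        h2 = from_angstrom(["H", "H"], [[0, 0, 0], [0.74, 0, 0]])
        res = scc_solve(h2, toy_params)
        np.testing.assert_allclose(res.charges, 0.0, atol=1e-12)
        assert res.e_gamma == 0.0 and res.e_gamma3 == 0.0

    def test_mulliken_charges_sum_to_net_charge(self, toy_params):
        s = from_angstrom(["O", "H", "H", "H"],
                          [[0, 0, 0], [0.98, 0, 0], [-0.40, 0.90, 0],
                           [-0.40, -0.45, 0.80]], charge=1)
        res = scc_solve(s, toy_params)
        assert res.charges.sum() == pytest.approx(-1.0, abs=1e-9)

    def test_energy_invariant_under_rigid_motion(self, toy_params, water, rng):
        from tbforge.rotations import rotation_to_z

        e0 = scc_solve(water, toy_params).e_total
        for _ in range(3):
            R = rotation_to_z(rng.normal(size=3))
            moved = _rotate(water, R, rng.normal(size=3))
            assert scc_solve(moved, toy_params).e_total == pytest.approx(
                e0, abs=1e-9
            )

    def test_second_order_limit_when_hubbard_derivs_vanish(self, toy_params, water):
        import copy

        p2 = copy.copy(toy_params)
        p2.hubbard_derivs = {k: 0.0 for k in toy_params.hubbard_derivs}
        res = scc_solve(water, p2)
        assert res.e_gamma3 == 0.0
        res3 = scc_solve(water, toy_params, third_order=False)
        assert res3.e_gamma3 == 0.0

    def test_resolve_from_converged_charges_is_idempotent(self, toy_params, water):
        res = scc_solve(water, toy_params, tol=1e-12)
        res2 = scc_solve(water, toy_params, charges0=res.charges, tol=1e-12)
        assert res2.e_total == pytest.approx(res.e_total, abs=1e-10)
        assert len(res2.history) <= 2

    def test_variational_band_energy_consistency(self, toy_params, water):
        from tbforge.engine import build_h0_s

        res = scc_solve(water, toy_params, tol=1e-12)
        H0, S, offsets, sizes = build_h0_s(water, toy_params)
        e_sum = sum(
            n * float(c @ H0 @ c)
            for n, c in zip(res.occupations, res.coefficients.T)
        )
        assert res.e_h0 == pytest.approx(e_sum, abs=1e-12)

    def test_energy_breakdown_sums_exactly(self, toy_params, water):
        res = scc_solve(water, toy_params)
        total = res.e_h0 + res.e_gamma + res.e_gamma3 + res.e_rep + res.e_disp
        assert res.e_total == total

    def test_periodic_input_rejected(self, toy_params):
        s = Structure(["H"], np.zeros((1, 3)), lattice=np.eye(3) * 5.0)
        with pytest.raises(ValueError, match="periodic"):
            scc_solve(s, toy_params)


class TestRepulsive:
    def test_matches_pair_loop_oracle(self, toy_params, rng):
        pos = rng.uniform(0, 3.0, (4, 3))
        pos += np.arange(4)[:, None] * 1.2  # avoid clashes
        s = Structure(["O", "H", "O", "H"], pos)
        e = repulsive_energy(s, toy_params)
        d = s.distance_matrix()
        ref = 0.0
        for a in range(4):
            for b in range(a + 1, 4):
                rep = toy_params.table(s.symbols[a], s.symbols[b]).repulsive
                ref += rep(d[a, b])
        assert e == pytest.approx(ref, abs=1e-14)

    def test_zero_beyond_all_cutoffs(self, toy_params):
        s = from_angstrom(["O", "O"], [[0, 0, 0], [30.0, 0, 0]])
        assert repulsive_energy(s, toy_params) == 0.0

    def test_dimer_at_knot_equals_segment_polynomial(self, toy_params):
        rep = toy_params.table("O", "O").repulsive
        k = rep.knots[2]
        c = rep.coefficients[2]
        assert rep(k) == pytest.approx(c[0], abs=1e-14)


class TestDispersion:
    def test_disabled_by_default_and_zero_for_single_atom(self, toy_params, water):
        res = scc_solve(water, toy_params)
        assert res.e_disp == 0.0
        one = Structure(["H"], np.zeros((1, 3)))
        settings = {"c6": {"H": 3.9}, "s6": 1.0}
        assert dispersion_energy(one, settings) == 0.0

    def test_pair_expression_against_direct_evaluation(self):
        s = from_angstrom(["O", "H"], [[0, 0, 0], [2.0, 0, 0]])
        settings = {"c6": {"H": 3.9, "O": 5.4}, "c8": {"H": 92.0, "O": 81.0},
                    "s6": 1.0, "s8": 0.72, "a1": 0.4, "a2": 4.8}
        e = dispersion_energy(s, settings)
        r = s.distance_matrix()[0, 1]
        c6 = np.sqrt(3.9 * 5.4)
        c8 = np.sqrt(92.0 * 81.0)
        f = 0.4 * np.sqrt(c8 / c6) + 4.8
        ref = -c6 / (r**6 + f**6) - 0.72 * c8 / (r**8 + f**8)
        assert e == pytest.approx(ref, abs=1e-14)

    def test_missing_coefficients_raise(self, water):
        with pytest.raises(ValueError):
            dispersion_energy(water, {})


class TestForcesAndOptimization:
    def test_isolated_atom_and_translational_sum(self, toy_params, water):
        f = numerical_forces(water, toy_params)
        assert np.abs(f.sum(axis=0)).max() < 1e-5

    def test_dimer_force_matches_1d_energy_spline(self, toy_params):
        from scipy.interpolate import CubicSpline

        dists = np.linspace(1.7, 1.9, 25)
        energies = []
        for d in dists:
            s = Structure(["O", "H"], [[0, 0, 0], [d, 0, 0]], charge=-1)
            energies.append(scc_solve(s, toy_params, tol=1e-11).e_total)
        spl = CubicSpline(dists, energies)
        d0 = 1.8
        s = Structure(["O", "H"], [[0, 0, 0], [d0, 0, 0]], charge=-1)
        f = numerical_forces(s, toy_params, tol=1e-11)
        dEdr = float(spl(d0, 1))
        assert f[1, 0] == pytest.approx(-dEdr, rel=1e-4, abs=1e-7)

    def test_diatomic_minimum_recovered(self, toy_params):
        # scan for the true minimum, then optimize from a perturbed start
        dists = np.linspace(1.55, 2.2, 40)
        energies = [
            scc_solve(Structure(["O", "H"], [[0, 0, 0], [d, 0, 0]], charge=-1),
                      toy_params).e_total
            for d in dists
        ]
        from scipy.interpolate import CubicSpline

        spl = CubicSpline(dists, energies)
        fine = np.linspace(dists[0], dists[-1], 2000)
        d_min = fine[np.argmin(spl(fine))]
        start = Structure(["O", "H"], [[0, 0, 0], [d_min * 1.06, 0, 0]],
                          charge=-1)
        opt, res, log = optimize_geometry(start, toy_params, fmax=1e-5)
        d_opt = np.linalg.norm(opt.positions[1] - opt.positions[0])
        assert log["converged"]
        assert d_opt == pytest.approx(d_min, abs=1e-3)
        # accepted steps never raise the energy
        e = log["energies"]
        assert e[-1] <= e[0]

    def test_start_at_minimum_converges_immediately(self, toy_params):
        dists = np.linspace(1.55, 2.2, 40)
        energies = [
            scc_solve(Structure(["O", "H"], [[0, 0, 0], [d, 0, 0]], charge=-1),
                      toy_params).e_total
            for d in dists
        ]
        from scipy.interpolate import CubicSpline

        spl = CubicSpline(dists, energies)
        fine = np.linspace(dists[0], dists[-1], 4000)
        d_min = fine[np.argmin(spl(fine))]
        start = Structure(["O", "H"], [[0, 0, 0], [d_min, 0, 0]], charge=-1)
        opt, res, log = optimize_geometry(start, toy_params, fmax=5e-4)
        assert log["converged"]
        assert len(log["energies"]) <= 4
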