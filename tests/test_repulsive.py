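"""Repulsive-potential fitting: scans, residuals, spline recovery, continuity."""

import numpy as np
import pytest

from tbforge.constants import ANGSTROM_TO_BOHR
from tbforge.repulsive import (
    ReferenceCurve,
    fit_spline,
    make_scan,
    multi_curve_fit,
    residual_curve,
)
from tbforge.structure import Structure, from_angstrom


class TestMakeScan:
    def test_crystal_scan_count_and_scaling(self):
        lat = np.diag([6.0, 6.0, 9.0])
        cell = Structure(["O", "O"], [[0, 0, 0], [3.0, 3.0, 4.5]], lattice=lat)
        scales = np.arange(0.88, 1.2501, 0.01)
        scans = make_scan(cell, (0, 1), scales)
        assert len(scans) == 38
        np.testing.assert_allclose(scans[0].lattice, 0.88 * lat, atol=1e-12)
        np.testing.assert_allclose(scans[-1].lattice, 1.25 * lat, atol=1e-10)

    def test_unit_scale_returns_input_unchanged(self, water):
        (scan,) = make_scan(water, (0, 1), [1.0])
        np.testing.assert_allclose(scan.positions, water.positions, atol=1e-14)

    def test_molecular_scan_moves_group_rigidly(self):
        # methanol-like toy: scanning the O-H bond must carry only that H
        s = from_angstrom(
            ["O", "H", "H"],
            [[0, 0, 0], [0.96, 0, 0], [-0.3, 0.9, 0]],
        )
        scales = [0.9, 1.0, 1.1]
        scans = make_scan(s, (0, 1), scales)
        d0 = np.linalg.norm(s.positions[1] - s.positions[0])
        for sc, scan in zip(scales, scans):
            d = np.linalg.norm(scan.positions[1] - scan.positions[0])
            assert d == pytest.approx(sc * d0, abs=1e-10)
            np.testing.assert_allclose(scan.positions[2], s.positions[2],
                                       atol=1e-14)

    def test_clash_detection(self):
        s = from_angstrom(["O", "H"], [[0, 0, 0], [0.4, 0, 0]])
        with pytest.raises(ValueError, match="clash"):
            make_scan(s, (0, 1), [0.3])


class TestResidualCurve:
    def _curve(self, f):
        d = np.linspace(2.0, 5.0, 20)
        e_elec = -1.0 - 0.1 * d
        return ReferenceCurve(pair=("O", "H"), distances=d,
                              e_ref=e_elec + f(d), e_elec=e_elec)

    def test_identical_energies_give_zero_target(self):
        d, v = residual_curve(self._curve(lambda d: np.zeros_like(d)))
        np.testing.assert_allclose(v, 0.0, atol=1e-14)

    def test_known_morse_recovered(self):
        def morse(d):
            return 0.2 * (1 - np.exp(-1.1 * (d - 3.0))) ** 2

        d, v = residual_curve(self._curve(morse))
        anchor = morse(d[-1])
        np.testing.assert_allclose(v, morse(d) - anchor, atol=1e-10)

    def test_anchor_is_zero_at_largest_distance(self):
        d, v = residual_curve(self._curve(lambda d: np.exp(-d)))
        assert v[-1] == 0.0


class TestFitSpline:
    def test_representable_targets_recovered_exactly(self, rng):
        truth = fit_spline(
            [(x, 5.0 * np.exp(-x / 0.6)) for x in np.linspace(1.0, 4.0, 30)],
            knots=7, cutoff=4.3,
        )
        # sample strictly inside the cubic region (the tail segment carries
        # no data and is fixed by the cutoff constraints alone)
        d = np.linspace(1.0, 3.99, 80)
        refit = fit_spline(list(zip(d, truth(d))), knots=truth.knots,
                           cutoff=truth.cutoff)
        np.testing.assert_allclose(refit(d), truth(d), atol=1e-12)

    def test_exponential_decay_recovered(self):
        d = np.linspace(1.2, 4.8, 60)
        target = 4.0 * (np.exp(-d / 0.5) - np.exp(-5.1 / 0.5))
        rep = fit_spline(list(zip(d, target)), knots=max(6, d.size // 3),
                         cutoff=5.1)
        np.testing.assert_allclose(rep(d), target, atol=1e-5)

    def test_cutoff_value_and_slope_vanish(self):
        d = np.linspace(1.0, 4.0, 40)
        rep = fit_spline(list(zip(d, np.exp(-d))), knots=8, cutoff=4.3)
        assert abs(rep(rep.cutoff - 1e-9)) < 1e-8
        assert abs(rep.derivative(rep.cutoff - 1e-6)) < 1e-5
        assert rep(rep.cutoff + 0.5) == 0.0

    def test_c2_continuity_at_knots(self):
        from math import factorial

        d = np.linspace(1.0, 4.0, 50)
        rep = fit_spline(list(zip(d, 3 * np.exp(-1.3 * d))), knots=9, cutoff=4.4)

        def left_limit(i, order):
            # exact one-sided limit from segment i-1 evaluated at its end
            h = rep.knots[i] - rep.knots[i - 1]
            c = rep.coefficients[i - 1]
            return sum(
                cj * factorial(j) / factorial(j - order) * h ** (j - order)
                for j, cj in enumerate(c) if j >= order
            )

        for i in range(1, len(rep.knots) - 1):
            for order, tol in ((0, 1e-10), (1, 1e-10), (2, 1e-8)):
                c = rep.coefficients[i]
                right = c[order] * factorial(order)
                assert abs(left_limit(i, order) - right) < tol, (i, order)

    def test_exponential_head_is_continuous(self):
        d = np.linspace(1.0, 4.0, 40)
        rep = fit_spline(list(zip(d, 6 * np.exp(-d / 0.4))), knots=8, cutoff=4.3)
        r0 = rep.knots[0]
        assert rep(r0 - 1e-9) == pytest.approx(rep(r0 + 1e-9), rel=1e-6)
        assert rep(0.6 * r0) > rep(r0)  # repulsive when extrapolating inward

    def test_underdetermined_fit_raises(self):
        with pytest.raises(ValueError, match="at least 4|no data"):
            fit_spline([(1.0, 1.0), (2.0, 0.5), (3.0, 0.2)], knots=6, cutoff=4.0)
        with pytest.raises(ValueError, match="no data"):
            fit_spline(
                [(1.0, 1.0), (1.1, 0.9), (1.2, 0.8), (4.0, 0.1), (4.1, 0.05)],
                knots=np.array([1.0, 1.5, 2.0, 2.5, 3.0, 4.5]), cutoff=4.5,
            )


class TestMultiCurveFit:
    def _synthetic_curves(self, noise, seed):
        # ground truth vanishes smoothly at the cutoff (like a physical
        # repulsive), so the zero-anchor convention is gauge-consistent
        rng = np.random.default_rng(seed)
        truth = lambda d: 2.0 * np.clip(1.0 - d / 5.0, 0.0, None) ** 3
        curves = []
        for lo, hi in ((1.3, 4.85), (2.0, 4.9)):
            d = np.linspace(lo, hi, 30)
            e_elec = -2.0 + 0.05 * d
            e_ref = e_elec + truth(d) + rng.normal(0, noise, d.size)
            curves.append(ReferenceCurve(pair=("O", "H"), distances=d,
                                         e_ref=e_ref, e_elec=e_elec))
        return curves, truth

    def test_single_curve_equals_fit_spline(self):
        curves, _ = self._synthetic_curves(0.0, 0)
        joint = multi_curve_fit(curves[:1], knots=8, cutoff=5.0)
        d, v = residual_curve(curves[0])
        direct = fit_spline(list(zip(d, v)), knots=8, cutoff=5.0)
        x = np.linspace(1.3, 4.9, 100)
        np.testing.assert_allclose(joint(x), direct(x), atol=1e-12)

    def test_duplicated_curve_changes_nothing(self):
        curves, _ = self._synthetic_curves(0.0, 0)
        one = multi_curve_fit(curves[:1], knots=8, cutoff=5.0)
        two = multi_curve_fit([curves[0], curves[0]], knots=8, cutoff=5.0)
        x = np.linspace(1.3, 4.9, 100)
        np.testing.assert_allclose(one(x), two(x), atol=1e-10)

    def test_noisy_joint_recovery_within_three_sigma(self):
        sigma = 1e-4
        curves, truth = self._synthetic_curves(sigma, 3)
        rep = multi_curve_fit(curves, knots=10, cutoff=5.0)
        x = np.linspace(1.5, 4.4, 60)
        err = np.max(np.abs(rep(x) - truth(x)))
        assert err < 3.0 * sigma

    def test_mixed_pairs_rejected(self):
        curves, _ = self._synthetic_curves(0.0, 0)
        other = ReferenceCurve(pair=("O", "O"),
                               distances=curves[0].distances,
                               e_ref=curves[0].e_ref, e_elec=curves[0].e_elec)
        with pytest.raises(ValueError, match="different pairs"):
            multi_curve_fit([curves[0], other], knots=8, cutoff=5.0)


def test_skf_spline_round_trip_evaluates_identically(tmp_path, rng):
    from tbforge.skf import read_skf, write_skf
    from tbforge.twocenter import SlaterKosterTable

    d = np.linspace(1.0, 4.0, 40)
    rep = fit_spline(list(zip(d, 5 * np.exp(-d / 0.5))), knots=9, cutoff=4.3)
    t = SlaterKosterTable(
        pair=("O", "O"), start=0.1, step=0.1, n_points=30,
        h={(0, 0, 0): rng.normal(size=30)}, s={(0, 0, 0): rng.normal(size=30)},
        onsite={0: -0.4}, hubbard={0: 0.4}, occupations={0: 2.0},
        repulsive=rep,
    )
    path = tmp_path / "O-O.skf"
    write_skf(t, path)
    back = read_skf(path).repulsive
    x = np.linspace(0.4, 5.0, 300)
    np.testing.assert_allclose(back(x), rep(x), atol=1e-12)
    np.testing.assert_allclose(back.derivative(x), rep.derivative(x), atol=1e-10)
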