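"""P(r), Debye I(q), unit conversion, scaling and radii of gyration."""

import math

import numpy as np
import pytest

from flexsaxs import (
    PofR,
    ScatteringCurve,
    compute_iq_debye,
    compute_pr,
    convert_units,
    interpolate_to_grid,
    rg_from_coords,
    rg_from_pr,
    scale_and_chi2,
)

from conftest import make_atoms


def debye_double_loop(structure, q, f=None):
    """Brute-force O(N²) Debye sum — the independent oracle."""
    coords = structure.coords
    if f is None:
        f = structure.electron_counts
    out = np.zeros_like(q, dtype=float)
    for k, qk in enumerate(q):
        total = 0.0
        for i in range(len(coords)):
            for j in range(len(coords)):
                r = np.linalg.norm(coords[i] - coords[j])
                x = qk * r
                sinc = 1.0 if x == 0 else math.sin(x) / x
                total += f[i] * f[j] * sinc
        out[k] = total
    return out


class TestConvertUnits:
    def test_inverse_nm_to_inverse_angstrom(self):
        c = ScatteringCurve(np.array([1.0, 2.0]), np.array([5.0, 6.0]))
        out = convert_units(c, "inv_nm")
        np.testing.assert_allclose(out.q, [0.1, 0.2])
        np.testing.assert_allclose(out.intensity, [5.0, 6.0])

    def test_nm_to_angstrom_conserves_area(self):
        pr = PofR(np.array([0.0, 0.5, 1.0, 1.5]), np.array([0.0, 2.0, 4.0, 1.0]))
        out = convert_units(pr, "nm")
        np.testing.assert_allclose(out.r, [0.0, 5.0, 10.0, 15.0])
        assert out.area == pytest.approx(pr.area)

    def test_identity_units(self):
        c = ScatteringCurve(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        assert convert_units(c, "inv_angstrom") is c


class TestComputePr:
    def test_two_carbons_single_bin(self):
        s = make_atoms([[0, 0, 0], [5.4, 0, 0]], element="C")
        pr = compute_pr(s)
        nonzero = np.nonzero(pr.p)[0]
        assert list(nonzero) == [5]  # 5.4 falls in bin [5, 6)
        assert pr.area == pytest.approx(2 * 12.011, rel=1e-9)

    def test_rigid_motion_invariance(self, toy_chain):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [11, 22, 33], degrees=True).as_matrix()
        moved = toy_chain.with_coords(toy_chain.coords @ rot.T + 7.5)
        pr0 = compute_pr(toy_chain)
        pr1 = compute_pr(moved)
        # same pair distances, so bit-identical histograms
        np.testing.assert_array_equal(pr1.p, pr0.p)

    def test_area_equals_molecular_mass(self, toy_chain):
        pr = compute_pr(toy_chain)
        assert pr.area == pytest.approx(toy_chain.molecular_mass, rel=1e-6)

    def test_rg_consistent_with_coordinates(self):
        rng = np.random.default_rng(5)
        s = make_atoms(rng.uniform(0, 20, size=(30, 3)), element="C")
        rg_pr = rg_from_pr(compute_pr(s))
        rg_xyz = rg_from_coords(s)
        assert rg_pr == pytest.approx(rg_xyz, abs=0.5)  # 1 Å binning tolerance

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError, match="2 atoms"):
            compute_pr(make_atoms([[0, 0, 0]]))


class TestDebye:
    def test_single_atom_flat_z_squared(self):
        s = make_atoms([[1, 2, 3]], element="N")
        q = np.linspace(0, 0.5, 11)
        iq = compute_iq_debye(s, q)
        np.testing.assert_allclose(iq.intensity, 49.0)

    def test_two_unit_scatterers_closed_form(self):
        d = 4.0
        s = make_atoms([[0, 0, 0], [d, 0, 0]], element="H")  # Z = 1
        q = np.linspace(0.0, 1.0, 21)
        iq = compute_iq_debye(s, q)
        with np.errstate(invalid="ignore"):
            expected = 2 * (1 + np.sinc(q * d / np.pi))
        assert iq.intensity[0] == pytest.approx(4.0)
        np.testing.assert_allclose(iq.intensity, expected, rtol=1e-12)

    @pytest.mark.parametrize("mode", ["point", "cromer_mann"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(17)
        s = make_atoms(
            rng.uniform(0, 15, size=(20, 3)),
            element=[["C", "N", "O", "S"][i % 4] for i in range(20)],
        )
        q = np.linspace(0.0, 0.6, 13)
        iq = compute_iq_debye(s, q, mode=mode)
        if mode == "point":
            expected = debye_double_loop(s, q)
            np.testing.assert_allclose(iq.intensity, expected, rtol=1e-10)
        else:
            from flexsaxs.profiles import _form_factors

            f = _form_factors(s, q, "cromer_mann")
            expected = np.array(
                [debye_double_loop(s, np.array([qk]), f[k])[0] for k, qk in enumerate(q)]
            )
            np.testing.assert_allclose(iq.intensity, expected, rtol=1e-10)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        s = make_atoms(rng.uniform(0, 10, size=(12, 3)))
        rot = Rotation.from_euler("xyz", [5, 15, 25], degrees=True).as_matrix()
        moved = s.with_coords(s.coords @ rot.T - 3.0)
        q = np.linspace(0.0, 0.8, 9)
        np.testing.assert_allclose(
            compute_iq_debye(moved, q).intensity,
            compute_iq_debye(s, q).intensity,
            rtol=1e-12,
        )

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_iq_debye(make_atoms([[0, 0, 0]]), np.array([-0.1, 0.1]))


class TestInterpolate:
    def test_same_grid_unchanged(self):
        c = ScatteringCurve(np.linspace(0.1, 0.5, 5), np.arange(5.0))
        out = interpolate_to_grid(c, c.q)
        np.testing.assert_array_equal(out.intensity, c.intensity)

    def test_midpoint_of_linear_curve(self):
        q = np.linspace(0.1, 0.5, 5)
        c = ScatteringCurve(q, 2 * q + 1)
        out = interpolate_to_grid(c, np.array([0.15]))
        assert out.intensity[0] == pytest.approx((c.intensity[0] + c.intensity[1]) / 2)

    def test_extrapolation_rejected(self):
        c = ScatteringCurve(np.linspace(0.1, 0.5, 5), np.arange(5.0))
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_to_grid(c, np.array([0.05]))


class TestScaleAndChi2:
    def test_exact_double_scale(self):
        q = np.linspace(0.1, 0.3, 3)
        calc = ScatteringCurve(q, np.array([1.0, 2.0, 3.0]))
        exp = ScatteringCurve(q, np.array([2.0, 4.0, 6.0]))
        res = scale_and_chi2(calc, exp)
        assert res.scale == pytest.approx(2.0)
        assert res.nchi2 == pytest.approx(0.0, abs=1e-24)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_computation(self):
        q = np.linspace(0.1, 0.3, 3)
        calc = ScatteringCurve(q, np.array([1.0, 2.0, 3.0]))
        exp = ScatteringCurve(q, np.array([2.0, 4.0, 7.0]), np.ones(3))
        res = scale_and_chi2(calc, exp)
        assert res.scale == pytest.approx(31 / 14)
        resid = np.array([2 - 31 / 14, 4 - 62 / 14, 7 - 93 / 14])
        assert res.nchi2 == pytest.approx(np.sum(resid**2) / 2)
        assert res.rmsd == pytest.approx(np.sqrt(np.mean(resid**2)))

    def test_no_sd_falls_back_to_unweighted(self):
        q = np.linspace(0.1, 0.3, 3)
        calc = ScatteringCurve(q, np.array([1.0, 2.0, 3.0]))
        exp_no_sd = ScatteringCurve(q, np.array([2.0, 4.0, 7.0]))
        exp_unit_sd = ScatteringCurve(q, np.array([2.0, 4.0, 7.0]), np.ones(3))
        r1 = scale_and_chi2(calc, exp_no_sd)
        r2 = scale_and_chi2(calc, exp_unit_sd)
        assert r1.scale == pytest.approx(r2.scale)
        assert r1.nchi2 == pytest.approx(r2.nchi2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        q = np.linspace(0.05, 0.5, 20)
        base = np.exp(-(q**2) * 40) * 1e4
        exp = ScatteringCurve(q, base * 3.3, 0.01 * base * 3.3)
        calc = ScatteringCurve(q, base * (1 + 0.02 * rng.standard_normal(20)))
        a = 7.5
        r1 = scale_and_chi2(calc, exp)
        r2 = scale_and_chi2(ScatteringCurve(q, a * calc.intensity), exp)
        assert r2.scale == pytest.approx(r1.scale / a)
        assert r2.nchi2 == pytest.approx(r1.nchi2)
        assert r2.rmsd == pytest.approx(r1.rmsd)

    def test_zero_calculated_curve_rejected(self):
        q = np.linspace(0.1, 0.3, 3)
        with pytest.raises(ValueError, match="zero"):
            scale_and_chi2(
                ScatteringCurve(q, np.zeros(3)), ScatteringCurve(q, np.ones(3))
            )


class TestRg:
    def test_two_equal_points(self):
        s = make_atoms([[0, 0, 0], [2.0, 0, 0]], element="C")
        assert rg_from_coords(s) == pytest.approx(1.0)

    def test_single_atom_zero(self):
        assert rg_from_coords(make_atoms([[5, 5, 5]])) == 0.0

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(23)
        s = make_atoms(
            rng.uniform(0, 30, size=(50, 3)),
            element=[["C", "N", "O"][i % 3] for i in range(50)],
        )
        w = s.electron_counts
        x = s.coords
        cen = (x * w[:, None]).sum(axis=0) / w.sum()
        expected = np.sqrt((w * ((x - cen) ** 2).sum(axis=1)).sum() / w.sum())
        assert rg_from_coords(s) == pytest.approx(expected, abs=1e-12)

    def test_rg_from_pr_single_bin(self):
        # two-point system at distance 5.5 (a bin center): Rg = d/sqrt(2)
        p = np.zeros(8)
        p[5] = 3.0
        pr = PofR(np.arange(8.0), p)
        assert rg_from_pr(pr) == pytest.approx(5.5 / math.sqrt(2))

    def test_rg_from_pr_uniform_sphere(self):
        radius = 40.0
        dr = 0.2
        r = np.arange(0, 2 * radius + dr, dr)
        x = r / radius
        centers = x + dr / (2 * radius)
        gamma = np.where(centers <= 2, 1 - 0.75 * centers + centers**3 / 16, 0.0)
        p = (centers * radius) ** 2 * gamma
        pr = PofR(r, np.clip(p, 0, None))
        assert rg_from_pr(pr) == pytest.approx(radius * math.sqrt(3 / 5), rel=0.01)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rg_from_pr(PofR(np.arange(5.0), np.zeros(5)))


class TestConsistencyTriangle:
    """Coordinate Rg, P(r)-moment Rg and Guinier-region Debye Rg agree."""

    def test_toy_chain_triangle(self, toy_chain):
        rg_xyz = rg_from_coords(toy_chain)
        rg_pr = rg_from_pr(compute_pr(toy_chain))
        assert rg_pr == pytest.approx(rg_xyz, abs=0.5)

        q = np.linspace(1e-4, 0.45 / rg_xyz, 30)
        iq = compute_iq_debye(toy_chain, q)
        slope = np.polyfit(q**2, np.log(iq.intensity), 1)[0]
        rg_guinier = math.sqrt(-3 * slope)
        assert rg_guinier == pytest.approx(rg_xyz, rel=0.02)

    def test_compact_blob_triangle(self):
        rng = np.random.default_rng(31)
        s = make_atoms(rng.uniform(0, 12, size=(40, 3)), element="C")
        rg_xyz = rg_from_coords(s)
        assert rg_from_pr(compute_pr(s)) == pytest.approx(rg_xyz, abs=0.5)
        q = np.linspace(1e-4, 0.45 / rg_xyz, 30)
        iq = compute_iq_debye(s, q)
        slope = np.polyfit(q**2, np.log(iq.intensity), 1)[0]
        assert math.sqrt(-3 * slope) == pytest.approx(rg_xyz, rel=0.02)
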