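"""Scattering: Debye curves, Guinier, P(r), Porod, arms, GA ensembles."""

import numpy as np
import pytest

from oligoxl import saxs
from oligoxl import synthetic


def sphere_curve(radius_nm, q, i0=1.0):
    x = q * radius_nm
    return saxs.SAXSCurve(q, i0 * (3 * (np.sin(x) - x * np.cos(x))
                                   / x ** 3) ** 2)


class TestDebye:
    def test_single_point_constant(self):
        q = np.linspace(0.1, 3.0, 10)
        c = saxs.debye_curve(np.zeros((1, 3)), q, form_factor=2.0)
        np.testing.assert_allclose(c.intensity, 4.0)

    def test_two_point_closed_form(self):
        q = np.linspace(0.1, 5.0, 50)
        r = 7.5  # A
        pts = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        c = saxs.debye_curve(pts, q)
        x = q * r / 10.0
        np.testing.assert_allclose(c.intensity, 2 * (1 + np.sin(x) / x),
                                   rtol=1e-12)

    def test_forward_scattering_is_n_squared(self, sphere_cloud):
        pts, _ = sphere_cloud
        c = saxs.debye_curve(pts, np.array([1e-6]))
        assert c.intensity[0] == pytest.approx(len(pts) ** 2, rel=1e-9)

    def test_positive_everywhere(self, sphere_cloud):
        pts, _ = sphere_cloud
        c = saxs.debye_curve(pts[:400], np.linspace(0.05, 10.0, 200))
        assert np.all(c.intensity > 0)

    def test_matches_analytic_sphere(self, sphere_cloud):
        pts, radius = sphere_cloud
        r_nm = radius / 10.0
        q = np.linspace(0.05, 5.0 / r_nm, 80)  # q R <= 5
        c = saxs.debye_curve(pts, q)
        expected = sphere_curve(r_nm, q).intensity
        dev = np.abs(c.intensity / c.intensity[0] - expected)
        assert dev.max() < 0.02

    def test_histogram_path_agrees_with_exact(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(300, 3)) * 15
        q = np.linspace(0.05, 3.0, 40)
        exact = saxs.debye_curve(pts, q)
        fast = saxs.debye_curve(pts, q, exact_pair_limit=10)
        # 0.1 A binning bounds the phase error at q*dr/2 < 1.5% here
        np.testing.assert_allclose(fast.intensity, exact.intensity,
                                   rtol=5e-3)

    def test_empty_coordinates_raises(self):
        with pytest.raises(saxs.SAXSError):
            saxs.debye_curve(np.zeros((0, 3)), np.array([0.1]))


class TestGuinier:
    def test_sphere_rg_analytic(self):
        q = np.linspace(0.02, 1.5, 120)
        c = sphere_curve(2.0, q)
        fit = saxs.guinier_fit(c)
        assert fit["rg"] == pytest.approx(2.0 * np.sqrt(3.0 / 5.0), rel=0.01)
        assert fit["i0"] == pytest.approx(1.0, rel=0.01)

    def test_matches_coordinate_rg_on_noiseless_curves(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cloud = rng.normal(size=(rng.integers(30, 150), 3)) * 12
            rg_true = saxs.coordinate_rg(cloud)
            q = np.linspace(0.01, 1.8 / rg_true, 80)
            fit = saxs.guinier_fit(saxs.debye_curve(cloud, q))
            assert fit["rg"] == pytest.approx(rg_true, rel=0.01)

    def test_range_respects_qrg_bound(self):
        q = np.linspace(0.02, 3.0, 200)
        fit = saxs.guinier_fit(sphere_curve(2.0, q))
        assert fit["q_range"][1] * fit["rg"] <= 1.3 + 1e-9

    def test_out_of_range_curve_raises(self):
        # every point has q Rg >= 1.3 for Rg ~ 1.55 nm
        q = np.linspace(2.0, 3.0, 30)
        with pytest.raises(saxs.SAXSError):
            saxs.guinier_fit(sphere_curve(2.0, q))


class TestPairDistribution:
    def test_two_point_single_peak(self):
        pts = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        pr = saxs.pair_distribution(pts, n_bins=61)
        peak_r = pr.r[np.argmax(pr.p)]
        assert peak_r == pytest.approx(1.2, abs=pr.r[1] - pr.r[0] + 1e-9)

    def test_sphere_dmax_is_diameter(self, sphere_cloud):
        pts, radius = sphere_cloud
        pr = saxs.pair_distribution(pts)
        assert pr.dmax == pytest.approx(2 * radius / 10.0, abs=0.1)

    def test_indirect_transform_round_trip(self, sphere_cloud):
        pts, radius = sphere_cloud
        sub = pts[::4]
        q = np.linspace(0.05, 6.0, 120)
        curve = saxs.debye_curve(sub, q)
        curve = saxs.SAXSCurve(q, curve.intensity,
                               1e-3 * curve.intensity[0] * np.ones_like(q))
        pr_fit = saxs.pair_distribution(curve, n_bins=61,
                                        dmax_nm=2 * radius / 10.0)
        pr_ref = saxs.pair_distribution(sub, n_bins=61)
        p1 = np.interp(pr_ref.r, pr_fit.r, pr_fit.p)
        p1 /= np.trapezoid(p1, pr_ref.r)
        l2 = (np.trapezoid((p1 - pr_ref.p) ** 2, pr_ref.r)
              / np.trapezoid(pr_ref.p ** 2, pr_ref.r)) ** 0.5
        assert l2 < 0.05

    def test_nonnegative_with_zero_ends(self, sphere_cloud):
        pts, radius = sphere_cloud
        q = np.linspace(0.05, 6.0, 100)
        curve = saxs.debye_curve(pts[::6], q)
        pr = saxs.pair_distribution(curve, n_bins=41)
        assert np.all(pr.p >= -1e-12)
        assert pr.p[0] == pytest.approx(0.0, abs=1e-6 * max(pr.p.max(), 1))
        assert pr.p[-1] == pytest.approx(0.0, abs=1e-6 * max(pr.p.max(), 1))


class TestPorod:
    def test_sphere_volume_within_ten_percent(self):
        r_nm = 2.0
        q = np.linspace(0.02, 12.0, 600)
        result = saxs.porod(sphere_curve(r_nm, q), 1.0)
        v_true = 4.0 / 3.0 * np.pi * r_nm ** 3
        assert result.volume == pytest.approx(v_true, rel=0.10)
        assert result.mass_porod == result.volume / 1.6

    def test_published_table_arithmetic(self):
        assert saxs.round_half_up(saxs.porod_mass(510)) == 319
        assert saxs.round_half_up(saxs.porod_mass(116)) == 73
        assert saxs.dammif_mass(544) == pytest.approx(272)


class TestChi2:
    def test_identical_curves_zero(self):
        q = np.linspace(0.1, 3.0, 30)
        c = sphere_curve(2.0, q, i0=100.0)
        exp = saxs.SAXSCurve(q, c.intensity, 0.05 * c.intensity)
        assert saxs.chi2(c, exp) == pytest.approx(0.0, abs=1e-18)

    def test_scale_invariance(self):
        q = np.linspace(0.1, 3.0, 30)
        c = sphere_curve(2.0, q, i0=100.0)
        exp = saxs.SAXSCurve(q, c.intensity, 0.05 * c.intensity)
        doubled = saxs.SAXSCurve(q, 2.0 * c.intensity)
        assert saxs.chi2(doubled, exp) == pytest.approx(0.0, abs=1e-18)

    def test_hand_computed_three_points(self):
        # model (1,2,3), exp (2,2,2), sigma 1; optimal scale
        # c = sum(Im*Ie)/sum(Im^2) = 12/14
        model = saxs.SAXSCurve([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        exp = saxs.SAXSCurve([1.0, 2.0, 3.0], [2.0, 2.0, 2.0],
                             [1.0, 1.0, 1.0])
        c = 12.0 / 14.0
        expected = sum((c * m - 2.0) ** 2 for m in (1.0, 2.0, 3.0)) / 2.0
        assert saxs.chi2(model, exp) == pytest.approx(expected, rel=1e-12)


class TestArms:
    def test_zero_length_returns_cores(self, toy_dimer):
        core = toy_dimer.ca_coords()
        pool = saxs.generate_arms(core, core[:1], arm_length=0, n=3, seed=1)
        assert len(pool) == 3
        for conf in pool.conformers:
            np.testing.assert_allclose(conf.coords, core)

    def test_outside_arms_increase_rg(self, toy_dimer):
        core = toy_dimer.ca_coords()
        anchor = core[np.argmax(np.linalg.norm(core - core.mean(0), axis=1))]
        pool = saxs.generate_arms(core, [anchor], arm_length=15, n=10, seed=2,
                                  mode="outside")
        rg_core = saxs.coordinate_rg(core)
        assert len(pool) > 0
        mean_rg = np.mean([c.rg_nm for c in pool.conformers])
        assert mean_rg > rg_core

    def test_inside_vs_outside_rg_distributions(self):
        asm, _, _ = synthetic.make_assembly_fixture(30, 35, seed=4,
                                                    n_residues=20)
        core = asm.ca_coords()
        centre = core.mean(axis=0)
        anchors = core[np.argsort(np.linalg.norm(core - centre, axis=1))[-3:]]
        out_pool = saxs.generate_arms(core, anchors, arm_length=12, n=12,
                                      seed=3, mode="outside")
        in_anchor = core[np.argsort(np.linalg.norm(core - centre, axis=1))[:3]]
        in_pool = saxs.generate_arms(core, in_anchor, arm_length=12, n=12,
                                     seed=3, mode="inside")
        assert len(out_pool) and len(in_pool)
        assert (np.mean([c.rg_nm for c in out_pool.conformers])
                > np.mean([c.rg_nm for c in in_pool.conformers]))

    def test_walk_geometry(self, toy_dimer):
        core = toy_dimer.ca_coords()
        pool = saxs.generate_arms(core, core[:1], arm_length=10, n=2, seed=5)
        n_core = len(core)
        for conf in pool.conformers:
            arm = conf.coords[n_core:]
            steps = np.linalg.norm(np.diff(
                np.vstack([core[0], arm]), axis=0), axis=1)
            np.testing.assert_allclose(steps, 3.8, rtol=1e-9)


class TestEnsemble:
    def test_self_recovery(self):
        q = np.linspace(0.05, 3.0, 50)
        pools = synthetic.make_oligomer_pools(
            q, states=("dodecamer",), n_per_state=15, arm_length=8,
            n_residues=15, seed=6)
        target = pools[0].conformers[4].curve
        exp = saxs.SAXSCurve(q, target.intensity,
                             1e-4 * target.intensity[0] * np.ones_like(q))
        ens = saxs.optimize_ensemble(pools, exp, generations=120, seed=6)
        assert ens.chi2 < 1e-3

    def test_weights_normalized_and_seeded_reproducible(self):
        curve, _, pools = synthetic.make_saxs_mixture(
            {"dodecamer": 0.7, "hexamer": 0.3}, noise=0.01, seed=7,
            n_per_state=15, arm_length=8, n_residues=15)
        e1 = saxs.optimize_ensemble(pools, curve, generations=60, seed=1)
        e2 = saxs.optimize_ensemble(pools, curve, generations=60, seed=1)
        assert e1.weights.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(e1.weights, e2.weights)
        assert e1.chi2 == e2.chi2

    def test_wrong_pool_fits_worse(self):
        q = np.linspace(0.05, 3.0, 50)
        pools = synthetic.make_oligomer_pools(
            q, states=("dodecamer", "dimer"), n_per_state=12, arm_length=8,
            n_residues=15, seed=8)
        dodeca, dimer = pools
        curve, _, _ = synthetic.make_saxs_mixture(
            {"dodecamer": 1.0}, noise=0.01, q=q, seed=8,
            pools=[dodeca])
        matched = saxs.optimize_ensemble([dodeca], curve, generations=80,
                                         seed=2)
        mismatched = saxs.optimize_ensemble([dimer], curve, generations=80,
                                            seed=2)
        assert matched.chi2 < mismatched.chi2

    def test_empty_pool_raises(self):
        q = np.linspace(0.1, 1.0, 10)
        exp = saxs.SAXSCurve(q, np.ones_like(q))
        with pytest.raises(saxs.SAXSError):
            saxs.optimize_ensemble(saxs.ConformerPool([], "dodecamer"), exp)


class TestCurveIO:
    def test_round_trip(self, tmp_path):
        q = np.linspace(0.1, 2.0, 20)
        c = saxs.SAXSCurve(q, np.exp(-q), 0.01 * np.exp(-q))
        path = tmp_path / "curve.dat"
        saxs.write_curve(c, path)
        back = saxs.read_curve(path)
        np.testing.assert_allclose(back.q, c.q, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-6)

    def test_angstrom_unit_conversion(self, tmp_path):
        path = tmp_path / "curve_a.dat"
        path.write_text("0.01 1.0 0.1\n0.02 0.5 0.1\n")
        c = saxs.read_curve(path, unit="A")
        np.testing.assert_allclose(c.q, [0.1, 0.2])

    def test_invalid_curve_rejected(self):
        with pytest.raises(saxs.SAXSError):
            saxs.SAXSCurve([0.2, 0.1], [1.0, 1.0])
        with pytest.raises(saxs.SAXSError):
            saxs.SAXSCurve([0.1, 0.2], [1.0, 1.0], [0.0, 1.0])
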