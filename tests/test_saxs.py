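"""Scattering transforms against closed forms and geometric oracles."""

import numpy as np
import pytest

from smlight import saxs, synthetic as syn

from oracles import sphere_pofr_mc


@pytest.fixture(scope="module")
def sphere30():
    return syn.sphere_points(30.0, n_points=1200, seed=0)


@pytest.fixture(scope="module")
def sphere_profile(sphere30):
    q = np.linspace(1e-3, 4.0 / 30.0, 60)
    return saxs.debye_profile(sphere30, q)


class TestDebyeProfile:
    def test_single_point_scatters_flat(self):
        coords = saxs.CoordinateSet(points=np.zeros((1, 3)), weights=np.ones(1),
                                    labels=[("A", 1, "CA")])
        curve = saxs.debye_profile(coords, np.linspace(0.0, 0.5, 20))
        np.testing.assert_allclose(curve.intensity, 1.0, rtol=1e-12)

    def test_two_point_closed_form(self):
        d = 10.0
        coords = saxs.CoordinateSet(
            points=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]]),
            weights=np.ones(2), labels=[("A", 1, "CA"), ("A", 2, "CA")],
        )
        q = np.linspace(0.0, 0.6, 40)
        curve = saxs.debye_profile(coords, q)
        expected = 2.0 * (1.0 + np.sinc(q * d / np.pi))
        np.testing.assert_allclose(curve.intensity, expected, rtol=1e-12)
        assert curve.intensity[0] == pytest.approx(4.0)

    def test_zero_angle_is_total_weight_squared(self, sphere30):
        curve = saxs.debye_profile(sphere30, np.array([0.0]))
        assert curve.intensity[0] == pytest.approx(sphere30.weights.sum() ** 2,
                                                   rel=1e-12)

    def test_sphere_matches_analytic_form_factor(self, sphere_profile):
        """Debye sum over a uniform ball tracks the sphere form factor <=2%."""
        norm = sphere_profile.intensity / sphere_profile.intensity[0]
        analytic = saxs.sphere_form_factor(sphere_profile.q, 30.0)
        assert np.max(np.abs(norm - analytic)) < 0.02

    def test_histogram_acceleration_matches_direct(self, sphere30):
        q = np.linspace(1e-3, 0.3, 40)
        direct = saxs.debye_profile(sphere30, q, method="direct").intensity
        hist = saxs.debye_profile(sphere30, q, method="histogram").intensity
        np.testing.assert_allclose(hist, direct, rtol=1e-3)

    def test_rigid_motion_invariance(self, sphere30):
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        moved = saxs.CoordinateSet(
            points=sphere30.points @ rot.T + np.array([5.0, -3.0, 11.0]),
            weights=sphere30.weights, labels=sphere30.labels,
        )
        q = np.linspace(1e-3, 0.3, 30)
        a = saxs.debye_profile(sphere30, q).intensity
        b = saxs.debye_profile(moved, q).intensity
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_intensity_bounded_by_zero_angle(self, sphere_profile):
        assert (sphere_profile.intensity <= sphere_profile.intensity[0] * (1 + 1e-12)).all()


class TestGuinier:
    def test_exact_guinier_curve_recovered(self):
        q = np.linspace(1e-3, 0.05, 300)
        curve = saxs.SaxsCurve(q=q, intensity=100.0 * np.exp(-(q * 30.0) ** 2 / 3.0))
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(30.0, rel=1e-6)
        assert res.i0 == pytest.approx(100.0, rel=1e-6)

    def test_sphere_rg_closed_form(self, sphere_profile):
        """Rg of a solid sphere is R sqrt(3/5); fitted in the true low-q limit."""
        res = saxs.guinier_fit(sphere_profile, qrg_max=0.8)
        assert res.rg == pytest.approx(30.0 * np.sqrt(3.0 / 5.0), rel=0.01)

    def test_intensity_scaling_moves_i0_only(self, sphere_profile):
        scaled = saxs.SaxsCurve(q=sphere_profile.q,
                                intensity=sphere_profile.intensity * 7.0)
        a = saxs.guinier_fit(sphere_profile)
        b = saxs.guinier_fit(scaled)
        assert b.rg == pytest.approx(a.rg, rel=1e-9)
        assert b.i0 == pytest.approx(7.0 * a.i0, rel=1e-9)

    def test_rising_curve_rejected(self):
        q = np.linspace(1e-3, 0.05, 50)
        curve = saxs.SaxsCurve(q=q, intensity=1.0 + (q * 30.0) ** 2)
        with pytest.raises(saxs.GuinierError):
            saxs.guinier_fit(curve)


class TestKratky:
    @pytest.fixture()
    def guinier_curve(self):
        q = np.linspace(1e-3, 0.12, 600)
        return saxs.SaxsCurve(q=q, intensity=50.0 * np.exp(-(q * 30.0) ** 2 / 3.0))

    def test_peak_at_globular_point(self, guinier_curve):
        """Exact Guinier intensity peaks at (sqrt(3), 3/e) in dimensionless form."""
        g = saxs.guinier_fit(guinier_curve)
        _, _, (xp, yp) = saxs.dimensionless_kratky(guinier_curve, g)
        assert xp == pytest.approx(np.sqrt(3.0), abs=1e-3)
        assert yp == pytest.approx(3.0 / np.e, abs=1e-4)

    def test_invariant_under_intensity_rescale(self, guinier_curve):
        g1 = saxs.guinier_fit(guinier_curve)
        scaled = saxs.SaxsCurve(q=guinier_curve.q,
                                intensity=guinier_curve.intensity * 13.0)
        g2 = saxs.guinier_fit(scaled)
        _, y1, _ = saxs.dimensionless_kratky(guinier_curve, g1)
        _, y2, _ = saxs.dimensionless_kratky(scaled, g2)
        np.testing.assert_allclose(y1, y2, rtol=1e-9)

    def test_flexible_chain_peak_shifts_right(self):
        """A Gaussian-chain profile plateaus with its peak right of sqrt(3)."""
        rg = 30.0
        q = np.linspace(1e-3, 0.2, 800)
        curve = saxs.SaxsCurve(q=q, intensity=80.0 * saxs.debye_chain_intensity(q, rg))
        g = saxs.guinier_fit(curve)
        x, y, (xp, _) = saxs.dimensionless_kratky(curve, g)
        assert xp > np.sqrt(3.0)
        tail = y[x > 4.0]
        assert tail.size and np.all(tail > 1.0)   # plateau, no fall-off


class TestPofr:
    @pytest.fixture(scope="class")
    def sphere_curve(self):
        q = np.linspace(1e-3, 0.35, 80)
        return saxs.SaxsCurve(q=q, intensity=saxs.sphere_form_factor(q, 30.0))

    def test_sphere_pofr_matches_analytic(self, sphere_curve):
        p = saxs.pofr_ift(sphere_curve, dmax=60.0)
        analytic = saxs.sphere_pofr(p.r, 30.0)
        analytic /= np.trapezoid(analytic, p.r)
        mine = p.p / np.trapezoid(p.p, p.r)
        nrms = np.sqrt(np.mean((mine - analytic) ** 2)) / analytic.max()
        assert nrms < 0.03
        assert p.p[0] == 0.0 and p.p[-1] == 0.0
        assert (p.p >= 0).all()

    def test_analytic_pofr_agrees_with_monte_carlo(self):
        """Cross-check of the closed-form sphere p(r) against direct sampling."""
        r = np.linspace(1.0, 59.0, 30)
        mc = sphere_pofr_mc(30.0, r, n_samples=200_000, seed=1)
        analytic = saxs.sphere_pofr(r, 30.0)
        analytic /= np.trapezoid(analytic, r)
        assert np.sqrt(np.mean((mc - analytic) ** 2)) / analytic.max() < 0.02

    def test_second_moment_rg_matches_guinier(self, sphere_curve):
        p = saxs.pofr_ift(sphere_curve, dmax=60.0)
        g = saxs.guinier_fit(sphere_curve, qrg_max=0.8)
        assert p.rg() == pytest.approx(g.rg, rel=0.02)

    def test_forward_transform_refits_profile(self, sphere_curve):
        p = saxs.pofr_ift(sphere_curve, dmax=60.0)
        model = saxs.SaxsCurve(q=sphere_curve.q, intensity=p.predict(sphere_curve.q))
        _, chi, _, _ = saxs.fit_profile(model, sphere_curve)
        assert chi < 1.5

    def test_chi2_nondecreasing_in_alpha(self, sphere_curve):
        chis = []
        for alpha in (1e2, 1e5, 1e8, 1e11):
            p = saxs.pofr_ift(sphere_curve, dmax=60.0, alpha=alpha)
            resid = sphere_curve.intensity - p.predict(sphere_curve.q)
            chis.append(float(np.sum(resid**2)))
        assert all(b >= a * (1 - 1e-9) for a, b in zip(chis, chis[1:]))

    def test_underestimated_dmax_warns(self, sphere_curve):
        with pytest.warns(UserWarning, match="dmax"):
            saxs.pofr_ift(sphere_curve, dmax=25.0, alpha=1.0)


class TestProfileFit:
    def test_identity_fit(self):
        q = np.linspace(0.01, 0.3, 50)
        i = saxs.sphere_form_factor(q, 25.0)
        c = saxs.SaxsCurve(q=q, intensity=i, sigma=np.ones(50))
        scale, chi, resid, _ = saxs.fit_profile(c, c)
        assert scale == pytest.approx(1.0)
        assert chi == pytest.approx(0.0, abs=1e-12)

    def test_doubled_model_halves_scale(self):
        q = np.linspace(0.01, 0.3, 50)
        i = saxs.sphere_form_factor(q, 25.0)
        expt = saxs.SaxsCurve(q=q, intensity=i, sigma=np.ones(50))
        model = saxs.SaxsCurve(q=q, intensity=2.0 * i)
        scale, chi, _, _ = saxs.fit_profile(model, expt)
        assert scale == pytest.approx(0.5)
        assert chi == pytest.approx(0.0, abs=1e-12)

    def test_unit_noise_gives_unit_chi(self):
        """With N(0, sigma) residuals the reduced chi concentrates near 1."""
        q = np.linspace(0.01, 0.3, 200)
        base = 1000.0 * saxs.sphere_form_factor(q, 25.0)
        sigma = np.full(q.size, 5.0)
        chis = []
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0, 5.0, q.size)
            expt = saxs.SaxsCurve(q=q, intensity=base + noise, sigma=sigma)
            model = saxs.SaxsCurve(q=q, intensity=base)
            _, chi, _, _ = saxs.fit_profile(model, expt)
            chis.append(chi)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_disjoint_ranges_rejected(self):
        a = saxs.SaxsCurve(q=np.linspace(0.01, 0.1, 25),
                           intensity=np.ones(25))
        b = saxs.SaxsCurve(q=np.linspace(0.2, 0.3, 25),
                           intensity=np.ones(25))
        with pytest.raises(ValueError, match="overlap"):
            saxs.fit_profile(a, b)


class TestResidueDistances:
    def test_pythagorean_distance(self):
        coords = saxs.CoordinateSet(
            points=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
            weights=np.ones(2), labels=[("A", 1, "CA"), ("A", 2, "CA")],
        )
        assert saxs.residue_distance(coords, 1, 2) == pytest.approx(5.0)
        assert saxs.residue_distance(coords, 2, 1) == pytest.approx(5.0)

    def test_missing_residue_named_in_error(self):
        coords = saxs.CoordinateSet(
            points=np.zeros((2, 3)) + np.arange(2)[:, None],
            weights=np.ones(2), labels=[("A", 1, "CA"), ("A", 2, "CA")],
        )
        with pytest.raises(KeyError, match="99"):
            saxs.residue_distance(coords, 1, 99)

    @pytest.mark.parametrize("distance", [45.0, 62.0])
    def test_two_state_fixture_reports_designed_separation(self, distance):
        """Compact vs extended toy conformers carry their designed Ca spans."""
        fx = syn.two_state_calpha_fixture(distance, n_residues=40, seed=3)
        first = fx.labels[0][1]
        last = fx.labels[-1][1]
        assert saxs.residue_distance(fx, first, last) == pytest.approx(distance,
                                                                       rel=1e-9)

    def test_pdb_round_trip(self, tmp_path):
        """A synthetic PDB written from the fixture reads back to the same Ca set."""
        fx = syn.two_state_calpha_fixture(45.0, n_residues=8, seed=1)
        lines = []
        for i, (pt, (ch, num, _)) in enumerate(zip(fx.points, fx.labels)):
            lines.append(
                f"ATOM  {i+1:5d}  CA  ALA {ch}{num:4d}    "
                f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        path = tmp_path / "synthetic_two_state.pdb"
        path.write_text("\n".join(lines) + "\n")
        coords = saxs.coordinates_from_pdb(str(path))
        assert coords.n_points == 8
        np.testing.assert_allclose(coords.points, fx.points, atol=1e-3)
        assert saxs.residue_distance(coords, 1, 8) == pytest.approx(45.0, abs=0.01)
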