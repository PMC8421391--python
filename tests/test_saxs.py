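"""Debye profiles, Guinier analysis, chi-square fitting, ensemble selection."""

import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingekit import (ScatteringProfile, debye_profile, ensemble_select,
                      fit_profile_to_model, guinier_fit, radius_of_gyration,
                      read_profile, write_profile)
from hingekit.saxs import SAXSError
from hingekit import synth


def brute_force_debye(coords, f, q_grid):
    """Naive O(N^2) double loop -- the oracle for the vectorized path."""
    out = np.zeros(len(q_grid))
    for iq, q in enumerate(q_grid):
        total = 0.0
        for i in range(len(coords)):
            for j in range(len(coords)):
                r = np.linalg.norm(coords[i] - coords[j])
                x = q * r
                total += f[i] * f[j] * (1.0 if x < 1e-12 else np.sin(x) / x)
        out[iq] = total
    return out


class TestDebye:
    def test_single_scatterer_flat_unity(self):
        s = synth._pseudo_chain(np.zeros((1, 3)), "A")
        prof = debye_profile(s, [0.0, 0.1, 0.5], "uniform")
        np.testing.assert_allclose(prof.I, 1.0)

    def test_two_scatterers_hand_value(self):
        # f=1 pair at 2 A, q=1: I = 2 + 2 sin(2)/2
        s = synth._pseudo_chain(np.array([[0.0, 0, 0], [2.0, 0, 0]]), "A")
        prof = debye_profile(s, [1.0], "uniform")
        assert prof.I[0] == pytest.approx(2 + 2 * np.sin(2.0) / 2.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        coords = rng.normal(size=(25, 3)) * 8
        s = synth._pseudo_chain(coords, "A")
        q = np.linspace(0.0, 0.5, 7)
        fast = debye_profile(s, q, "electron-count").I
        slow = brute_force_debye(coords, np.full(25, 6.0), q)
        np.testing.assert_allclose(fast, slow, rtol=1e-9)

    def test_rigid_motion_invariance_and_forward_value(self, hinge60):
        s = hinge60.structure
        q = np.linspace(0.01, 0.3, 10)
        base = debye_profile(s, q).I
        rot = Rotation.random(random_state=5).as_matrix()
        moved = s.transformed(rotation=rot, translation=np.array([30.0, -7.0, 2.0]))
        np.testing.assert_allclose(debye_profile(moved, q).I, base, rtol=1e-9)

    def test_i_zero_equals_total_scattering_squared(self, hinge60):
        s = hinge60.structure
        prof = debye_profile(s, [0.0])
        assert prof.I[0] == pytest.approx(float(s.atomic_number.sum()) ** 2, rel=1e-12)
        assert (debye_profile(s, np.linspace(0.0, 0.5, 20)).I > 0).all()

    def test_residue_coarse_matches_atomic_at_low_q(self, hinge60):
        # one bead per pseudo-residue == one atom here, so exact agreement
        s = hinge60.structure
        q = np.linspace(0.0, 0.2, 5)
        np.testing.assert_allclose(debye_profile(s, q, "residue-coarse").I,
                                   debye_profile(s, q, "electron-count").I,
                                   rtol=1e-9)


class TestGuinier:
    def test_ideal_guinier_curve_exact(self):
        q = np.linspace(0.001, 0.05, 60)
        I = 100.0 * np.exp(-(q ** 2) * 30.0 ** 2 / 3.0)
        fit = guinier_fit(ScatteringProfile(q, I), q_max=0.04)
        assert fit.rg == pytest.approx(30.0, abs=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)

    def test_hard_sphere_rg(self):
        # amplitude of a uniform sphere, radius R: Rg = sqrt(3/5) R
        R = 30.0
        rg_true = np.sqrt(3.0 / 5.0) * R
        q = np.linspace(1e-4, 1.3 / rg_true, 80)
        x = q * R
        amp = 3 * (np.sin(x) - x * np.cos(x)) / x ** 3
        fit = guinier_fit(ScatteringProfile(q, amp ** 2), q_max=q[-1] + 1e-9)
        assert fit.rg == pytest.approx(rg_true, rel=0.02)

    def test_consistency_with_coordinate_rg(self):
        # Guinier-route Rg vs electron-count coordinate Rg on a globule
        bundle = synth.make_hinge_structure(theta=100, seed=9, globule_radius=7,
                                            atoms_per_globule=30, arm_length=18)
        s = bundle.structure
        rg_coord = radius_of_gyration(s, "electron-count")
        q = np.linspace(1e-3, 1.3 / rg_coord, 50)
        fit = guinier_fit(debye_profile(s, q), q_max=q[-1] + 1e-9)
        assert fit.rg == pytest.approx(rg_coord, rel=0.03)

    def test_empty_window_raises(self):
        q = np.linspace(0.1, 0.5, 20)
        with pytest.raises(SAXSError):
            guinier_fit(ScatteringProfile(q, np.ones_like(q)), q_max=0.04)

    def test_nonpositive_intensity_raises(self):
        q = np.linspace(0.001, 0.05, 10)
        I = np.ones_like(q)
        I[3] = -1.0
        with pytest.raises(SAXSError):
            guinier_fit(ScatteringProfile(q, I))

    def test_guard_flag_set_for_wide_window(self):
        q = np.linspace(0.001, 0.2, 100)
        I = 10.0 * np.exp(-(q ** 2) * 40.0 ** 2 / 3.0)
        fit = guinier_fit(ScatteringProfile(q, I), q_max=0.1)
        assert fit.guard_exceeded


class TestProfileFit:
    def test_exact_proportionality(self):
        e = ScatteringProfile([0.1, 0.2, 0.3], [2.0, 4.0, 6.0], [1.0, 1.0, 1.0])
        m = ScatteringProfile([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        chi2, c = fit_profile_to_model(e, m)
        assert c == pytest.approx(2.0)
        assert chi2 == pytest.approx(0.0, abs=1e-24)

    def test_chi2_near_one_at_matched_noise(self, hinge60):
        q = np.linspace(0.01, 0.3, 200)
        noisy = synth.simulate_saxs(hinge60.structure, q, 0.02, seed=17)
        model = debye_profile(hinge60.structure, q)
        chi2, _ = fit_profile_to_model(noisy, model)
        sd = np.sqrt(2.0 / (len(q) - 1))
        assert abs(chi2 - 1.0) < 4 * sd

    def test_sigma_scaling_identity(self, hinge60):
        q = np.linspace(0.01, 0.3, 50)
        noisy = synth.simulate_saxs(hinge60.structure, q, 0.05, seed=23)
        model = debye_profile(hinge60.structure, q)
        chi2, c = fit_profile_to_model(noisy, model)
        doubled = ScatteringProfile(noisy.q, noisy.I, 2 * noisy.sigma)
        chi2b, cb = fit_profile_to_model(doubled, model)
        assert chi2b == pytest.approx(chi2 / 4.0, rel=1e-12)
        assert cb == pytest.approx(c, rel=1e-12)

    def test_model_scale_invariance(self, hinge60):
        q = np.linspace(0.01, 0.3, 50)
        noisy = synth.simulate_saxs(hinge60.structure, q, 0.05, seed=29)
        model = debye_profile(hinge60.structure, q)
        chi2, c = fit_profile_to_model(noisy, model)
        scaled = ScatteringProfile(model.q, 7.5 * model.I)
        chi2b, cb = fit_profile_to_model(noisy, scaled)
        assert chi2b == pytest.approx(chi2, rel=1e-10)
        assert cb == pytest.approx(c / 7.5, rel=1e-10)

    def test_grid_mismatch_requires_interpolation(self):
        e = ScatteringProfile([0.1, 0.2, 0.3], [2.0, 4.0, 6.0], [1.0, 1.0, 1.0])
        m = ScatteringProfile([0.05, 0.15, 0.25, 0.35], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(SAXSError):
            fit_profile_to_model(e, m)
        chi2, _ = fit_profile_to_model(e, m, interpolate=True)
        assert chi2 >= 0
        short = ScatteringProfile([0.15, 0.25], [1.0, 2.0])
        with pytest.raises(SAXSError):
            fit_profile_to_model(e, short, interpolate=True)


@pytest.fixture(scope="module")
def model_family():
    return [(f"m{th}", synth.make_hinge_structure(theta=th, seed=11).structure, th)
            for th in range(50, 81, 2)]


class TestEnsembleSelect:

    def test_noiseless_self_curve_accepts_generator(self, hinge60, model_family):
        q = np.linspace(0.01, 0.3, 60)
        exact = synth.simulate_saxs(hinge60.structure, q, 0.0)
        res = ensemble_select(exact, model_family)
        assert res.best["model"] == "m60"
        assert res.best["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert "m60" in set(res.accepted["model"])

    def test_noisy_curve_accepted_interval_contains_truth(self, hinge60, model_family):
        q = np.linspace(0.01, 0.3, 120)
        noisy = synth.simulate_saxs(hinge60.structure, q, 0.02, seed=41)
        res = ensemble_select(noisy, model_family)
        lo, hi = res.theta_range()
        assert lo <= 60 <= hi

    def test_zero_threshold_rejects_noisy_data(self, hinge60, model_family):
        q = np.linspace(0.01, 0.3, 40)
        noisy = synth.simulate_saxs(hinge60.structure, q, 0.02, seed=43)
        res = ensemble_select(noisy, model_family, threshold=0.0)
        assert len(res.accepted) == 0

    def test_empty_model_list_raises(self, hinge60):
        q = np.linspace(0.01, 0.3, 40)
        noisy = synth.simulate_saxs(hinge60.structure, q, 0.02, seed=47)
        with pytest.raises(SAXSError):
            ensemble_select(noisy, [])


class TestProfileIO:
    def test_roundtrip(self, tmp_path, hinge60):
        q = np.linspace(0.01, 0.3, 30)
        prof = synth.simulate_saxs(hinge60.structure, q, 0.02, seed=53)
        path = tmp_path / "curve.dat"
        write_profile(prof, str(path))
        back = read_profile(str(path))
        np.testing.assert_allclose(back.q, prof.q)
        np.testing.assert_allclose(back.I, prof.I)
        np.testing.assert_allclose(back.sigma, prof.sigma)

    def test_comments_and_two_column(self):
        text = "# comment line\n0.01 10.0\n0.02 9.5\n0.03 9.0\n"
        prof = read_profile(text)
        assert prof.sigma is None
        assert len(prof) == 3

    def test_invalid_profiles_rejected(self):
        with pytest.raises(SAXSError):
            ScatteringProfile([0.2, 0.1], [1.0, 1.0])
        with pytest.raises(SAXSError):
            ScatteringProfile([0.1, 0.2], [1.0, 1.0], [1.0, -1.0])
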