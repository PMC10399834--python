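"""Cartilage law: depth profiles, tension-only fibrils, energy-limiter
softening, stress-energy consistency and MD-curve fitting."""

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from kneeland import cartilage as c
from kneeland import synthetic as sy


@pytest.fixture(scope="module")
def p():
    return c.CartilageParams()


def fd_stress(F, z, p, h=1e-6):
    """Cauchy stress from central differences of the declared energy."""
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            d = np.zeros((3, 3))
            d[i, j] = h
            wp = c.total_energy(c.DeformationState(F + d), z, None, p)
            wm = c.total_energy(c.DeformationState(F - d), z, None, p)
            P[i, j] = (wp - wm) / (2 * h)
    return P @ F.T / np.linalg.det(F)


class TestDepthProfiles:
    def test_bone_junction_values(self, p):
        vt, eta, vfp, vfs = c.depth_profiles(0.0, p)
        assert np.isclose(vt, 0.59) and np.isclose(eta, 0.1)

    def test_surface_values(self, p):
        vt, eta, *_ = c.depth_profiles(1.0, p)
        assert np.isclose(vt, 0.89) and np.isclose(eta, 0.2)

    def test_primary_to_secondary_ratio_is_three(self, p):
        for z in np.linspace(0, 1, 7):
            _, _, vfp, vfs = c.depth_profiles(z, p)
            assert np.isclose(vfp / vfs, 3.0)

    def test_total_fraction_minimum_at_quadratic_vertex(self, p):
        zs = np.linspace(0, 1, 2001)
        vts = np.polyval(p.vt_poly, zs)
        assert abs(zs[np.argmin(vts)] - 1.1 / 2.8) < 1e-3

    def test_eta_increasing_with_depth_coordinate(self, p):
        zs = np.linspace(0, 1, 50)
        etas = [c.depth_profiles(z, p)[1] for z in zs]
        assert np.all(np.diff(etas) > 0)

    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            c.depth_profiles(1.2, p)


class TestFibrilLaw:
    def test_compressed_fibril_carries_no_stress(self, p):
        s = c.fibril_stress_intact(-0.05, 0.5, np.array([1, 0, 0.]), 1.0, p)
        assert np.allclose(s, 0.0)

    def test_surface_tensile_spot_value(self, p):
        s = c.fibril_stress_intact(0.1, 1.0, np.array([1, 0, 0.]), 1.0, p)
        expect = 0.2 * (8.121 * 0.1 + 5326.32 * 0.01)
        assert np.isclose(s[0, 0], expect, rtol=1e-12)

    def test_stress_tensor_is_rank_one_along_direction(self, p):
        d = np.array([1.0, 2.0, -1.0])
        d /= np.linalg.norm(d)
        s = c.fibril_stress_intact(0.08, 0.5, d, 1.1, p)
        w, v = np.linalg.eigh(s)
        assert np.sum(np.abs(w) > 1e-12) == 1
        assert np.isclose(abs(v[:, np.argmax(np.abs(w))] @ d), 1.0)

    def test_energy_derivative_matches_axial_stress(self, p):
        h = 1e-7
        for eps in (0.02, 0.05, 0.1):
            dw = (c.fibril_energy(eps + h, 0.7, p)
                  - c.fibril_energy(eps - h, 0.7, p)) / (2 * h)
            sig = c.fibril_stress_intact(eps, 0.7, np.array([1, 0, 0.]),
                                         1.0, p)[0, 0]
            assert np.isclose(dw, sig, rtol=1e-6)

    def test_energy_strictly_increasing(self, p):
        eps = np.linspace(0.0, 0.4, 60)
        w = [c.fibril_energy(e, 0.5, p) for e in eps]
        assert np.all(np.diff(w) > 0)


class TestEnergyLimiter:
    def test_softened_never_exceeds_intact(self, p):
        d = np.array([1, 0, 0.])
        for eps in np.linspace(0.01, 1.0, 40):
            si = c.fibril_stress_intact(eps, 1.0, d, 1.0, p)[0, 0]
            ss = c.softened_fibril_stress(eps, 1.0, d, 1.0, p)[0, 0]
            assert ss <= si + 1e-14

    def test_attenuation_is_inverse_e_at_limiter(self, p):
        assert np.isclose(c.attenuation(p.phi, p), np.exp(-1.0), rtol=1e-12)

    def test_huge_limiter_recovers_intact_law(self, p):
        from dataclasses import replace
        big = replace(p, phi=1e9)
        d = np.array([1, 0, 0.])
        for eps in (0.05, 0.2, 0.5):
            si = c.fibril_stress_intact(eps, 1.0, d, 1.0, big)[0, 0]
            ss = c.softened_fibril_stress(eps, 1.0, d, 1.0, big)[0, 0]
            assert np.isclose(ss, si, rtol=1e-9)

    def test_softened_axial_stress_has_interior_maximum(self, p):
        """Dense 1-D scan: the softened law peaks and then decays."""
        eps = np.linspace(1e-4, 1.0, 4000)
        d = np.array([1, 0, 0.])
        s = np.array([c.softened_fibril_stress(e, 1.0, d, 1.0, p)[0, 0]
                      for e in eps])
        k = np.argmax(s)
        assert 0 < k < len(s) - 1
        assert s[-1] < 0.5 * s[k]

    def test_softened_energy_properties(self, p):
        assert c.softened_energy(0.0, p) == 0.0
        # derivative equals the attenuation factor
        h = 1e-5
        for w in (5.0, 40.0, 80.0, 90.0):
            d = (c.softened_energy(w + h, p) - c.softened_energy(w - h, p)) / (2 * h)
            assert np.isclose(d, c.attenuation(w, p), rtol=1e-6)
        sat = (p.phi / p.m) * gamma_fn(1.0 / p.m)
        assert np.isclose(c.softened_energy(1e6, p), sat, rtol=1e-12)
        assert np.isclose(c.softened_energy_saturation(p), sat)


class TestMatrixAndAssembly:
    def test_identity_deformation_is_stress_free(self, p):
        st = c.DeformationState(np.eye(3))
        assert np.allclose(c.nonfibrillar_stress(st, 0.5, p), 0.0)
        assert np.allclose(c.total_cauchy_stress(st, 0.5, None, p), 0.0,
                           atol=1e-12)

    def test_volumetric_pressure_sign_follows_dilatation(self, p):
        for lam in (0.97, 1.03):
            st = c.DeformationState(lam * np.eye(3))
            s = c.nonfibrillar_stress(st, 0.5, p)
            assert np.sign(s[0, 0]) == np.sign(st.J - 1.0)

    def test_compressive_states_reduce_to_matrix_stress(self, p):
        """All-fibril-compression: total equals (1 - v_t) sigma_nf."""
        st = c.DeformationState(np.diag([0.95, 0.96, 0.97]))
        vt = c.depth_profiles(0.5, p)[0]
        expect = (1 - vt) * c.nonfibrillar_stress(st, 0.5, p)
        assert np.allclose(c.total_cauchy_stress(st, 0.5, None, p), expect)

    def test_uniaxial_stretch_hand_assembly(self, p):
        """Surface point stretched along one primary bundle direction:
        total = v_f * softened fibril + (1 - v_t) * matrix, by hand."""
        z = 1.0
        lam = 1.06
        F = np.diag([lam, 1.0, 1.0])
        st = c.DeformationState(F)
        vt, eta, vfp, vfs = c.depth_profiles(z, p)
        eps = np.log(lam)
        sig = c.total_cauchy_stress(st, z, None, p)
        hand = (1 - vt) * c.nonfibrillar_stress(st, z, p)
        # primary bundle 1 along e1 is stretched; bundle 2 (e2) is not;
        # secondary bundles e1 and the four diagonals see tension too
        hand = hand + vfp * c.softened_fibril_stress(
            eps, z, np.array([1, 0, 0.]), st.J, p)
        for d in c.default_bundles(z).directions[2:]:
            e, cur = c.fiber_kinematics(F, d)
            hand = hand + vfs * c.softened_fibril_stress(e, z, cur, st.J, p)
        assert np.allclose(sig, hand, rtol=1e-12, atol=1e-12)

    def test_total_stress_symmetric(self, p, rng):
        F = np.eye(3) + 0.06 * rng.standard_normal((3, 3))
        s = c.total_cauchy_stress(c.DeformationState(F), 0.3, None, p)
        assert np.allclose(s, s.T)

    @pytest.mark.parametrize("z", [0.0, 0.4, 1.0])
    def test_stress_is_energy_gradient(self, p, rng, z):
        for _ in range(8):
            F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
            sig = c.total_cauchy_stress(c.DeformationState(F), z, None, p)
            fd = fd_stress(F, z, p)
            scale = max(np.abs(sig).max(), 1e-3)
            assert np.abs(sig - fd).max() / scale < 1e-5


class TestFitting:
    def test_noise_free_recovery_within_tenth_percent(self):
        cur = sy.gen_synthetic_fibril_curve(900.0, 35000.0, phi_true=1e12,
                                            noise_sd=0.0)
        fit = c.fit_fibril_params_to_md(cur, scale=1.0)
        assert abs(fit.E0 - 900.0) / 900.0 < 1e-3
        assert abs(fit.Ee - 35000.0) / 35000.0 < 1e-3

    def test_seventy_percent_scaling_rule_is_exact(self):
        cur = sy.gen_synthetic_fibril_curve(900.0, 35000.0, phi_true=1e12)
        full = c.fit_fibril_params_to_md(cur, scale=1.0)
        scaled = c.fit_fibril_params_to_md(cur, scale=0.7)
        assert np.isclose(scaled.E0, 0.7 * full.E0, rtol=1e-12)
        assert np.isclose(scaled.Ee, 0.7 * full.Ee, rtol=1e-12)

    def test_defaults_returned_without_curve(self, p):
        fit = c.fit_fibril_params_to_md(None)
        assert fit.E0 == p.E0 and fit.Ee == p.Ee

    def test_softened_curve_recovered_with_known_limiter(self):
        cur = sy.gen_synthetic_fibril_curve(900.0, 35000.0, phi_true=30.0,
                                            m_true=12.0, max_strain=0.12)
        fit = c.fit_fibril_params_to_md(cur, scale=1.0, phi=30.0, m=12.0)
        assert abs(fit.E0 - 900.0) / 900.0 < 1e-3
        assert abs(fit.Ee - 35000.0) / 35000.0 < 1e-3

    def test_too_few_prepeak_points_rejected(self):
        from kneeland.curve import StressStrainCurve
        cur = StressStrainCurve([0.0, 0.01, 0.02], [0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            c.fit_fibril_params_to_md(cur)


class TestDamageIndicator:
    def test_zero_history_gives_zero(self, p):
        assert np.allclose(c.damage_indicator([0.0, 0.0], p), 0.0)

    def test_monotone_in_peak_strain(self, p):
        peaks = np.linspace(0.1, 0.9, 9)
        vals = [c.damage_indicator([0.0, e], p, z=1.0)[0] for e in peaks]
        assert np.all(np.diff(vals) >= 0)

    def test_zero_threshold_flags_any_resolvable_tension(self, p):
        # 0.25 log strain: indicator ~1e-10, below any practical threshold
        # yet positive, so a zero threshold flags it; zero strain never does
        assert c.damage_indicator([0.25], p, z=1.0)[0] < 1e-6
        assert c.damage_flag([0.25], p, threshold=0.0)
        assert not c.damage_flag([0.0], p, threshold=0.0)
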