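"""Ligament/tendon hyper-elastoplasticity: pre-strain conventions,
invariants, stress-energy consistency, tension switch, KKT return mapping
and aggregate calibration."""

import numpy as np
import pytest

from kneeland import ligament as lg
from kneeland.curve import StressStrainCurve


@pytest.fixture(scope="module")
def p():
    return lg.LigamentParams()


@pytest.fixture(scope="module")
def hardening():
    """Linear-hardening yield curve: y = 5 + 50 * slip (MPa)."""
    g = np.linspace(0.0, 0.5, 26)
    return StressStrainCurve(g, 5.0 + 50.0 * g)


def fd_stress(F, p, pre=None, plastic=None, h=1e-6):
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            d = np.zeros((3, 3))
            d[i, j] = h
            wp = lg.ligament_energy(F + d, plastic, pre, p)
            wm = lg.ligament_energy(F - d, plastic, pre, p)
            P[i, j] = (wp - wm) / (2 * h)
    return P @ F.T / np.linalg.det(F)


class TestPreStrain:
    def test_unit_prestrain_is_identity(self):
        assert np.allclose(lg.prestrain_gradient(1.0), np.eye(3))

    def test_isochoric_convention_preserves_volume(self):
        for a0 in (0.9, 1.02, 1.2):
            F0 = lg.prestrain_gradient(a0, convention="isochoric")
            assert np.isclose(np.linalg.det(F0), 1.0)
            assert np.isclose(F0[0, 0], a0)

    def test_printed_variant_structure(self):
        F0 = lg.prestrain_gradient(1.05, convention="printed")
        assert np.isclose(F0[0, 0], 1.05)
        assert np.isclose(F0[1, 1], 1 / 1.05)
        assert np.isclose(F0[2, 2], 1 / 1.05)

    def test_prestrain_at_identity_motion_generates_fiber_tension(self, p):
        pre = lg.PreStrain(1.05)
        sig = lg.total_stress(np.eye(3), None, pre, p)
        _, sig_f = lg.stress_parts(np.eye(3), None, pre, p)
        assert sig_f[0, 0] > 0
        # equals the response to F = F0 with no pre-strain
        F0 = lg.prestrain_gradient(1.05, p.n0)
        assert np.allclose(sig, lg.total_stress(F0, None, None, p))

    def test_composition_property_random_motion(self, p, rng):
        pre = lg.PreStrain(1.04)
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        F0 = lg.prestrain_gradient(1.04, p.n0)
        assert np.allclose(lg.total_stress(F, None, pre, p),
                           lg.total_stress(F @ F0, None, None, p))


class TestInvariants:
    def test_reference_values(self, p):
        I1e, I4e, I1ef = lg.kinematic_invariants(np.eye(3), np.eye(3), p.n0)
        assert np.allclose([I1e, I4e, I1ef], [3.0, 1.0, 3.0])

    def test_isochoric_uniaxial_elastic_stretch(self, p):
        lam = 1.13
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        _, I4e, _ = lg.kinematic_invariants(F, np.eye(3), p.n0)
        assert np.isclose(I4e, lam ** 2)

    def test_singular_plastic_gradient_rejected(self, p):
        with pytest.raises(ValueError):
            lg.kinematic_invariants(np.eye(3), np.zeros((3, 3)), p.n0)


class TestEnergy:
    def test_reference_state_energy_zero(self, p):
        assert lg.fibril_energy(3.0, 1.0, p) == pytest.approx(0.0)
        assert lg.ligament_energy(np.eye(3), None, None, p) == pytest.approx(0.0)

    def test_fibril_energy_increases_with_stretch_invariant(self, p):
        i4 = np.linspace(1.0, 1.4, 40)
        w = [lg.fibril_energy(x + 2 / np.sqrt(x), x, p) for x in i4]
        assert np.all(np.diff(w) > 0)

    def test_matrix_only_degenerates_to_neo_hookean(self):
        p = lg.LigamentParams(v_f=1e-12, v_m=1.0 - 1e-12)
        lam = 1.08
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        J = np.linalg.det(F)
        I1 = J ** (-2 / 3) * np.trace(F @ F.T)
        expect = 0.5 * p.mu_m * (I1 - 3.0)
        # tissue shear term vanishes elastically (I1e == I1), fibril group
        # is negligible at v_f ~ 0
        assert np.isclose(lg.ligament_energy(F, None, None, p), expect,
                          rtol=1e-6)

    def test_term_by_term_assembly(self, p):
        F = np.diag([1.1, 0.97, 0.95])
        J = np.linalg.det(F)
        I1 = J ** (-2 / 3) * np.trace(F @ F.T)
        I1e, I4e, I1ef = lg.kinematic_invariants(F, np.eye(3), p.n0)
        expect = (p.v_f * lg.fiber_energy(I1e, I4e, p)
                  + p.v_m * 0.5 * p.mu_m * (I1 - 3.0)
                  + 0.5 * p.mu_m * p.chi_tissue * (I1 - I1e)
                  + 0.5 * p.Ek * (J - 1.0) ** 2)
        assert np.isclose(lg.ligament_energy(F, None, None, p), expect,
                          rtol=1e-12)


class TestStress:
    def test_reference_state_stress_free(self, p):
        assert np.allclose(lg.total_stress(np.eye(3), None, None, p), 0.0,
                           atol=1e-12)

    def test_fiber_compression_switches_off_fibrillar_part(self, p):
        F = np.diag([0.93, 1.02, 1.02])
        _, sig_f = lg.stress_parts(F, None, None, p)
        assert np.allclose(sig_f, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_stress_is_energy_gradient_in_tension(self, p, seed):
        rng = np.random.default_rng(seed)
        count = 0
        while count < 8:
            F = np.diag([1.0 + 0.12 * rng.random(), 1.0, 1.0])
            F += 0.02 * rng.standard_normal((3, 3))
            if lg.total_fiber_invariant(F, p.n0) <= 1.02:
                continue
            sig = lg.total_stress(F, None, None, p)
            fd = fd_stress(F, p)
            scale = max(np.abs(sig).max(), 1e-3)
            assert np.abs(sig - fd).max() / scale < 1e-5
            count += 1

    def test_stress_energy_consistency_with_plastic_flow(self, p):
        plastic = lg.PlasticState(lg.plastic_gradient(1.03, p.n0), 0.03, True)
        F = np.diag([1.12, 0.97, 0.96])
        sig = lg.total_stress(F, plastic, None, p)
        fd = fd_stress(F, p, plastic=plastic)
        assert np.abs(sig - fd).max() / np.abs(sig).max() < 1e-5

    def test_near_incompressibility_under_default_penalty(self, p):
        for lam in np.linspace(1.0, 1.10, 6):
            _, F = lg.uniaxial_stress(lam, p, full=True)
            J = np.linalg.det(F)
            assert 0.99 <= J <= 1.01


class TestPlasticity:
    def test_elastic_trial_leaves_state_unchanged(self, hardening):
        s0 = lg.PlasticState()
        s1 = lg.plastic_update(s0, 2.0, hardening)
        assert not s1.yielding
        assert s1.accumulated_slip == 0.0
        assert np.allclose(s1.Fp, np.eye(3))

    def test_return_mapping_satisfies_kkt(self, hardening):
        E = 1000.0
        s0 = lg.PlasticState()
        trial = 20.0
        s1 = lg.plastic_update(s0, trial, hardening, tol=1e-10,
                               elastic_modulus=E)
        dg = s1.accumulated_slip
        assert dg > 0
        f_end = trial - E * dg - np.interp(dg, hardening.strain,
                                           hardening.stress)
        assert abs(f_end) <= 1e-8
        assert abs(dg * f_end) <= 1e-10
        assert np.isclose(np.linalg.det(s1.Fp), 1.0)
        # closed-form check for linear hardening: dg = f / (E + H)
        assert np.isclose(dg, (trial - 5.0) / (E + 50.0), rtol=1e-6)

    def test_load_unload_leaves_residual_strain(self, hardening):
        E = 1000.0
        path = np.concatenate([np.linspace(0, 0.04, 40),
                               np.linspace(0.04, 0.0, 40)])
        sig, eps_p = lg.uniaxial_elastoplastic_cycle(path, hardening, E)
        assert eps_p[-1] > 1e-4                 # permanent set
        assert sig[np.argmax(path)] > 5.0       # yielded
        assert abs(sig[-1] - E * (0.0 - eps_p[-1])) < 1e-9

    def test_cycle_matches_independent_return_mapping_oracle(self, hardening):
        """Compare against a directly coded 1-D linear-hardening oracle."""
        E, y0, H = 1000.0, 5.0, 50.0
        path = np.concatenate([np.linspace(0, 0.05, 50),
                               np.linspace(0.05, 0.01, 40),
                               np.linspace(0.01, 0.06, 50)])
        sig, _ = lg.uniaxial_elastoplastic_cycle(path, hardening, E)
        ep, a = 0.0, 0.0
        oracle = []
        for eps in path:
            t = E * (eps - ep)
            f = t - (y0 + H * a)
            if t > 0 and f > 0:
                dg = f / (E + H)
                ep += dg
                a += dg
            oracle.append(E * (eps - ep))
        assert np.allclose(sig, oracle, atol=1e-6)

    def test_dissipation_nonnegative_over_closed_cycle(self, hardening):
        path = np.concatenate([np.linspace(0, 0.05, 60),
                               np.linspace(0.05, 0.0, 60)])
        sig, _ = lg.uniaxial_elastoplastic_cycle(path, hardening, 1000.0)
        dissipation = np.trapezoid(sig, path)
        assert dissipation >= 0.0


class TestCalibration:
    def test_noise_free_recovery_within_one_percent(self, p):
        lams = 1.0 + np.linspace(0.005, 0.10, 12)
        truth = np.array([lg.uniaxial_stress(l, p) for l in lams])
        target = StressStrainCurve(lams - 1.0, truth)
        fitted, rms, trace = lg.calibrate_aggregate(target, p,
                                                    free=("mu_o", "a2"))
        assert abs(fitted.mu_o - p.mu_o) / p.mu_o < 0.01
        assert abs(fitted.a2 - p.a2) / p.a2 < 0.01
        assert rms < 1e-6
        assert trace[-1] <= trace[0]

    def test_empty_subset_returns_inputs(self, p):
        target = StressStrainCurve([0.01, 0.02], [1.0, 2.0])
        fitted, rms, trace = lg.calibrate_aggregate(target, p, free=())
        assert fitted is p and rms == 0.0 and trace == []

    def test_unknown_parameter_rejected(self, p):
        target = StressStrainCurve([0.01, 0.02, 0.03], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            lg.calibrate_aggregate(target, p, free=("bogus",))
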