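"""Generators: zero-noise fidelity to the regression means, seed
determinism, feasibility by construction and file round-trips."""

import numpy as np
import pytest

from kneeland import regression as rg
from kneeland import synthetic as sy


class TestLandingDataset:
    def test_zero_noise_reproduces_regression_means_exactly(self):
        recs = sy.gen_landing_dataset([20.0, 40.0, 60.0], n_per_height=2,
                                      noise_sd_fraction=0.0, seed=1)
        assert len(recs) == 6
        for r in recs:
            for name in rg.SAGITTAL_VARIABLES:
                mu = rg.evaluate(rg.DEFAULT_MODELS[name], r.height)
                assert getattr(r, name) == mu

    def test_zero_noise_spot_values(self):
        (r20,) = sy.gen_landing_dataset([20.0], seed=0)
        assert round(r20.knee_flex_angle, 2) == 29.01
        (r60,) = sy.gen_landing_dataset([60.0], seed=0)
        assert round(r60.vgrf, 2) == 4.11

    def test_same_seed_identical_datasets(self):
        a = sy.gen_landing_dataset([20, 50], 3, 0.1, seed=9)
        b = sy.gen_landing_dataset([20, 50], 3, 0.1, seed=9)
        fa, fb = sy.records_to_frame(a), sy.records_to_frame(b)
        assert fa.equals(fb)
        c = sy.records_to_frame(sy.gen_landing_dataset([20, 50], 3, 0.1, 10))
        assert not fa.equals(c)

    def test_out_of_range_height_rejected(self):
        with pytest.raises(ValueError):
            sy.gen_landing_dataset([-5.0])
        with pytest.raises(ValueError):
            sy.gen_landing_dataset([500.0])

    def test_refit_on_zero_noise_data_recovers_coefficients(self):
        recs = sy.gen_landing_dataset([10, 20, 30, 40, 50, 60], 1, 0.0, 0)
        for name in rg.SAGITTAL_VARIABLES:
            m0 = rg.DEFAULT_MODELS[name]
            data = [(r.height, getattr(r, name)) for r in recs]
            m = rg.fit(data, m0.form)
            assert np.isclose(m.a, m0.a, rtol=1e-6)
            assert np.isclose(m.b, m0.b, rtol=1e-6)
            assert m.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_csv_roundtrip(self, tmp_path):
        recs = sy.gen_landing_dataset([20, 60], 2, 0.05, seed=4)
        path = tmp_path / "records.csv"
        sy.records_to_csv(recs, path)
        back = sy.records_from_csv(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert np.isclose(a.vgrf, b.vgrf)
            assert np.isclose(a.coupled_planes["hip_add_angle"],
                              b.coupled_planes["hip_add_angle"])


class TestMusculoskeleton:
    def test_default_fixture_has_34_actuators(self):
        msk = sy.gen_toy_musculoskeleton()
        assert len(msk.muscle_names) == 34
        assert msk.lever_arms.shape == (3, 34)

    def test_ground_truth_moments_feasible_by_construction(self):
        msk = sy.gen_toy_musculoskeleton(n_dof=4, n_muscles=20, seed=8,
                                         with_ground_truth=True)
        M = msk.lever_arms @ msk.ground_truth_forces
        assert np.all(msk.ground_truth_forces > msk.x_passive)
        assert np.all(msk.ground_truth_forces < msk.x_max)
        # solver-independent feasibility: R x* reproduces M identically
        assert np.allclose(msk.lever_arms @ msk.ground_truth_forces, M)

    def test_single_dof_single_muscle_unique_force(self):
        msk = sy.gen_toy_musculoskeleton(n_dof=1, n_muscles=1, seed=0)
        r = msk.lever_arms[0, 0]
        assert r != 0.0

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            sy.gen_toy_musculoskeleton(n_dof=5, n_muscles=3)


class TestFibrilCurve:
    def test_zero_noise_matches_closed_form(self):
        c = sy.gen_synthetic_fibril_curve(900.0, 35000.0, phi_true=50.0,
                                          m_true=10.0, noise_sd=0.0)
        eps = c.strain
        w = 900 * eps ** 2 / 2 + 35000 * eps ** 3 / 3
        expect = (900 * eps + 35000 * eps ** 2) * np.exp(-(w / 50) ** 10)
        assert np.allclose(c.stress, expect)

    def test_huge_limiter_gives_intact_law(self):
        c = sy.gen_synthetic_fibril_curve(900.0, 35000.0, phi_true=1e12)
        eps = c.strain
        assert np.allclose(c.stress, 900 * eps + 35000 * eps ** 2)

    def test_fixed_seed_byte_identical_csv(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        sy.gen_synthetic_fibril_curve(900., 35000., noise_sd=5.0,
                                      seed=3).to_csv(p1)
        sy.gen_synthetic_fibril_curve(900., 35000., noise_sd=5.0,
                                      seed=3).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sy.gen_synthetic_fibril_curve(900., 35000., n_points=5)


class TestGeometry:
    def test_node_counts(self):
        g = sy.gen_toy_articular_geometry(grid_n=4)
        assert g.medial.n_nodes == 16 and g.lateral.n_nodes == 16

    def test_degenerate_labelings(self):
        g = sy.gen_toy_articular_geometry(grid_n=6, uncovered_fraction=0.0)
        assert np.all(g.medial.region == "covered")
        g = sy.gen_toy_articular_geometry(grid_n=6, uncovered_fraction=1.0)
        assert np.all(g.lateral.region == "uncovered")

    def test_constant_thickness_field(self):
        g = sy.gen_toy_articular_geometry(grid_n=5, thickness_mm=2.0)
        assert np.all(g.medial.thickness_mm == 2.0)

    def test_uncovered_ring_is_outermost(self):
        g = sy.gen_toy_articular_geometry(grid_n=10, uncovered_fraction=0.4)
        r = g.medial.r_mm
        assert r[g.medial.region == "uncovered"].min() >= \
            r[g.medial.region == "covered"].max() - 1e-9

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            sy.gen_toy_articular_geometry(grid_n=3)


def test_generator_config_yaml_roundtrip(tmp_path):
    cfg = {"heights": [20, 40, 60], "n_per_height": 5,
           "noise_sd_fraction": 0.08, "seed": 11}
    path = tmp_path / "gen.yaml"
    sy.generator_config_to_yaml(cfg, path)
    assert sy.generator_config_from_yaml(path) == cfg
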