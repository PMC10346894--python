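import dataclasses

import numpy as np
import pytest

from fcsweep.synthetic_data import (
    SimulationConfig,
    TaskDesign,
    block_membership,
    hrf_double_gamma,
    make_parcellation,
    make_task_regressor,
    perturb_subject_sigma,
    planted_sigma,
    render_cohort,
    sample_cohort_timeseries,
    sample_node_timeseries,
    write_cohort,
)
from fcsweep.types import FmriImage


class TestConfig:
    def test_defaults_match_acquisition(self):
        cfg = SimulationConfig()
        assert cfg.tr_s == 3.0
        assert cfg.voxel_size_mm == 3.0
        assert cfg.n_volumes * cfg.tr_s == 300.0  # resting run length
        assert cfg.n_subjects == 20
        assert cfg.n_nodes == 32 and cfg.n_blocks == 8

    def test_json_round_trip(self):
        cfg = SimulationConfig(task=TaskDesign(), seed=9)
        again = SimulationConfig.from_json(cfg.to_json())
        assert again == cfg

    @pytest.mark.parametrize("kwargs", [
        {"rho_within": 1.0},
        {"rho_between": -1.0},
        {"n_volumes": 1},
        {"n_subjects": 0},
        {"n_blocks": 40},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_default_node_names_are_32_grouped_labels(self):
        names = SimulationConfig().node_names()
        assert len(names) == 32
        assert names[0] == "DMN.MPFC"
        assert sum(n.startswith("SN.") for n in names) == 7


class TestParcellation:
    def test_default_config_32_disjoint_rois(self):
        atlas = make_parcellation(SimulationConfig())
        labels = atlas.labels
        assert sorted(np.unique(labels)) == list(range(33))
        # disjointness is implied by the single label volume; check sizes
        counts = np.bincount(labels.ravel())[1:]
        assert (counts == counts[0]).all()

    def test_single_roi_ball_voxel_count(self):
        # discrete ball of radius 2: integer offsets with squared norm <= 4
        expected = sum(
            1
            for a in range(-2, 3) for b in range(-2, 3) for c in range(-2, 3)
            if a * a + b * b + c * c <= 4
        )
        assert expected == 33
        cfg = SimulationConfig(grid_shape=(8, 8, 8), n_nodes=1, n_blocks=1)
        atlas = make_parcellation(cfg)
        assert (atlas.labels == 1).sum() == expected

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=3)
        a = make_parcellation(cfg)
        b = make_parcellation(cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_grid_too_small_raises(self):
        cfg = SimulationConfig(grid_shape=(8, 8, 8), n_nodes=32)
        with pytest.raises(ValueError, match="grid too small"):
            make_parcellation(cfg)


class TestPlantedSigma:
    def test_zero_rho_is_identity(self):
        np.testing.assert_array_equal(planted_sigma(6, 3, 0.0, 0.0), np.eye(6))

    def test_two_block_structure(self):
        sigma = planted_sigma(4, 2, 0.6, 0.1)
        expected = np.array([
            [1.0, 0.6, 0.1, 0.1],
            [0.6, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.6],
            [0.1, 0.1, 0.6, 1.0],
        ])
        np.testing.assert_allclose(sigma, expected)

    def test_default_32_8_positive_definite(self):
        sigma = planted_sigma(32, 8, 0.6, 0.1)
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_non_pd_combination_raises_with_eigenvalue(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            planted_sigma(8, 4, -0.9, 0.8)

    def test_block_membership_even_split(self):
        memb = block_membership(32, 8)
        assert np.bincount(memb).tolist() == [4] * 8


class TestSampleNodeTimeseries:
    def test_identity_sigma_uncorrelated(self):
        ts = sample_node_timeseries(np.eye(4), 100_000, rng=1)
        r = np.corrcoef(ts)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_planted_correlation_recovered(self):
        sigma = planted_sigma(4, 2, 0.6, 0.1)
        ts = sample_node_timeseries(sigma, 100_000, rng=2)
        r = np.corrcoef(ts)
        assert abs(r[0, 1] - 0.6) < 0.02
        assert abs(r[0, 2] - 0.1) < 0.02

    def test_degenerate_length_two(self):
        ts = sample_node_timeseries(np.eye(3), 2, rng=0)
        np.testing.assert_allclose(ts.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(ts.std(axis=1), 1.0, atol=1e-12)

    def test_non_pd_sigma_raises(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            sample_node_timeseries(bad, 10, rng=0)


class TestTaskRegressor:
    def test_all_baseline_is_zero(self):
        task = TaskDesign(baseline_s=30, n_trials=0)
        np.testing.assert_array_equal(make_task_regressor(task, 3.0, 100),
                                      np.zeros(100))

    def test_single_stimulus_peak_location(self):
        # independent oracle: convolve the boxcar with the double-gamma
        # response numerically on a fine grid
        task = TaskDesign(baseline_s=0, stim_s=6, gap_s=1, n_trials=1)
        reg = make_task_regressor(task, 3.0, 20)
        dt = 0.01
        t = np.arange(0, 60, dt)
        box = ((t >= 0) & (t < 6)).astype(float)
        hrf = hrf_double_gamma(t)
        oracle = np.convolve(box, hrf)[: t.size] * dt
        oracle_peak_s = t[np.argmax(oracle)]
        assert np.argmax(reg) == int(round(oracle_peak_s / 3.0))
        assert abs(np.argmax(reg) * 3.0 - 6.0) <= 3.0  # max near ~6 s
        assert reg[np.argmax(reg)] > 0

    def test_default_encoding_run_is_96_samples(self):
        task = TaskDesign()
        assert task.duration_s <= 288.0
        reg = make_task_regressor(task, 3.0, 96)  # 288 s at TR = 3 s
        assert reg.shape == (96,)
        assert reg.max() > 0

    def test_design_longer_than_run_raises(self):
        with pytest.raises(ValueError, match="does not fit"):
            make_task_regressor(TaskDesign(), 3.0, 10)

    def test_hrf_peaks_at_six_seconds(self):
        t = np.arange(0, 32, 0.01)
        h = hrf_double_gamma(t)
        assert abs(t[np.argmax(h)] - 6.0) < 0.05
        assert h.max() == pytest.approx(1.0)
        assert h.min() < 0  # undershoot present


class TestSubjectSigma:
    def test_tau_zero_identity(self, rng):
        sigma = planted_sigma(6, 2, 0.5, 0.1)
        np.testing.assert_array_equal(perturb_subject_sigma(sigma, 0.0, rng), sigma)

    def test_perturbed_is_valid_correlation(self, rng):
        sigma = planted_sigma(8, 2, 0.6, 0.1)
        out = perturb_subject_sigma(sigma, 0.3, rng)
        np.testing.assert_allclose(out, out.T)
        np.testing.assert_allclose(np.diag(out), 1.0)
        assert np.linalg.eigvalsh(out).min() > 0
        assert np.abs(out).max() <= 1.0 + 1e-12


class TestRenderCohort:
    def test_noiseless_voxels_equal_latent(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, noise_sd=0.0, subject_tau=0.0)
        for image, truth in render_cohort(cfg):
            labels = truth.atlas.labels
            for node in range(cfg.n_nodes):
                vox = image.data[labels == node + 1]
                np.testing.assert_allclose(
                    vox - truth.node_timeseries[node][None, :], 0.0, atol=1e-12)

    def test_default_geometry(self):
        cfg = SimulationConfig(n_subjects=2)
        cohort = render_cohort(cfg)
        assert len(cohort) == 2
        img = cohort[0][0]
        assert img.shape == (24, 24, 24, 100)
        assert img.voxel_size_mm == (3.0, 3.0, 3.0)

    def test_seed_contract_signal_noise_independent(self, tiny_config):
        # same seed, different noise scale: identical latent signals,
        # different rendered images
        a = render_cohort(dataclasses.replace(tiny_config, noise_sd=1.0))
        b = render_cohort(dataclasses.replace(tiny_config, noise_sd=2.0))
        for (img_a, gt_a), (img_b, gt_b) in zip(a, b):
            np.testing.assert_array_equal(gt_a.node_timeseries, gt_b.node_timeseries)
            assert not np.array_equal(img_a.data, img_b.data)

    def test_determinism(self, tiny_config):
        a = render_cohort(tiny_config)
        b = render_cohort(tiny_config)
        for (img_a, _), (img_b, _) in zip(a, b):
            np.testing.assert_array_equal(img_a.data, img_b.data)

    def test_subjects_have_distinct_latent_signals(self, tiny_config):
        cohort = render_cohort(tiny_config)
        assert not np.array_equal(cohort[0][1].node_timeseries,
                                  cohort[1][1].node_timeseries)

    def test_task_modulation_adds_signal(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, task=TaskDesign(
            baseline_s=10, stim_s=6, gap_s=1, n_trials=5), n_volumes=30,
            noise_sd=0.0, subject_tau=0.0)
        base = dataclasses.replace(cfg, task=None)
        img_task = render_cohort(cfg)[0][0]
        img_rest = render_cohort(base)[0][0]
        assert not np.array_equal(img_task.data, img_rest.data)

    def test_fast_timeseries_path_matches_render(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, noise_sd=0.0)
        fast = sample_cohort_timeseries(cfg)
        full = render_cohort(cfg)
        for ts, (_, truth) in zip(fast, full):
            np.testing.assert_allclose(ts, truth.node_timeseries, atol=1e-12)


class TestCohortIO:
    def test_write_and_reload(self, tiny_config, tmp_path):
        paths = write_cohort(tiny_config, tmp_path)
        assert len(paths) == tiny_config.n_subjects
        img = FmriImage.load(paths[0])
        assert img.shape == (*tiny_config.grid_shape, tiny_config.n_volumes)
        assert img.voxel_size_mm == (3.0, 3.0, 3.0)
        assert img.tr_s == pytest.approx(3.0)
        # round trip preserves the float64 data exactly
        original = render_cohort(tiny_config)[0][0]
        np.testing.assert_array_equal(img.data, original.data)
        assert (tmp_path / "atlas.nii.gz").exists()
        assert (tmp_path / "sigma_true.tsv").exists()
        assert (tmp_path / "config.json").exists()

    def test_affine_encodes_3mm_voxels(self, tiny_config, tmp_path):
        write_cohort(tiny_config, tmp_path)
        import nibabel as nib
        img = nib.load(tmp_path / "subject01.nii.gz")
        np.testing.assert_allclose(np.diag(img.affine)[:3], 3.0)
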