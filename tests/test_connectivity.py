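"""Seed correlation maps, classifier training, voxelwise classification, PIT."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import langmap as lm
from langmap import connectivity as cn
from langmap.exceptions import UndefinedCorrelationError


def _two_voxel_runs(series_a, series_b, shape=(8, 8, 8)):
    """Embed two time series at fixed voxels of an otherwise noisy run."""
    rng = np.random.default_rng(0)
    t = len(series_a)
    run = rng.standard_normal(shape + (t,))
    run[0, 0, 0] = series_a
    run[1, 1, 1] = series_b
    return [run]


class TestSeedCorrelation:
    def test_self_seed_is_clipped_finite(self, cohort, mask, atlas):
        seed = atlas[0].foci[0]
        cmap = cn.seed_correlation_map(cohort[0].rest_runs, seed, mask)
        assert cmap.values[seed] == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isfinite(cmap.values[mask]).all()

    def test_orthogonal_series_give_zero(self):
        t = np.arange(64)
        a = np.sin(2 * np.pi * t / 16)
        b = np.cos(2 * np.pi * t / 16)
        runs = _two_voxel_runs(a, b)
        full = np.ones((8, 8, 8), dtype=bool)
        cmap = cn.seed_correlation_map(runs, (0, 0, 0), full)
        assert cmap.values[1, 1, 1] == pytest.approx(0.0, abs=1e-10)

    def test_known_r_maps_through_atanh(self):
        # construct series with exact Pearson r = 0.5
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(5000)
        # orthogonalize the residual exactly
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = y - (y @ xs) * xs
        y = 0.5 * xs + np.sqrt(0.75) * (e - e.mean()) / np.linalg.norm(e - e.mean())
        runs = _two_voxel_runs(xs, y)
        full = np.ones((8, 8, 8), dtype=bool)
        cmap = cn.seed_correlation_map(runs, (0, 0, 0), full)
        assert cmap.values[1, 1, 1] == pytest.approx(0.5493, abs=1e-3)

    def test_single_voxel_seed_symmetry(self, cohort, mask, atlas):
        a = atlas[0].foci[0]
        b = atlas[1].foci[0]
        runs = cohort[0].rest_runs
        z_ab = cn.seed_correlation_map(runs, a, mask).values[b]
        z_ba = cn.seed_correlation_map(runs, b, mask).values[a]
        assert z_ab == pytest.approx(z_ba, abs=1e-10)

    def test_constant_seed_rejected(self, mask):
        run = np.ones((16, 16, 16, 20), dtype=np.float32)
        seed = tuple(np.argwhere(mask)[0])
        with pytest.raises(UndefinedCorrelationError):
            cn.seed_correlation_map([run], seed, mask)

    def test_roi_seed_uses_mean_series(self, cohort, mask, atlas):
        roi = atlas[0].weight_map >= 0.7
        cmap = cn.seed_correlation_map(cohort[0].rest_runs, roi & mask, mask)
        assert cmap.seed_descriptor == "roi"
        assert np.isfinite(cmap.values[mask]).all()


class TestTrainingSet:
    def test_row_count_is_subjects_times_seeds(self, cohort, mask):
        ts = cn.build_training_set(
            cohort, cohort[0].truth_atlas, seeds_per_network=3, mask=mask, seed=11
        )
        assert ts.inputs.shape == (5 * 21, int(mask.sum()))
        assert ts.n_seed_rois == 21

    def test_all_classes_represented(self, cohort, mask):
        ts = cn.build_training_set(
            cohort, cohort[0].truth_atlas, seeds_per_network=2, mask=mask, seed=11
        )
        assert set(ts.labels) == set(range(7))

    def test_eligibility_threshold_enforced(self, cohort, mask):
        with pytest.raises(ValueError):
            cn.build_training_set(
                cohort,
                cohort[0].truth_atlas,
                mask=mask,
                eligibility_threshold=1.5,
            )


class TestMlp:
    def test_training_reduces_loss(self, trained_model):
        assert trained_model.loss_history[-1] < trained_model.loss_history[0]

    def test_separable_toy_problem_reaches_perfect_accuracy(self):
        # two disjoint input patterns -> a one-hidden-layer net must separate
        X = np.vstack([np.tile([1.0, -1.0], (20, 5)), np.tile([-1.0, 1.0], (20, 5))])
        y = np.repeat([0, 1], 20)
        ts = cn.TrainingSet(
            inputs=X, labels=y, class_labels=("A", "B"),
            mask=np.ones((8, 8, 8), bool), n_seed_rois=2, shuffle_seed=0,
        )
        model = cn.train_mlp(ts, hidden_units=4, max_epochs=300, seed=2)
        assert (model.forward(X).argmax(1) == y).all()

    def test_same_seed_gives_identical_weights(self, cohort, mask):
        ts = cn.build_training_set(
            cohort, cohort[0].truth_atlas, seeds_per_network=2, mask=mask, seed=11
        )
        m1 = cn.train_mlp(ts, max_epochs=50, seed=5)
        m2 = cn.train_mlp(ts, max_epochs=50, seed=5)
        np.testing.assert_array_equal(m1.w_hidden, m2.w_hidden)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)

    def test_model_roundtrip(self, trained_model, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = cn.MlpModel.load(path)
        np.testing.assert_array_equal(loaded.w_hidden, trained_model.w_hidden)
        assert loaded.class_labels == trained_model.class_labels
        assert loaded.layer_sizes == trained_model.layer_sizes


class TestClassification:
    def test_likelihoods_within_unit_interval(self, subject_likelihoods):
        assert subject_likelihoods.values.min() >= 0.0
        assert subject_likelihoods.values.max() <= 1.0
        assert subject_likelihoods.values.shape[1] == 7

    def test_language_channel_recovers_planted_network(
        self, subject_likelihoods, cohort, mask
    ):
        lan_mask = cohort[0].truth_atlas[0].weight_map >= 0.5
        vol = subject_likelihoods.language_volume(uniformized=False)
        inside = np.nanmedian(vol[lan_mask & mask])
        outside = np.nanmedian(vol[~lan_mask & mask])
        assert inside > outside

    def test_out_of_mask_voxels_carry_no_value(self, subject_likelihoods, mask):
        vol = subject_likelihoods.channel_volume("LAN")
        assert np.isnan(vol[~mask]).all()

    def test_grid_mismatch_rejected(self, trained_model):
        small = np.zeros((8, 8, 8), dtype=bool)
        small[2:6, 2:6, 2:6] = True
        runs = [np.random.default_rng(0).standard_normal((8, 8, 8, 30))]
        with pytest.raises(ValueError):
            cn.classify_voxelwise(runs, trained_model, small)


class TestUniformize:
    def test_three_value_example(self):
        out = cn.uniformize(np.array([5.0, 1.0, 3.0]))
        np.testing.assert_allclose(out, [0.8333, 0.1667, 0.5], atol=1e-4)

    def test_constant_input_maps_to_half(self):
        out = cn.uniformize(np.full(10, 3.3))
        np.testing.assert_allclose(out, 0.5)

    def test_large_map_is_uniform_by_ks(self, rng):
        from scipy.stats import kstest

        vals = cn.uniformize(rng.standard_normal(10_000))
        assert kstest(vals, "uniform").statistic < 0.01

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_idempotent_and_rank_preserving(self, values):
        x = np.asarray(values)
        once = cn.uniformize(x)
        twice = cn.uniformize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)
        assert ((once > 0) & (once < 1)).all()
        i, j = np.argsort(x, kind="stable")[[0, -1]]
        assert once[i] <= once[j]


class TestSplitRestRuns:
    def test_paper_geometry_three_portions(self, cohort):
        portions = cn.split_rest_runs(cohort[0].rest_runs, 3)
        assert len(portions) == 3
        assert all(p.shape[-1] == 106 for p in portions)  # floor(320/3)

    def test_portions_are_contiguous_and_disjoint(self, cohort):
        runs = cohort[0].rest_runs
        portions = cn.split_rest_runs(runs, 3)
        full = np.concatenate(runs, axis=-1)
        for i, p in enumerate(portions):
            np.testing.assert_array_equal(p, full[..., i * 106 : (i + 1) * 106])

    def test_single_portion_is_identity(self, cohort):
        runs = cohort[0].rest_runs
        (portion,) = cn.split_rest_runs(runs, 1)
        np.testing.assert_array_equal(portion, np.concatenate(runs, axis=-1))

    def test_invalid_portion_count(self, cohort):
        with pytest.raises(ValueError):
            cn.split_rest_runs(cohort[0].rest_runs, 0)
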