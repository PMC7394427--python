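"""Synthetic cohort generator: atlas geometry, run statistics, determinism."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import pearsonr

import langmap as lm
from langmap.exceptions import DegenerateRoiError
from langmap.simulate import (
    TASK_REGIONS,
    draw_subject_spec,
    simulate_rest_run,
    simulate_task_run,
)


def _spec(n_networks=7, noise_sd=0.8, seed=99, task=(1.0, 0.0, 1.0, 1.0)):
    return lm.SubjectSpec(
        subject_id="T",
        network_amplitudes=np.ones(n_networks),
        task_amplitudes=dict(zip(TASK_REGIONS, task)),
        noise_sd=noise_sd,
        rng_seed=seed,
    )


class TestAtlas:
    def test_peak_weight_is_one_at_each_focus(self, atlas):
        for net in atlas:
            for focus in net.foci:
                assert net.weight_map[focus] == 1.0
            assert net.weight_map.min() >= 0.0 and net.weight_map.max() <= 1.0

    def test_fixed_seed_is_bitwise_reproducible(self, grid, atlas):
        again = lm.make_network_atlas(grid, 7, seed=1)
        for a, b in zip(atlas, again):
            assert a.label == b.label and a.foci == b.foci
            np.testing.assert_array_equal(a.weight_map, b.weight_map)

    def test_language_map_has_two_left_components(self, grid, atlas):
        # independent connected-component labeling of the thresholded map
        lan = atlas[0]
        labeled, n = ndimage.label(lan.weight_map >= 0.5)
        assert n == 2
        left = grid.left_mask()
        for comp in range(1, n + 1):
            assert left[labeled == comp].all()

    def test_language_network_is_left_dominant(self, atlas):
        assert atlas[0].lateralization > 0.6

    def test_rejects_fewer_than_two_networks(self, grid):
        with pytest.raises(ValueError):
            lm.make_network_atlas(grid, 1, seed=0)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            lm.GridSpec(shape=(6, 16, 16))
        with pytest.raises(ValueError):
            lm.GridSpec(voxel_size_mm=0)


class TestRestRun:
    def test_default_frame_count(self, atlas):
        run = simulate_rest_run(atlas, _spec())
        assert run.shape[-1] == 160

    def test_shared_network_signal_correlates_perfectly_without_noise(self, grid):
        atlas = lm.make_network_atlas(grid, 2, seed=4)
        net = atlas[0]
        # force two voxels fully into network 0 and silence network 1
        spec = _spec(n_networks=2, noise_sd=0.0)
        spec.network_amplitudes = np.array([1.0, 0.0])
        run = simulate_rest_run(atlas, spec)
        v1, v2 = net.foci[0], net.foci[1]
        r = pearsonr(run[v1], run[v2]).statistic
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_distinct_networks_are_uncorrelated_at_long_runs(self, grid):
        atlas = lm.make_network_atlas(grid, 3, seed=4)
        spec = _spec(n_networks=3, noise_sd=0.0)
        acq = lm.AcquisitionParams(rest_frames_per_run=10_000)
        run = simulate_rest_run(atlas, spec, acq)
        a = atlas[1].foci[0]
        b = atlas[2].foci[0]
        # both voxels sit on single-network peaks; sampling error at 10^4
        # frames (effective n reduced ~5x by temporal smoothing) is ~0.02
        assert abs(pearsonr(run[a], run[b]).statistic) < 0.05

    def test_within_network_exceeds_between_network_correlation(self, grid):
        atlas = lm.make_network_atlas(grid, 3, seed=4)
        spec = _spec(n_networks=3, noise_sd=0.0)
        acq = lm.AcquisitionParams(rest_frames_per_run=1000)
        run = simulate_rest_run(atlas, spec, acq)
        lan = atlas[0]
        within = pearsonr(run[lan.foci[0]], run[lan.foci[1]]).statistic
        between = pearsonr(run[lan.foci[0]], run[atlas[1].foci[0]]).statistic
        assert within - between > 0.3


class TestTaskRun:
    def test_default_frame_count_is_five_offon_cycles(self, atlas):
        run = simulate_task_run(atlas, _spec())
        assert run.shape[-1] == 100
        assert lm.BlockDesign().total_frames == 100

    def test_zero_amplitudes_reduce_to_rest_model(self, atlas):
        spec = _spec(task=(0.0, 0.0, 0.0, 0.0))
        acq = lm.AcquisitionParams(task_frames=100)
        rng_a = np.random.default_rng(7)
        rng_b = np.random.default_rng(7)
        task = simulate_task_run(atlas, spec, acq, rng=rng_a)
        rest = simulate_rest_run(
            atlas, spec, lm.AcquisitionParams(rest_frames_per_run=100), rng=rng_b
        )
        np.testing.assert_array_equal(task, rest)

    def test_offon_block_means_match_when_amplitudes_zero(self, atlas):
        spec = _spec(task=(0.0, 0.0, 0.0, 0.0), noise_sd=0.5)
        design = lm.BlockDesign(block_len_frames=10, n_cycles=500)
        acq = lm.AcquisitionParams(task_frames=design.total_frames)
        run = simulate_task_run(atlas, spec, acq, design)
        box = design.boxcar().astype(bool)
        voxel = run[atlas[0].foci[0]]
        # difference of two means of ~5000 weakly dependent samples
        assert abs(voxel[box].mean() - voxel[~box].mean()) < 0.2

    def test_frame_mismatch_rejected(self, atlas):
        with pytest.raises(ValueError):
            simulate_task_run(
                atlas, _spec(), lm.AcquisitionParams(task_frames=99), lm.BlockDesign()
            )


class TestRoiSet:
    def test_masks_disjoint_and_left_confined(self, roi_set, grid):
        b, w, n = roi_set.broca_mask, roi_set.wernicke_mask, roi_set.nonlanguage_mask
        assert not (b & w).any() and not (b & n).any() and not (w & n).any()
        left = grid.left_mask()
        for m in (b, w, n):
            assert (m <= left).all()

    def test_each_focus_inside_its_own_mask(self, atlas, roi_set):
        assert roi_set.broca_mask[atlas[0].foci[0]]
        assert roi_set.wernicke_mask[atlas[0].foci[1]]

    def test_roi_volumes_comparable(self, roi_set):
        ratio = roi_set.broca_mask.sum() / roi_set.wernicke_mask.sum()
        assert 0.5 <= ratio <= 2.0

    def test_too_high_threshold_degenerates(self, atlas, grid):
        with pytest.raises(DegenerateRoiError):
            lm.make_roi_set(atlas[0], grid, weight_threshold=1.1)


class TestCohort:
    def test_requested_size_and_determinism(self, cohort, grid):
        assert len(cohort) == 5
        again = lm.make_cohort(5, master_seed=3, grid=grid)
        for a, b in zip(cohort, again):
            np.testing.assert_array_equal(a.task_run, b.task_run)
            for ra, rb in zip(a.rest_runs, b.rest_runs):
                np.testing.assert_array_equal(ra, rb)

    def test_rejects_single_subject(self, grid):
        with pytest.raises(ValueError):
            lm.make_cohort(1, master_seed=0, grid=grid)

    def test_run_geometry_matches_acquisition(self, cohort, grid):
        acq = lm.AcquisitionParams()
        subject = cohort[0]
        assert len(subject.rest_runs) == acq.rest_runs
        for run in subject.rest_runs:
            assert run.shape == grid.shape + (acq.rest_frames_per_run,)
        assert subject.task_run.shape == grid.shape + (acq.task_frames,)

    def test_amplitude_population_statistics(self):
        pop = lm.PopulationParams()
        draws = np.array(
            [
                draw_subject_spec(i, 7, pop, master_seed=42).task_amplitudes[
                    "language_expressive"
                ]
                for i in range(200)
            ]
        )
        assert abs(draws.std(ddof=1) - 0.3) / 0.3 < 0.10
        assert abs(draws.mean() - 1.0) < 0.08
        assert (draws >= 0).all()

    def test_focus_jitter_moves_foci_but_preserves_determinism(self, grid):
        pop = lm.PopulationParams(focus_jitter_vox=1.0)
        c1 = lm.make_cohort(2, pop, master_seed=9, grid=grid)
        c2 = lm.make_cohort(2, pop, master_seed=9, grid=grid)
        assert c1[0].truth_atlas[0].foci == c2[0].truth_atlas[0].foci
        # jittered subject atlases differ between subjects
        assert (
            c1[0].truth_atlas[0].foci != c1[1].truth_atlas[0].foci
            or c1[0].truth_atlas[1].foci != c1[1].truth_atlas[1].foci
        )
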