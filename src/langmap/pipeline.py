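"""End-to-end orchestration of the rest-vs-task language mapping comparison.

``run_pipeline`` ties the stages together: simulate a cohort, train the
network classifier on seed-correlation maps, classify each subject's rest
data (split into acquisition-time-matched portions), fit the task GLM and
smooth/mask the activation maps, distribution-match the group maps, build
SNR (consistency) maps per portion plus their average, a concordance map,
and ROC/AUC with paired DeLong comparisons against the planted language
ROIs.  Everything is a pure function of the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import connectivity, glm, group, roc
from ._seeds import stage_seed
from .simulate import (
    AcquisitionParams,
    BlockDesign,
    GridSpec,
    PopulationParams,
    make_cohort,
)

log = logging.getLogger("langmap")


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_subjects: int = 10
    n_networks: int = 7
    tr_s: float = 2.2
    rest_frames_per_run: int = 160
    rest_runs: int = 2
    task_frames: int = 100
    block_len_frames: int = 10
    n_cycles: int = 5
    network_amp_mean: float = 1.0
    network_amp_sd: float = 0.3
    task_amp_mean: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 1.0)
    task_amp_sd: tuple[float, float, float, float] = (0.3, 0.0, 0.3, 0.3)
    noise_sd: float = 0.8
    focus_jitter_vox: float = 0.0
    seeds_per_network: int = 3
    hidden_units: int = 20
    max_epochs: int = 500
    smoothing_fwhm_mm: float = 6.0
    n_portions: int = 3
    roc_mode: str = "voxel-count"
    concordance_threshold: float = 0.7
    master_seed: int = 0

    def grid(self) -> GridSpec:
        return GridSpec(shape=tuple(self.grid_shape), voxel_size_mm=self.voxel_size_mm)

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(
            tr_s=self.tr_s,
            rest_frames_per_run=self.rest_frames_per_run,
            rest_runs=self.rest_runs,
            task_frames=self.task_frames,
        )

    def block_design(self) -> BlockDesign:
        return BlockDesign(block_len_frames=self.block_len_frames, n_cycles=self.n_cycles)

    def population(self) -> PopulationParams:
        return PopulationParams(
            network_amp_mean=self.network_amp_mean,
            network_amp_sd=self.network_amp_sd,
            task_amp_mean=tuple(self.task_amp_mean),
            task_amp_sd=tuple(self.task_amp_sd),
            noise_sd=self.noise_sd,
            focus_jitter_vox=self.focus_jitter_vox,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All group-level outputs of one run plus provenance."""

    config: RunConfig
    rs_group_map: np.ndarray  # matched group-mean language-likelihood map
    task_group_map: np.ndarray  # matched group-mean task activation map
    concordance: np.ndarray
    rs_snr_portions: list[group.SnrMap]
    rs_snr_average: group.SnrMap
    task_snr: group.SnrMap
    roc_results: dict  # per-ROI AUC / DeLong numbers
    snr_summary: dict  # per-ROI mean SNR per modality
    provenance: dict

    def to_json_dict(self) -> dict:
        """The result numbers (not the maps) as a JSON-serializable dict."""
        return dict(
            config=asdict(self.config),
            provenance=self.provenance,
            roc=self.roc_results,
            snr=self.snr_summary,
        )


def _roi_mean(map_values: np.ndarray, mask: np.ndarray) -> float:
    vals = map_values[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full rest-vs-task comparison for one configuration."""
    grid = config.grid()
    acq = config.acquisition()
    design = config.block_design()
    mask = grid.brain_mask()

    log.info("simulate: n=%d grid=%s seed=%d", config.n_subjects,
             config.grid_shape, config.master_seed)
    cohort = make_cohort(
        n_subjects=config.n_subjects,
        population_params=config.population(),
        master_seed=config.master_seed,
        grid=grid,
        acq=acq,
        design=design,
        n_networks=config.n_networks,
    )
    atlas = cohort[0].truth_atlas
    roi_set = cohort[0].roi_set

    log.info("train-mlp: %d seeds/network, %d hidden units",
             config.seeds_per_network, config.hidden_units)
    ts = connectivity.build_training_set(
        cohort,
        atlas,
        seeds_per_network=config.seeds_per_network,
        mask=mask,
        seed=stage_seed(config.master_seed, "training-set"),
    )
    model = connectivity.train_mlp(
        ts,
        hidden_units=config.hidden_units,
        max_epochs=config.max_epochs,
        seed=stage_seed(config.master_seed, "mlp-init"),
    )

    # resting-state: classify per acquisition-time-matched portion
    n_port = config.n_portions
    portion_maps: list[list[np.ndarray]] = [[] for _ in range(n_port)]
    subject_rs_maps = []
    for subject in cohort:
        portions = connectivity.split_rest_runs(subject.rest_runs, n_port)
        per_subject = []
        for p, portion in enumerate(portions):
            lik = connectivity.classify_voxelwise([portion], model, mask)
            lan_map = lik.language_volume(uniformized=True)
            portion_maps[p].append(lan_map)
            per_subject.append(lan_map)
        mean_map = np.full(mask.shape, np.nan)
        mean_map[mask] = np.stack([m[mask] for m in per_subject]).mean(axis=0)
        subject_rs_maps.append(mean_map)

    # task: GLM -> percent map -> smooth -> mask; uniformize per subject
    X = glm.build_design(design, acq)
    subject_task_maps = []
    for subject in cohort:
        act = glm.fit_glm(subject.task_run, X, mask)
        smoothed = glm.smooth_gaussian(act.values, config.smoothing_fwhm_mm, grid, mask)
        subject_task_maps.append(glm.mask_brain(smoothed, mask))
    task_uniform = [connectivity.uniformize(m, mask) for m in subject_task_maps]

    # group maps, matched to a common uniform distribution
    rs_group = group.group_mean(group.stack_maps(subject_rs_maps, mask, "rs"))
    task_group = group.group_mean(group.stack_maps(subject_task_maps, mask, "task"))
    matched = group.match_distributions(rs_group, task_group, mask)
    concord = group.concordance_map(
        matched.map_a, matched.map_b, threshold=config.concordance_threshold
    )

    # SNR (consistency) maps on per-subject distribution-matched data
    rs_snr_portions = [
        group.snr_map(group.stack_maps(maps, mask, f"rs-portion-{p + 1}"))
        for p, maps in enumerate(portion_maps)
    ]
    rs_snr_avg = group.average_snr_maps(rs_snr_portions)
    task_snr = group.snr_map(group.stack_maps(task_uniform, mask, "task"))

    # ROC / DeLong against the a priori ROIs
    roc_results = {"mode": config.roc_mode}
    for roi_name, roi_mask in (
        ("broca", roi_set.broca_mask),
        ("wernicke", roi_set.wernicke_mask),
    ):
        ls = roc.make_labeled_scores(
            matched.map_a, matched.map_b, roi_mask, roi_set.nonlanguage_mask
        )
        auc_rs = roc.auc_from_scores(ls.score_a, ls.labels, mode=config.roc_mode)
        auc_task = roc.auc_from_scores(ls.score_b, ls.labels, mode=config.roc_mode)
        dl = roc.delong_test(ls)
        roc_results[roi_name] = dict(
            auc_rs=auc_rs.auc,
            auc_task=auc_task.auc,
            n_pos=auc_rs.n_pos,
            n_neg=auc_rs.n_neg,
            delong_z=dl.z,
            delong_p=dl.p,
            delong_var_diff=dl.var_diff,
        )

    snr_summary = {}
    for roi_name, roi_mask in (
        ("broca", roi_set.broca_mask),
        ("wernicke", roi_set.wernicke_mask),
    ):
        snr_summary[roi_name] = dict(
            rs=_roi_mean(rs_snr_avg.values, roi_mask),
            task=_roi_mean(task_snr.values, roi_mask),
        )

    provenance = dict(
        config_hash=config.config_hash(),
        master_seed=config.master_seed,
        mlp_training_seed=model.training_seed,
        n_seed_rois=ts.n_seed_rois,
        final_training_loss=float(model.loss_history[-1]),
    )
    return PipelineResult(
        config=config,
        rs_group_map=matched.map_a,
        task_group_map=matched.map_b,
        concordance=concord,
        rs_snr_portions=rs_snr_portions,
        rs_snr_average=rs_snr_avg,
        task_snr=task_snr,
        roc_results=roc_results,
        snr_summary=snr_summary,
        provenance=provenance,
    )


def write_result(result: PipelineResult, out_dir) -> Path:
    """Write result maps (NIfTI), numbers (JSON) and the config echo."""
    from .nifti_io import write_json, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.config.grid()
    write_volume(result.rs_group_map, grid, out / "rs_group_map.nii.gz")
    write_volume(result.task_group_map, grid, out / "task_group_map.nii.gz")
    write_volume(result.concordance, grid, out / "concordance.nii.gz")
    for p, snr in enumerate(result.rs_snr_portions, start=1):
        write_volume(snr.values, grid, out / f"rs_snr_portion{p}.nii.gz")
    if result.config.n_portions > 1:
        write_volume(result.rs_snr_average.values, grid, out / "rs_snr_average.nii.gz")
    write_volume(result.task_snr.values, grid, out / "task_snr.nii.gz")
    write_volume(
        result.task_snr.low_variance_mask, grid, out / "task_snr_lowvar.nii.gz"
    )
    write_json(result.to_json_dict(), out / "result.json")
    return out
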