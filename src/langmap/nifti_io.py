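"""NIfTI-1 volume I/O and per-subject directory layout.

Volumes are stored as ``.nii.gz`` (4-D runs, 3-D maps, uint8 masks) with a
diagonal affine carrying the voxel size; geometry beyond voxel size is not
used by the pipeline.  Each simulated subject directory holds its runs,
mask, ROI masks, and a JSON sidecar with the subject's generative
parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import FormatError
from .simulate import GridSpec, RoiSet, SyntheticSubject


def write_volume(array: np.ndarray, grid: GridSpec, path) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with the grid's voxel size."""
    affine = np.diag([grid.voxel_size_mm] * 3 + [1.0])
    data = array.astype(np.uint8) if array.dtype == bool else array
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path):
    """Read a NIfTI file; returns ``(array, grid)``.

    Raises :class:`FormatError` on non-NIfTI or truncated input.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    voxel = float(img.header.get_zooms()[0])
    grid = GridSpec(shape=tuple(int(s) for s in data.shape[:3]), voxel_size_mm=voxel)
    return data, grid


def write_subject(subject: SyntheticSubject, grid: GridSpec, out_dir) -> Path:
    """Write one subject's runs, masks and parameter sidecar to a directory."""
    out = Path(out_dir) / subject.spec.subject_id
    out.mkdir(parents=True, exist_ok=True)
    for i, run in enumerate(subject.rest_runs, start=1):
        write_volume(run, grid, out / f"rest_run{i}.nii.gz")
    write_volume(subject.task_run, grid, out / "task_run.nii.gz")
    write_volume(grid.brain_mask(), grid, out / "brain_mask.nii.gz")
    roi = subject.roi_set
    write_volume(roi.broca_mask, grid, out / "roi_broca.nii.gz")
    write_volume(roi.wernicke_mask, grid, out / "roi_wernicke.nii.gz")
    write_volume(roi.nonlanguage_mask, grid, out / "roi_nonlanguage.nii.gz")
    lan = subject.truth_atlas[0]
    write_volume(lan.weight_map, grid, out / "truth_language_weight.nii.gz")
    (out / "subject.json").write_text(subject.spec.to_json())
    return out


def read_subject_runs(subject_dir) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, RoiSet, GridSpec]:
    """Load a subject directory written by :func:`write_subject`.

    Returns ``(rest_runs, task_run, brain_mask, roi_set, grid)``.
    """
    d = Path(subject_dir)
    rest = []
    for i in range(1, 100):
        p = d / f"rest_run{i}.nii.gz"
        if not p.exists():
            break
        rest.append(read_volume(p)[0])
    if not rest:
        raise FormatError(f"no rest runs found in {d}")
    task, grid = read_volume(d / "task_run.nii.gz")
    mask = read_volume(d / "brain_mask.nii.gz")[0].astype(bool)
    roi = RoiSet(
        broca_mask=read_volume(d / "roi_broca.nii.gz")[0].astype(bool),
        wernicke_mask=read_volume(d / "roi_wernicke.nii.gz")[0].astype(bool),
        nonlanguage_mask=read_volume(d / "roi_nonlanguage.nii.gz")[0].astype(bool),
    )
    return rest, task, mask, roi, grid


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
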