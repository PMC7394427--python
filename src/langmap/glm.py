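"""Block-design GLM analysis of task runs.

Produces percent-signal-change activation maps: each voxel's time series is
regressed on a task regressor (block boxcar convolved with a canonical
double-gamma hemodynamic response function, scaled to unit peak), a
constant, and a linear drift.  Because the task regressor has unit peak,
the task coefficient is directly the peak evoked response in raw units and
``percent = 100 * beta_task / beta_constant``.

Activation maps are smoothed at the map level with a mask-normalized
isotropic Gaussian (6 mm FWHM by default) and masked to the brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

from .simulate import AcquisitionParams, BlockDesign, GridSpec


@dataclass
class HrfKernel:
    """Double-gamma hemodynamic impulse response sampled at TR resolution."""

    samples: np.ndarray
    tr_s: float
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_undershoot_ratio: float = 6.0


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> HrfKernel:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6).

    The kernel is zero at t = 0, has a positive main lobe, and is normalized
    to unit maximum (the design column is re-scaled to unit peak after
    convolution anyway).
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    peak_delay, undershoot_delay, ratio = 6.0, 16.0, 6.0
    if duration_s < peak_delay:
        raise ValueError("HRF duration must cover the response peak")
    t = np.arange(0.0, duration_s + 0.5 * tr_s, tr_s)
    # unit-scale gamma densities with modes at the stated delays
    h = gamma_dist.pdf(t, peak_delay + 1.0) - gamma_dist.pdf(t, undershoot_delay + 1.0) / ratio
    h = h / h.max()
    return HrfKernel(samples=h, tr_s=tr_s,
                     peak_delay_s=peak_delay,
                     undershoot_delay_s=undershoot_delay,
                     peak_undershoot_ratio=ratio)


def task_regressor(design: BlockDesign, hrf: HrfKernel) -> np.ndarray:
    """Boxcar convolved with the HRF, truncated to run length, unit peak."""
    box = design.boxcar()
    x = np.convolve(box, hrf.samples)[: design.total_frames]
    peak = np.abs(x).max()
    if peak == 0:
        raise ValueError("task regressor is identically zero")
    return x / peak


@dataclass
class DesignMatrix:
    """GLM design: task regressor, constant, centred linear drift."""

    matrix: np.ndarray  # (frames, 3)
    names: tuple[str, ...] = ("task", "constant", "drift")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def build_design(
    design: BlockDesign,
    acq: AcquisitionParams = AcquisitionParams(),
    hrf: HrfKernel | None = None,
) -> DesignMatrix:
    """Assemble the (frames × 3) design matrix for the block task."""
    if design.total_frames != acq.task_frames:
        raise ValueError(
            f"design frames ({design.total_frames}) != acquisition task frames "
            f"({acq.task_frames})"
        )
    if hrf is None:
        hrf = canonical_hrf(acq.tr_s)
    n = design.total_frames
    x_task = task_regressor(design, hrf)
    const = np.ones(n)
    drift = np.linspace(-1.0, 1.0, n)
    X = np.column_stack([x_task, const, drift])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(matrix=X)


@dataclass
class ActivationMap:
    """Per-voxel percent BOLD modulation and t statistics from the task GLM.

    ``flagged`` marks voxels whose baseline coefficient was non-positive,
    where percent signal change is undefined; their values are NaN.
    """

    values: np.ndarray  # percent signal change, NaN outside mask / where flagged
    tstats: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray = field(default=None)


def fit_glm(run: np.ndarray, X: DesignMatrix, mask: np.ndarray) -> ActivationMap:
    """Voxelwise OLS fit of the task design to a 4-D run.

    Returns percent signal change ``100 * beta_task / beta_constant`` and the
    task-coefficient t statistic (residual df = frames − 3).
    """
    if run.shape[-1] != X.n_frames:
        raise ValueError("run frame count does not match design matrix rows")
    if run.shape[:3] != mask.shape:
        raise ValueError("run grid does not match mask")
    A = X.matrix
    n, p = A.shape
    Y = run[mask].astype(np.float64).T  # (frames, voxels)
    beta, _, _, _ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(A.T @ A)
    se_task = np.sqrt(sigma2 * xtx_inv[0, 0])
    b_task, b_const = beta[0], beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_task > 0, b_task / se_task, np.inf * np.sign(b_task))
        pct = np.where(b_const > 0, 100.0 * b_task / b_const, np.nan)

    values = np.full(mask.shape, np.nan)
    tstats = np.full(mask.shape, np.nan)
    flagged = np.zeros(mask.shape, dtype=bool)
    values[mask] = pct
    tstats[mask] = t
    flagged[mask] = b_const <= 0
    return ActivationMap(values=values, tstats=tstats, mask=mask, flagged=flagged)


def smooth_gaussian(
    map_values: np.ndarray,
    fwhm_mm: float,
    grid: GridSpec,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-normalized isotropic Gaussian smoothing of a 3-D map.

    ``sigma_vox = fwhm / (2 sqrt(2 ln 2)) / voxel_size``.  Smoothing is
    renormalized by the smoothed mask so values near the brain edge are
    unbiased; out-of-mask voxels are NaN in the output.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if mask is None:
        mask = np.ones(map_values.shape, dtype=bool)
    if fwhm_mm == 0:
        out = np.full(map_values.shape, np.nan)
        out[mask] = map_values[mask]
        return out
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.voxel_size_mm
    filled = np.where(mask, map_values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox)
    den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    out = np.full(map_values.shape, np.nan)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def mask_brain(map_values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Set out-of-mask voxels to NaN (no value)."""
    if map_values.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    out = np.full(map_values.shape, np.nan)
    out[mask] = map_values[mask]
    return out
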