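"""Group-level statistics: distribution matching, SNR maps, concordance.

The two modalities produce voxelwise measures on incomparable scales
(percent BOLD modulation vs. network likelihood), so before any joint
analysis both are mapped to a common uniform [0, 1] distribution by the
probability integral transform (rank uniformization over the brain mask).

Inter-subject consistency is summarized as an SNR map — the voxelwise group
mean divided by the across-subject standard deviation — and agreement
between modalities as a concordance map, the voxelwise product of the two
matched group-mean maps thresholded at 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import uniformize


@dataclass
class GroupStack:
    """Per-subject 3-D maps of one modality on a common grid."""

    data: np.ndarray  # (n_subjects, x, y, z)
    mask: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("stack must be (subjects, x, y, z)")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("stack grid does not match mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def stack_maps(maps: list[np.ndarray], mask: np.ndarray, modality: str = "") -> GroupStack:
    return GroupStack(data=np.stack(maps, axis=0), mask=mask, modality=modality)


def group_mean(stack: GroupStack) -> np.ndarray:
    """Voxelwise arithmetic mean across subjects (NaN outside mask)."""
    out = np.full(stack.mask.shape, np.nan)
    out[stack.mask] = stack.data[:, stack.mask].mean(axis=0)
    return out


def group_sd(stack: GroupStack) -> np.ndarray:
    """Voxelwise across-subject standard deviation (n − 1 denominator)."""
    if stack.n_subjects < 2:
        raise ValueError("group sd needs at least 2 subjects")
    out = np.full(stack.mask.shape, np.nan)
    out[stack.mask] = stack.data[:, stack.mask].std(axis=0, ddof=1)
    return out


@dataclass
class MatchedMaps:
    """Two maps after probability-integral-transform matching to U[0, 1]."""

    map_a: np.ndarray
    map_b: np.ndarray
    mask: np.ndarray


def match_distributions(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray
) -> MatchedMaps:
    """Rank-uniformize each map over the mask so both share U[0, 1].

    The transform is monotone, so each map's rank order — and therefore any
    rank-based statistic such as ROC AUC — is unchanged; the two outputs'
    sorted in-mask values coincide (up to tie handling).
    """
    return MatchedMaps(
        map_a=uniformize(map_a, mask), map_b=uniformize(map_b, mask), mask=mask
    )


@dataclass
class SnrMap:
    """Voxelwise group mean over across-subject sd, with degenerate voxels
    (sd < epsilon) flagged and set to 0."""

    values: np.ndarray
    low_variance_mask: np.ndarray
    mask: np.ndarray


def snr_map(stack: GroupStack, epsilon: float = 1e-8) -> SnrMap:
    """Consistency (SNR) map: mean / sd across subjects.

    High values mark voxels where the response is consistent over subjects.
    Input maps are expected to be per-subject distribution-matched
    (uniformized), so both modalities' SNR maps are computed identically.
    """
    mean = group_mean(stack)
    sd = group_sd(stack)
    low = np.zeros(stack.mask.shape, dtype=bool)
    low[stack.mask] = sd[stack.mask] < epsilon
    values = np.full(stack.mask.shape, np.nan)
    ok = stack.mask & ~low
    values[ok] = mean[ok] / sd[ok]
    values[low] = 0.0
    return SnrMap(values=values, low_variance_mask=low, mask=stack.mask)


def average_snr_maps(maps: list[SnrMap]) -> SnrMap:
    """Voxelwise mean of unflagged SNR values over data portions.

    A voxel flagged (degenerate sd) in every input stays flagged with value
    0; otherwise the mean is taken over the unflagged inputs only.
    """
    if not maps:
        raise ValueError("need at least one SNR map")
    mask = maps[0].mask
    if any(m.mask.shape != mask.shape or not np.array_equal(m.mask, mask) for m in maps):
        raise ValueError("SNR maps are not on a common grid/mask")
    vals = np.stack([m.values for m in maps])
    ok = np.stack([~m.low_variance_mask & m.mask for m in maps])
    count = ok.sum(axis=0)
    total = np.where(ok, vals, 0.0).sum(axis=0)
    out = np.full(mask.shape, np.nan)
    all_flagged = mask & (count == 0)
    some = mask & (count > 0)
    out[some] = total[some] / count[some]
    out[all_flagged] = 0.0
    return SnrMap(values=out, low_variance_mask=all_flagged, mask=mask)


def concordance_map(
    mean_a: np.ndarray, mean_b: np.ndarray, threshold: float = 0.7
) -> np.ndarray:
    """Voxelwise product of two matched [0, 1] maps, sub-threshold set to 0.

    Symmetric in its arguments; highlights voxels high in both modalities.
    """
    prod = mean_a * mean_b
    return np.where(prod >= threshold, prod, np.where(np.isnan(prod), np.nan, 0.0))
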