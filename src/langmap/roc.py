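"""ROC evaluation of maps against a priori ROIs and the paired DeLong test.

Positives are the voxels of a target language ROI (Broca-like or
Wernicke-like); negatives are the left-hemisphere non-language background.
Sensitivity/specificity curves are parametric in the map threshold; the
area under the curve is computed by trapezoid integration, which in
voxel-count mode equals the Mann–Whitney statistic with ½ credit for ties.
Two modalities scored on the same voxels are compared with the fast
(midrank, O(n log n)) implementation of DeLong's paired AUC test.

Two sensitivity/specificity conventions are provided: ``voxel-count``
(each voxel counts once — the default) and ``magnitude-weighted`` (each
voxel contributes its response magnitude, i.e. above-threshold magnitude
summed over the ROI relative to the ROI total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .exceptions import NumericalDegeneracyError

MODES = ("voxel-count", "magnitude-weighted")


@dataclass
class LabeledScores:
    """Paired per-voxel scores of two maps over ROI ∪ background voxels."""

    labels: np.ndarray  # 1 inside target ROI, 0 in background
    score_a: np.ndarray
    score_b: np.ndarray
    voxel_index: np.ndarray  # flat voxel ids, for traceability

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.score_a) == len(self.score_b) == len(self.voxel_index) == n):
            raise ValueError("scores/labels are not paired")
        if self.labels.min() == self.labels.max():
            raise ValueError("both classes must be present")


def make_labeled_scores(
    map_a: np.ndarray,
    map_b: np.ndarray,
    roi: np.ndarray,
    background: np.ndarray,
) -> LabeledScores:
    """Collect paired scores over the target ROI and background voxels."""
    if np.logical_and(roi, background).any():
        raise ValueError("roi and background masks overlap")
    if not roi.any() or not background.any():
        raise ValueError("roi and background must both be nonempty")
    sel = roi | background
    idx = np.flatnonzero(sel.reshape(-1))
    labels = roi.reshape(-1)[idx].astype(int)
    a = map_a.reshape(-1)[idx]
    b = map_b.reshape(-1)[idx]
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("maps contain no-value voxels inside roi/background")
    return LabeledScores(labels=labels, score_a=a, score_b=b, voxel_index=idx)


@dataclass
class RocCurve:
    """Sensitivity/specificity parametric in a descending score threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    mode: str
    n_pos: int
    n_neg: int


def roc_curve(scores: np.ndarray, labels: np.ndarray, mode: str = "voxel-count") -> RocCurve:
    """Threshold sweep over the unique observed scores (plus ±∞ sentinels).

    voxel-count: sens(t) = P(score ≥ t | pos), spec(t) = P(score < t | neg).
    magnitude-weighted: each voxel contributes its (nonnegative) score
    instead of a unit count.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "magnitude-weighted" and scores.min() < 0:
        raise ValueError("magnitude-weighted mode requires nonnegative scores")

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]])
    if mode == "voxel-count":
        w_pos = np.ones_like(pos)
        w_neg = np.ones_like(neg)
    else:
        w_pos, w_neg = pos, neg
    tot_pos = w_pos.sum()
    tot_neg = w_neg.sum()
    sens = np.array([w_pos[pos >= t].sum() / tot_pos for t in thresholds])
    fpr = np.array([w_neg[neg >= t].sum() / tot_neg for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=1.0 - fpr,
        mode=mode,
        n_pos=len(pos),
        n_neg=len(neg),
    )


@dataclass
class AucResult:
    auc: float
    n_pos: int
    n_neg: int


def auc(curve: RocCurve) -> AucResult:
    """Trapezoid area under sensitivity vs. (1 − specificity).

    On the exact step curve, ties enter via the midpoint rule, so in
    voxel-count mode this equals the Mann–Whitney statistic with ½ for ties.
    """
    x = 1.0 - curve.specificity
    y = curve.sensitivity
    order = np.argsort(x, kind="stable")
    value = float(np.trapezoid(y[order], x[order]))
    return AucResult(auc=value, n_pos=curve.n_pos, n_neg=curve.n_neg)


def auc_from_scores(scores, labels, mode: str = "voxel-count") -> AucResult:
    """Convenience: ROC sweep + trapezoid AUC in one call."""
    return auc(roc_curve(scores, labels, mode=mode))


# ---------------------------------------------------------------------------
# Fast DeLong
# ---------------------------------------------------------------------------

def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Midrank-based structural components and AUC for one score set."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = rankdata(all_scores, method="average")
    tx = rankdata(pos, method="average")
    ty = rankdata(neg, method="average")
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc_value = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc_value, v10, v01


@dataclass
class DelongComparison:
    """Paired comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


def delong_test(ls: LabeledScores) -> DelongComparison:
    """Fast DeLong paired test of AUC(score_a) vs AUC(score_b).

    Uses midrank structural components (O(n log n)); the z statistic is the
    AUC difference over the DeLong standard error, with a two-sided normal
    p value (no continuity correction).
    """
    pos_mask = ls.labels == 1
    m = int(pos_mask.sum())
    n = int((~pos_mask).sum())
    if m < 2 or n < 2:
        raise ValueError("need at least 2 positives and 2 negatives")
    aucs, V10, V01 = [], [], []
    for s in (ls.score_a, ls.score_b):
        a, v10, v01 = _delong_components(s[pos_mask], s[~pos_mask])
        aucs.append(a)
        V10.append(v10)
        V01.append(v01)
    s10 = np.cov(np.stack(V10))
    s01 = np.cov(np.stack(V01))
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = aucs[0] - aucs[1]
    if var_diff <= 0:
        if delta == 0:
            return DelongComparison(aucs[0], aucs[1], 0.0, 0.0, 1.0)
        raise NumericalDegeneracyError(
            "zero DeLong variance with unequal AUCs"
        )
    z = delta / np.sqrt(var_diff)
    # floor at the smallest normal double: p is in (0, 1] even when the
    # normal tail underflows
    p = float(max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny))
    return DelongComparison(
        auc_a=float(aucs[0]), auc_b=float(aucs[1]), var_diff=var_diff, z=float(z), p=p
    )
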