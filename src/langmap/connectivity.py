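"""Seed-based correlation mapping and the voxelwise RSN classifier.

The resting-state pipeline: every in-brain voxel's time series is
correlated with every other in-brain voxel (Fisher-z transformed), the
resulting per-voxel correlation map is propagated through a small
feed-forward multilayer perceptron trained on seed maps with known network
labels, and the classifier emits, per voxel, one likelihood in [0, 1] per
network class.  The language-channel map is finally rank-uniformized over
the brain (probability integral transform) so its in-mask values are
uniform on [0, 1].

The MLP has one hidden layer, logistic activations on hidden and output
units, and independent (softmax-free) logistic outputs trained with
cross-entropy by full-batch gradient descent — so the per-class outputs are
likelihoods in [0, 1], not a simplex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._seeds import stage_rng
from .exceptions import UndefinedCorrelationError

#: |r| is clipped here before the Fisher transform so atanh stays finite.
R_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap:
    """Fisher-z seed-correlation map over a brain mask."""

    values: np.ndarray  # 3-D, NaN outside mask
    seed_descriptor: object
    mask: np.ndarray

    def masked_vector(self) -> np.ndarray:
        return self.values[self.mask]


def _concat_series(runs: list[np.ndarray]) -> np.ndarray:
    if not runs:
        raise ValueError("need at least one run")
    shape = runs[0].shape[:3]
    if any(r.shape[:3] != shape for r in runs):
        raise ValueError("runs are not on a common grid")
    # float64: correlations of a voxel with itself must hit 1 exactly
    return np.concatenate(
        [r.reshape(-1, r.shape[-1]).astype(np.float64) for r in runs], axis=1
    )


def _standardize_rows(data: np.ndarray) -> np.ndarray:
    """Rows to zero mean, unit L2 norm; constant rows become all-zero."""
    c = data - data.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, c / norm, 0.0)
    return z


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with |r| clipped to keep the transform finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def seed_correlation_map(
    runs: list[np.ndarray],
    seed,
    mask: np.ndarray,
) -> CorrelationMap:
    """Correlate every in-mask voxel with a seed over concatenated runs.

    ``seed`` is a voxel coordinate tuple or a boolean ROI mask (the seed
    series is then the spatial mean over the ROI).  Returns Fisher-z values.
    """
    series = _concat_series(runs)
    shape = runs[0].shape[:3]
    if isinstance(seed, np.ndarray) and seed.dtype == bool:
        if not seed[mask].any():
            raise ValueError("seed ROI lies outside the brain mask")
        seed_series = series[seed.reshape(-1)].mean(axis=0)
        descriptor = "roi"
    else:
        coord = tuple(int(c) for c in seed)
        if not mask[coord]:
            raise ValueError(f"seed voxel {coord} is outside the brain mask")
        seed_series = series[np.ravel_multi_index(coord, shape)]
        descriptor = coord
    if np.std(seed_series) == 0:
        raise UndefinedCorrelationError("seed series is constant")

    vox = _standardize_rows(series[mask.reshape(-1)])
    s = _standardize_rows(seed_series[None, :])[0]
    r = vox @ s
    values = np.full(shape, np.nan)
    values[mask] = fisher_z(r)
    return CorrelationMap(values=values, seed_descriptor=descriptor, mask=mask)


def all_voxel_correlation(runs: list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    """(V × V) Fisher-z correlation matrix between all in-mask voxels."""
    series = _concat_series(runs)[mask.reshape(-1)]
    z = _standardize_rows(series)
    return fisher_z(z @ z.T)


# ---------------------------------------------------------------------------
# Training set
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Row-per-seed correlation maps with network labels."""

    inputs: np.ndarray  # (rows, n_mask_voxels), z-scored per row
    labels: np.ndarray  # (rows,) class indices
    class_labels: tuple[str, ...]
    mask: np.ndarray
    n_seed_rois: int
    shuffle_seed: int


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def build_training_set(
    cohort,
    atlas,
    seeds_per_network: int = 3,
    mask: np.ndarray | None = None,
    eligibility_threshold: float = 0.7,
    seed: int = 0,
) -> TrainingSet:
    """Correlation maps from high-weight seed voxels of each planted network.

    One row per (subject × seed); the row label is the seed's network.  Seeds
    are drawn without replacement from voxels whose true membership weight
    exceeds ``eligibility_threshold``.  Rows are z-scored and shuffled with a
    logged seed.
    """
    if mask is None:
        from .simulate import GridSpec

        mask = GridSpec(shape=atlas[0].weight_map.shape).brain_mask()
    rng = stage_rng(seed, "training-seeds")
    seed_coords: list[tuple[tuple[int, int, int], int]] = []
    for k, net in enumerate(atlas):
        eligible = np.argwhere((net.weight_map >= eligibility_threshold) & mask)
        if len(eligible) == 0:
            raise ValueError(
                f"network {net.label} has no voxels above the seed-eligibility "
                f"threshold {eligibility_threshold}"
            )
        take = min(seeds_per_network, len(eligible))
        if take < seeds_per_network:
            warnings.warn(f"network {net.label}: only {take} eligible seed voxels")
        pick = rng.choice(len(eligible), size=take, replace=False)
        seed_coords.extend((tuple(int(v) for v in eligible[i]), k) for i in pick)

    rows, labels = [], []
    for subject in cohort:
        series = _concat_series(subject.rest_runs)
        vox = _standardize_rows(series[mask.reshape(-1)])
        shape = subject.rest_runs[0].shape[:3]
        for coord, k in seed_coords:
            s = _standardize_rows(series[np.ravel_multi_index(coord, shape)][None])[0]
            rows.append(fisher_z(vox @ s))
            labels.append(k)

    X = _zscore_rows(np.asarray(rows))
    y = np.asarray(labels)
    perm = stage_rng(seed, "training-shuffle").permutation(len(y))
    return TrainingSet(
        inputs=X[perm],
        labels=y[perm],
        class_labels=tuple(net.label for net in atlas),
        mask=mask,
        n_seed_rois=len(seed_coords),
        shuffle_seed=seed,
    )


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class MlpModel:
    """One-hidden-layer feed-forward classifier with logistic units."""

    w_hidden: np.ndarray  # (n_inputs, hidden)
    b_hidden: np.ndarray
    w_out: np.ndarray  # (hidden, n_classes)
    b_out: np.ndarray
    class_labels: tuple[str, ...]
    training_seed: int
    loss_history: np.ndarray = field(default=None)
    converged: bool = True

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w_hidden.shape[0], self.w_hidden.shape[1], self.w_out.shape[1])

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Per-class likelihoods in [0, 1] for each input row."""
        h = _sigmoid(X @ self.w_hidden + self.b_hidden)
        return _sigmoid(h @ self.w_out + self.b_out)

    def save(self, path) -> None:
        """Serialize weights plus metadata into a single .npz container."""
        meta = {
            "class_labels": list(self.class_labels),
            "training_seed": int(self.training_seed),
            "converged": bool(self.converged),
        }
        np.savez_compressed(
            path,
            w_hidden=self.w_hidden,
            b_hidden=self.b_hidden,
            w_out=self.w_out,
            b_out=self.b_out,
            loss_history=self.loss_history
            if self.loss_history is not None
            else np.zeros(0),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "MlpModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"]).decode())
            return cls(
                w_hidden=f["w_hidden"],
                b_hidden=f["b_hidden"],
                w_out=f["w_out"],
                b_out=f["b_out"],
                class_labels=tuple(meta["class_labels"]),
                training_seed=meta["training_seed"],
                loss_history=f["loss_history"],
                converged=meta["converged"],
            )


def _cross_entropy(P: np.ndarray, T: np.ndarray) -> float:
    eps = 1e-12
    P = np.clip(P, eps, 1.0 - eps)
    return float(-(T * np.log(P) + (1.0 - T) * np.log(1.0 - P)).mean())


def train_mlp(
    ts: TrainingSet,
    hidden_units: int = 20,
    max_epochs: int = 500,
    learning_rate: float = 1.0,
    seed: int = 0,
    loss_tol: float = 1e-5,
) -> MlpModel:
    """Fit the classifier by full-batch gradient descent on cross-entropy.

    Targets are one-hot per class but outputs are independent logistics, so
    each class likelihood is trained as its own binary problem.  Training is
    reproducible from ``seed``; if the loss has not flattened within
    ``max_epochs`` a warning is raised and the model is returned with its
    loss history for diagnosis.
    """
    X, y = ts.inputs, ts.labels
    n, d = X.shape
    k = len(ts.class_labels)
    T = np.zeros((n, k))
    T[np.arange(n), y] = 1.0

    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, np.sqrt(2.0 / (d + hidden_units)), size=(d, hidden_units))
    b1 = np.zeros(hidden_units)
    w2 = rng.normal(0.0, np.sqrt(2.0 / (hidden_units + k)), size=(hidden_units, k))
    b2 = np.zeros(k)

    losses = np.empty(max_epochs + 1)
    converged = False
    for epoch in range(max_epochs):
        H = _sigmoid(X @ w1 + b1)
        P = _sigmoid(H @ w2 + b2)
        losses[epoch] = _cross_entropy(P, T)
        # gradient of mean binary cross-entropy w.r.t. pre-activations
        dZ2 = (P - T) / (n * k)
        gw2 = H.T @ dZ2
        gb2 = dZ2.sum(axis=0)
        dH = dZ2 @ w2.T * H * (1.0 - H)
        gw1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        w1 -= learning_rate * gw1
        b1 -= learning_rate * gb1
        w2 -= learning_rate * gw2
        b2 -= learning_rate * gb2
        if epoch > 10 and abs(losses[epoch - 1] - losses[epoch]) < loss_tol * losses[epoch]:
            converged = True
    H = _sigmoid(X @ w1 + b1)
    losses[max_epochs] = _cross_entropy(_sigmoid(H @ w2 + b2), T)
    converged = converged or losses[max_epochs] < 0.5 * losses[0]
    if not converged:
        warnings.warn("MLP training did not converge within max_epochs")
    return MlpModel(
        w_hidden=w1,
        b_hidden=b1,
        w_out=w2,
        b_out=b2,
        class_labels=ts.class_labels,
        training_seed=seed,
        loss_history=losses,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Voxelwise classification
# ---------------------------------------------------------------------------

@dataclass
class RsnLikelihoodMap:
    """Per-voxel network-class likelihoods in [0, 1] over a brain mask."""

    values: np.ndarray  # (n_mask_voxels, n_classes)
    class_labels: tuple[str, ...]
    mask: np.ndarray

    @property
    def language_index(self) -> int:
        return self.class_labels.index("LAN")

    def channel_volume(self, label_or_index) -> np.ndarray:
        """One class channel as a 3-D map, NaN outside the mask."""
        idx = (
            self.class_labels.index(label_or_index)
            if isinstance(label_or_index, str)
            else int(label_or_index)
        )
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.values[:, idx]
        return vol

    def language_volume(self, uniformized: bool = True) -> np.ndarray:
        """The language-channel map, optionally rank-uniformized in-mask."""
        vol = self.channel_volume(self.language_index)
        if uniformized:
            vol[self.mask] = uniformize(vol[self.mask])
        return vol


def classify_voxelwise(
    rest_runs: list[np.ndarray],
    model: MlpModel,
    mask: np.ndarray,
) -> RsnLikelihoodMap:
    """Apply the classifier to every in-mask voxel of a subject's rest data.

    For each voxel, its whole-brain Fisher-z correlation map (voxel as seed)
    is z-scored — the same normalization used at training — and propagated
    through the network.
    """
    n_mask = int(mask.sum())
    if model.layer_sizes[0] != n_mask:
        raise ValueError(
            f"model expects {model.layer_sizes[0]} input voxels, mask has {n_mask}"
        )
    Z = all_voxel_correlation(rest_runs, mask)  # (V, V)
    values = model.forward(_zscore_rows(Z))
    return RsnLikelihoodMap(values=values, class_labels=model.class_labels, mask=mask)


def uniformize(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Probability integral transform via midranks: value → (midrank − ½)/N.

    Preserves rank order, maps into (0, 1), and is idempotent up to ties.
    With a mask, only in-mask entries are transformed (others NaN).
    """
    if mask is None:
        flat = np.asarray(values, dtype=float)
        if flat.size < 2:
            raise ValueError("need at least 2 values to uniformize")
        return (rankdata(flat, method="average") - 0.5) / flat.size
    out = np.full(values.shape, np.nan)
    v = values[mask]
    if v.size < 2:
        raise ValueError("need at least 2 in-mask voxels to uniformize")
    out[mask] = (rankdata(v, method="average") - 0.5) / v.size
    return out


def split_rest_runs(rest_runs: list[np.ndarray], n_portions: int = 3) -> list[np.ndarray]:
    """Split concatenated rest data into contiguous equal-length portions.

    Each portion has ``floor(T / n)`` frames; remainder frames at the end
    are discarded.  Portions emulate shorter acquisitions comparable to the
    task run's duration.
    """
    if n_portions < 1:
        raise ValueError("n_portions must be >= 1")
    full = np.concatenate(rest_runs, axis=-1)
    total = full.shape[-1]
    if total < n_portions:
        raise ValueError("fewer frames than portions")
    plen = total // n_portions
    return [full[..., i * plen : (i + 1) * plen] for i in range(n_portions)]
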