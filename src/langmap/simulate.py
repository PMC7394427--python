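"""Synthetic multi-subject BOLD cohorts with planted resting-state networks.

This module generates everything the downstream mapping pipeline consumes:
a small 3-D voxel grid with a brain mask, an atlas of K spatial network
topographies (one of which is a left-lateralized language network with a
frontal "Broca-like" and a temporal "Wernicke-like" focus), per-subject rest
and task runs driven by shared network time courses, and ground-truth ROI
masks derived from the planted language network.

The generative model for a voxel time series is a linear mixture

    y_v(t) = baseline + sum_k w_kv * a_k * s_k(t) + task_v(t) + noise_sd * eps_v(t)

where ``s_k`` are temporally smoothed (5-frame moving average), mutually
independent, unit-variance network time courses shared by all voxels of a
subject-run, ``w_kv`` the network membership weights, ``a_k`` per-subject
network gains, and ``eps`` white Gaussian noise.  Task runs add a
block-design evoked response (boxcar convolved with a hemodynamic response
function) over the expressive language focus and over task-general
(salience-like and attention-like) regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from ._seeds import stage_rng, stage_seed

#: The seven resting-state network classes assigned by the classifier.
#: LAN is the language network; DAN (dorsal attention) and VAN
#: (ventral attention / salience) double as the task-general systems
#: recruited by any goal-directed task.
RSN_LABELS = ("LAN", "DAN", "VAN", "MOT", "VIS", "FPC", "DMN")

#: Default scanner baseline of the simulated BOLD signal, in arbitrary
#: scanner units.  Task amplitudes are specified in percent of this baseline.
BASELINE = 100.0

#: Width (frames) of the moving average applied to network time courses to
#: mimic BOLD autocorrelation.
TEMPORAL_SMOOTH_FRAMES = 5

#: Gaussian blob weights below this are truncated to exactly 0, giving each
#: network a compact spatial support (radius ~2.4 sigma) so that most of the
#: brain is genuinely outside every network, as in real topographies.
WEIGHT_SUPPORT_THRESHOLD = 0.05

#: Evoked task responses are confined to the core of their region (membership
#: weight at or above this), emulating focal activation rather than
#: activation of a network's entire correlational extent.
TASK_REGION_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Grid / acquisition descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry.

    The grid is split at the midpoint of ``hemisphere_axis``; lower indices
    are the "left" hemisphere.  The brain mask is an inscribed ellipsoid
    covering ``brain_radius_frac`` of each half-extent.
    """

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    hemisphere_axis: int = 0
    brain_radius_frac: float = 0.9

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"all grid dimensions must be >= 8, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.hemisphere_axis not in (0, 1, 2):
            raise ValueError("hemisphere_axis must be 0, 1 or 2")

    def brain_mask(self) -> np.ndarray:
        """Boolean ellipsoid mask centred on the grid."""
        axes = np.ogrid[tuple(slice(0, s) for s in self.shape)]
        center = [(s - 1) / 2.0 for s in self.shape]
        radii = [self.brain_radius_frac * s / 2.0 for s in self.shape]
        d2 = sum(((ax - c) / r) ** 2 for ax, c, r in zip(axes, center, radii))
        return d2 <= 1.0

    def left_mask(self) -> np.ndarray:
        """Boolean mask of the left-hemisphere half of the grid."""
        mask = np.zeros(self.shape, dtype=bool)
        idx = [slice(None)] * 3
        idx[self.hemisphere_axis] = slice(0, self.shape[self.hemisphere_axis] // 2)
        mask[tuple(idx)] = True
        return mask


@dataclass(frozen=True)
class AcquisitionParams:
    """Frame counts and repetition time of the emulated protocol."""

    tr_s: float = 2.2
    rest_frames_per_run: int = 160
    rest_runs: int = 2
    task_frames: int = 100

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for name in ("rest_frames_per_run", "rest_runs", "task_frames"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class BlockDesign:
    """Alternating off/on block design, starting with rest."""

    block_len_frames: int = 10
    n_cycles: int = 5
    starts_with: str = "rest"

    @property
    def total_frames(self) -> int:
        return 2 * self.block_len_frames * self.n_cycles

    def boxcar(self) -> np.ndarray:
        """0/1 task indicator per frame (0 during rest blocks)."""
        cycle = np.concatenate(
            [np.zeros(self.block_len_frames), np.ones(self.block_len_frames)]
        )
        if self.starts_with == "task":
            cycle = 1.0 - cycle
        return np.tile(cycle, self.n_cycles)


# ---------------------------------------------------------------------------
# Network atlas
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """One planted network topography.

    ``weight_map`` holds per-voxel membership weights in [0, 1] with peak
    weight exactly 1 at each focus.  ``foci`` lists the primary focus
    centres (voxel coordinates); homotopic mirror blobs, if any, are part of
    the weight map but are not listed as foci.
    """

    label: str
    weight_map: np.ndarray
    foci: list[tuple[int, int, int]]
    lateralization: float
    sigma_vox: float = 1.8
    mirror_fraction: float = 1.0 / 3.0

    def focus_component(self, index: int) -> np.ndarray:
        """Truncated Gaussian blob (peak 1) of one focus, on the full grid."""
        return _gaussian_blob(self.weight_map.shape, self.foci[index], self.sigma_vox)


def _gaussian_blob(shape, center, sigma):
    axes = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((ax - c) ** 2 for ax, c in zip(axes, center))
    g = np.exp(-d2 / (2.0 * sigma**2))
    g[g < WEIGHT_SUPPORT_THRESHOLD] = 0.0
    return g


def _mirror(coord, grid: GridSpec):
    c = list(coord)
    ax = grid.hemisphere_axis
    c[ax] = grid.shape[ax] - 1 - c[ax]
    return tuple(c)


def make_network_atlas(
    grid: GridSpec,
    n_networks: int = 7,
    seed: int = 0,
    sigma_vox: float = 1.8,
    mirror_fraction: float = 1.0 / 3.0,
    nonlan_mirror_fraction: float = 1.0,
    min_focus_sep_vox: float = 5.0,
) -> list[NetworkSpec]:
    """Plant ``n_networks`` Gaussian-blob network topographies.

    The first network is the language network (label ``LAN``) with two
    disjoint left-hemisphere foci — an anterior "Broca-like" and a posterior
    "Wernicke-like" one — plus weaker homotopic mirror blobs in the right
    hemisphere (weight ``mirror_fraction``), which lateralizes roughly 75%
    of the weight mass to the left.  Remaining networks get one primary
    focus each with a full-weight homotopic mirror
    (``nonlan_mirror_fraction``): non-language networks are hemispherically
    symmetric, the language network is left-dominant.  Foci are placed by
    rejection sampling with a minimum pairwise separation.

    Deterministic for a fixed seed.
    """
    if n_networks < 2:
        raise ValueError("need the language network plus at least one other class")
    rng = np.random.default_rng(seed)
    brain = grid.brain_mask()
    shape = grid.shape
    ax = grid.hemisphere_axis

    # Eligible focus sites: inside the brain and far enough left of the
    # midline that the half-max component (radius sigma*sqrt(2 ln 2)) stays
    # entirely in the left hemisphere.  Placing every primary focus on the
    # left also guarantees focus-to-mirror separation.
    coords = np.argwhere(brain)
    half = shape[ax] / 2.0
    component_radius = sigma_vox * np.sqrt(2.0 * np.log(2.0))
    left_sites = coords[coords[:, ax] < half - component_radius - 0.5]
    n_foci = n_networks + 1  # LAN has two foci
    # the two language foci define disjoint ROIs: their half-max spheres
    # must be separated by at least one empty voxel on the integer lattice
    lan_sep = 2.0 * np.floor(component_radius) + 2.0

    def _place_all() -> list[tuple[int, int, int]] | None:
        placed: list[tuple[int, int, int]] = []
        order = rng.permutation(len(left_sites))
        for i in order:
            cand = tuple(int(v) for v in left_sites[i])
            required = max(min_focus_sep_vox, lan_sep) if len(placed) == 1 else min_focus_sep_vox
            if all(
                np.linalg.norm(np.subtract(cand, p)) >= required
                for p in placed
            ):
                placed.append(cand)
                if len(placed) == n_foci:
                    return placed
        return None

    foci = None
    for _ in range(50):
        foci = _place_all()
        if foci is not None:
            break
    if foci is None:
        raise RuntimeError(
            "could not place network foci with the requested separation; "
            "use a larger grid or a smaller min_focus_sep_vox"
        )
    focus_iter = iter(foci)

    def _draw(_sites=None) -> tuple[int, int, int]:
        return next(focus_iter)

    def _weight_map(foci, mirror) -> np.ndarray:
        w = np.zeros(shape)
        for f in foci:
            np.maximum(w, _gaussian_blob(shape, f, sigma_vox), out=w)
            np.maximum(
                w, mirror * _gaussian_blob(shape, _mirror(f, grid), sigma_vox), out=w
            )
        return w

    def _lateralization(w) -> float:
        left = grid.left_mask()
        total = float(w[brain].sum())
        return float(w[brain & left].sum()) / total if total > 0 else 0.0

    atlas: list[NetworkSpec] = []
    lan_foci = [_draw(), _draw()]
    w = _weight_map(lan_foci, mirror_fraction)
    atlas.append(
        NetworkSpec(
            "LAN", w, lan_foci, _lateralization(w),
            sigma_vox=sigma_vox, mirror_fraction=mirror_fraction,
        )
    )
    labels = list(RSN_LABELS[1:]) + [
        f"NET{i}" for i in range(7, n_networks)
    ]
    for k in range(n_networks - 1):
        focus = _draw()
        w = _weight_map([focus], nonlan_mirror_fraction)
        atlas.append(
            NetworkSpec(
                labels[k], w, [focus], _lateralization(w),
                sigma_vox=sigma_vox, mirror_fraction=nonlan_mirror_fraction,
            )
        )
    return atlas


def rebuild_weight_map(
    foci, grid: GridSpec, sigma_vox: float, mirror_fraction: float
) -> np.ndarray:
    """Weight map as the max over focus Gaussians and their weaker mirrors."""
    w = np.zeros(grid.shape)
    for f in foci:
        np.maximum(w, _gaussian_blob(grid.shape, f, sigma_vox), out=w)
        np.maximum(
            w,
            mirror_fraction * _gaussian_blob(grid.shape, _mirror(f, grid), sigma_vox),
            out=w,
        )
    return w


def jitter_atlas(
    atlas: list[NetworkSpec],
    grid: GridSpec,
    jitter_vox: float,
    rng: np.random.Generator,
) -> list[NetworkSpec]:
    """Per-subject topographic variability: shift every focus by a rounded
    isotropic normal offset (sd ``jitter_vox``) and rebuild the weight maps.

    With ``jitter_vox == 0`` the input atlas is returned unchanged.
    """
    if jitter_vox <= 0:
        return atlas
    brain = grid.brain_mask()
    left = grid.left_mask()
    out = []
    for net in atlas:
        foci = []
        for f in net.foci:
            for _ in range(100):
                offset = np.rint(rng.normal(0.0, jitter_vox, size=3)).astype(int)
                cand = tuple(int(np.clip(c + o, 0, s - 1))
                             for c, o, s in zip(f, offset, grid.shape))
                if brain[cand] and left[cand]:
                    break
            else:
                cand = f
            foci.append(cand)
        w = rebuild_weight_map(foci, grid, net.sigma_vox, net.mirror_fraction)
        total = float(w[brain].sum())
        lat = float(w[brain & left].sum()) / total if total > 0 else 0.0
        out.append(
            NetworkSpec(net.label, w, foci, lat,
                        sigma_vox=net.sigma_vox, mirror_fraction=net.mirror_fraction)
        )
    return out


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

#: Task-amplitude region classes, in percent-signal-change units.
TASK_REGIONS = ("language_expressive", "language_receptive", "salience", "attention")


@dataclass
class SubjectSpec:
    """Per-subject generative parameters."""

    subject_id: str
    network_amplitudes: np.ndarray  # per-network gain, in signal sd units
    task_amplitudes: dict[str, float]  # percent signal change per region class
    noise_sd: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not np.all(np.isfinite(self.network_amplitudes)):
            raise ValueError("network amplitudes must be finite")
        if not all(np.isfinite(v) for v in self.task_amplitudes.values()):
            raise ValueError("task amplitudes must be finite")

    def to_json(self) -> str:
        d = asdict(self)
        d["network_amplitudes"] = [float(v) for v in self.network_amplitudes]
        return json.dumps(d, indent=2)


@dataclass
class RoiSet:
    """A priori language ROI masks, confined to the left hemisphere."""

    broca_mask: np.ndarray
    wernicke_mask: np.ndarray
    nonlanguage_mask: np.ndarray


@dataclass
class SyntheticSubject:
    """One simulated patient: runs, ground truth, and ROI masks."""

    rest_runs: list[np.ndarray]
    task_run: np.ndarray
    truth_atlas: list[NetworkSpec]
    roi_set: RoiSet
    spec: SubjectSpec


@dataclass(frozen=True)
class PopulationParams:
    """Distributions the cohort's subject parameters are drawn from.

    Amplitude draws are normal with the stated mean/sd, truncated at 0.
    ``task_amp_mean`` keys are the :data:`TASK_REGIONS`; by default the task
    drives the expressive language focus and the task-general (salience-like,
    attention-like) regions but not the receptive focus, emulating an
    expressive task such as word-stem completion.
    """

    network_amp_mean: float = 1.0
    network_amp_sd: float = 0.3
    task_amp_mean: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 1.0)
    task_amp_sd: tuple[float, float, float, float] = (0.3, 0.0, 0.3, 0.3)
    noise_sd: float = 0.8
    focus_jitter_vox: float = 0.0


def _smoothed_unit_timecourse(rng: np.random.Generator, n_frames: int) -> np.ndarray:
    """White noise smoothed by a moving average, standardized to unit sd."""
    raw = rng.standard_normal(n_frames + TEMPORAL_SMOOTH_FRAMES - 1)
    kernel = np.ones(TEMPORAL_SMOOTH_FRAMES) / TEMPORAL_SMOOTH_FRAMES
    s = np.convolve(raw, kernel, mode="valid")
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def _simulate_run(
    atlas: list[NetworkSpec],
    spec: SubjectSpec,
    n_frames: int,
    rng: np.random.Generator,
    evoked: np.ndarray | None = None,
) -> np.ndarray:
    """Shared generative core for rest and task runs.

    ``evoked``, if given, is a (x, y, z, t) additive evoked-response array in
    raw signal units.
    """
    if not atlas:
        raise ValueError("atlas must be nonempty")
    shape = atlas[0].weight_map.shape
    n_vox = int(np.prod(shape))
    signals = np.zeros((n_vox, n_frames))
    for k, net in enumerate(atlas):
        s_k = _smoothed_unit_timecourse(rng, n_frames)
        a_k = float(spec.network_amplitudes[k])
        signals += np.outer(net.weight_map.reshape(-1), a_k * s_k)
    if spec.noise_sd > 0:
        signals += spec.noise_sd * rng.standard_normal((n_vox, n_frames))
    run = BASELINE + signals.reshape(shape + (n_frames,))
    if evoked is not None:
        run = run + evoked
    return run.astype(np.float32)


def simulate_rest_run(
    atlas: list[NetworkSpec],
    spec: SubjectSpec,
    acq: AcquisitionParams = AcquisitionParams(),
    run_index: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one resting-state run as a 4-D (x, y, z, t) array."""
    if rng is None:
        rng = stage_rng(spec.rng_seed, "rest", run_index)
    return _simulate_run(atlas, spec, acq.rest_frames_per_run, rng)


def task_amplitude_map(
    atlas: list[NetworkSpec], spec: SubjectSpec, grid: GridSpec | None = None
) -> np.ndarray:
    """Per-voxel evoked-response amplitude, in raw signal units.

    The expressive amplitude loads on the language network's first
    (anterior) focus, the receptive amplitude on its second (posterior)
    focus, and the salience/attention amplitudes on the weight maps of the
    VAN-like and DAN-like networks.
    """
    lan = atlas[0]
    by_label = {net.label: net for net in atlas}

    def _core(w: np.ndarray) -> np.ndarray:
        return w * (w >= TASK_REGION_THRESHOLD)

    pct = np.zeros(lan.weight_map.shape)
    pct += spec.task_amplitudes["language_expressive"] * _core(lan.focus_component(0))
    pct += spec.task_amplitudes["language_receptive"] * _core(lan.focus_component(1))
    salience_net = by_label.get("VAN", atlas[min(2, len(atlas) - 1)])
    attention_net = by_label.get("DAN", atlas[min(1, len(atlas) - 1)])
    pct += spec.task_amplitudes["salience"] * _core(salience_net.weight_map)
    pct += spec.task_amplitudes["attention"] * _core(attention_net.weight_map)
    return pct * BASELINE / 100.0


def simulate_task_run(
    atlas: list[NetworkSpec],
    spec: SubjectSpec,
    acq: AcquisitionParams = AcquisitionParams(),
    design: BlockDesign = BlockDesign(),
    hrf_kernel=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the block-design task run as a 4-D (x, y, z, t) array.

    The rest-run generative model plus ``A_v * (boxcar ⊛ HRF)(t)``, where
    ``A_v`` is the :func:`task_amplitude_map`.
    """
    if design.total_frames != acq.task_frames:
        raise ValueError(
            f"design total frames ({design.total_frames}) != acquisition task "
            f"frames ({acq.task_frames})"
        )
    from .glm import canonical_hrf, task_regressor

    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(acq.tr_s)
    x = task_regressor(design, hrf_kernel)  # unit peak
    amp = task_amplitude_map(atlas, spec)
    evoked = amp[..., None] * x[None, None, None, :]
    if rng is None:
        rng = stage_rng(spec.rng_seed, "task")
    return _simulate_run(atlas, spec, acq.task_frames, rng, evoked=evoked)


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def make_roi_set(
    lan: NetworkSpec, grid: GridSpec, weight_threshold: float = 0.5
) -> RoiSet:
    """Derive Broca-like / Wernicke-like / non-language masks from the
    planted language network.

    The two language ROIs are the connected components of the thresholded
    weight map that contain the anterior and posterior focus respectively;
    the non-language background is every other left-hemisphere in-brain
    voxel.  All three masks are pairwise disjoint and confined to the left
    hemisphere.
    """
    if len(lan.foci) < 2:
        raise ValueError("language network must have two foci")
    brain = grid.brain_mask()
    left = grid.left_mask()
    above = (lan.weight_map >= weight_threshold) & brain & left
    labeled, _ = ndimage.label(above)
    comp_ids = [labeled[tuple(f)] for f in lan.foci[:2]]
    from .exceptions import DegenerateRoiError

    if comp_ids[0] == 0 or comp_ids[1] == 0:
        raise DegenerateRoiError("a language focus fell outside its thresholded component")
    if comp_ids[0] == comp_ids[1]:
        raise DegenerateRoiError("the two language foci merged into one component")
    broca = labeled == comp_ids[0]
    wernicke = labeled == comp_ids[1]
    nonlang = brain & left & ~broca & ~wernicke
    return RoiSet(broca_mask=broca, wernicke_mask=wernicke, nonlanguage_mask=nonlang)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size=None):
    draw = rng.normal(mean, sd, size=size) if sd > 0 else np.full(size if size else (), mean, dtype=float)
    return np.maximum(draw, 0.0)


def draw_subject_spec(
    subject_index: int,
    n_networks: int,
    pop: PopulationParams,
    master_seed: int,
) -> SubjectSpec:
    """Draw one subject's generative parameters from the population."""
    rng = stage_rng(master_seed, "subject-params", subject_index)
    amps = _truncated_normal(rng, pop.network_amp_mean, pop.network_amp_sd, n_networks)
    task_amps = {
        region: float(_truncated_normal(rng, m, s))
        for region, m, s in zip(TASK_REGIONS, pop.task_amp_mean, pop.task_amp_sd)
    }
    return SubjectSpec(
        subject_id=f"SUB_{subject_index:03d}",
        network_amplitudes=amps,
        task_amplitudes=task_amps,
        noise_sd=pop.noise_sd,
        rng_seed=stage_seed(master_seed, "subject-rng", subject_index),
    )


def make_cohort(
    n_subjects: int = 35,
    population_params: PopulationParams = PopulationParams(),
    master_seed: int = 0,
    grid: GridSpec = GridSpec(),
    acq: AcquisitionParams = AcquisitionParams(),
    design: BlockDesign = BlockDesign(),
    n_networks: int = 7,
    roi_threshold: float = 0.5,
) -> list[SyntheticSubject]:
    """Generate a reproducible cohort of synthetic subjects.

    All subjects share one network atlas (derived from ``master_seed``) and
    hence one ROI set; per-subject amplitudes, noise, and time courses are
    drawn from per-subject streams, so cohorts are bitwise reproducible.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects (group sd undefined)")
    atlas = make_network_atlas(grid, n_networks, seed=stage_seed(master_seed, "atlas"))
    roi_set = make_roi_set(atlas[0], grid, weight_threshold=roi_threshold)
    subjects = []
    for i in range(n_subjects):
        spec = draw_subject_spec(i, n_networks, population_params, master_seed)
        subj_atlas = jitter_atlas(
            atlas, grid, population_params.focus_jitter_vox,
            stage_rng(master_seed, "jitter", i),
        )
        rest = [
            simulate_rest_run(subj_atlas, spec, acq, run_index=r)
            for r in range(acq.rest_runs)
        ]
        task = simulate_task_run(subj_atlas, spec, acq, design)
        subjects.append(
            SyntheticSubject(
                rest_runs=rest,
                task_run=task,
                truth_atlas=subj_atlas,
                roi_set=roi_set,
                spec=spec,
            )
        )
    return subjects
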