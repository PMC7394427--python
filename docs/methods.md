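# Methods

## The problem

Presurgical language mapping asks where the language system sits in an
individual brain so that surgery can spare it. Two fMRI routes exist:
task-based mapping (activate language with a task, fit a GLM) and
resting-state mapping (classify each voxel's spontaneous-fluctuation
correlation pattern into resting-state networks). This package implements
both routes and the group-level machinery for comparing them —
distribution matching, inter-subject consistency (SNR) maps, and ROC/AUC
against a priori regions with a paired DeLong test — driven entirely by a
synthetic cohort generator with planted ground truth.

## Generative model of the synthetic cohort

A subject's voxel time series is a linear mixture

    y_v(t) = B + Σ_k w_kv · a_k · s_k(t) + A_v · x(t) + σ · ε_v(t)

- `B = 100` — scanner baseline (arbitrary units); amplitudes quoted in
  percent are percent of `B`.
- `s_k` — per-network time courses: white Gaussian noise smoothed by a
  5-frame moving average (the simplest process with BOLD-like temporal
  autocorrelation), standardized to unit variance, independent across
  networks and subjects, shared by all voxels of a subject-run.
- `w_kv` — network topographies: isotropic Gaussian blobs (σ = 1.8 voxels
  of 3 mm), peak weight exactly 1 at each focus, truncated to 0 below
  weight 0.05 so each network has compact support and most of the brain
  belongs to no network. The language network has two left-hemisphere foci
  (anterior "Broca-like", posterior "Wernicke-like") at least 6 voxels
  apart plus homotopic right-hemisphere mirrors at ⅓ weight, which puts
  ≈ 75 % of its mass in the left hemisphere. The six other networks
  (attention-, salience-like, motor, visual, control, default-mode
  stand-ins) have one focus with a full-weight mirror — hemispherically
  symmetric, as non-language networks typically are.
- `a_k` — per-subject network gains, Normal(1, 0.3) truncated at 0.
- `A_v · x(t)` — task runs only: `x` is the 10-frame off/on boxcar (5
  cycles, 100 frames, TR 2.2 s) convolved with the canonical double-gamma
  HRF and scaled to unit peak. `A_v` loads the expressive amplitude on the
  Broca-like focus blob, the receptive amplitude on the Wernicke-like blob,
  and the salience/attention amplitudes on those two networks' weight maps,
  in each case restricted to the region core (membership ≥ 0.5): evoked
  responses are focal, not coextensive with a network's whole correlational
  footprint. Default population means (percent units, Normal, sd 0.3,
  truncated at 0): expressive 1.0, receptive 0.0, salience 1.0,
  attention 1.0 — an expressive task that recruits task-general systems
  but not the receptive language focus.
- `σ = 0.8` — white voxel noise, giving within-network rest correlations
  around 0.4–0.6, a realistic operating point for the classifier.

Geometry: 16³ grid of 3 mm voxels, ellipsoidal brain mask (90 % of each
half-extent, ≈ 1 570 voxels), hemispheres split at the grid midline with
"left" = lower indices. Acquisition mirrors a clinical protocol: two
160-frame rest runs and one 100-frame task run at TR 2.2 s.

All randomness flows from a master seed through named per-stage streams
(SHA-256 of `(master_seed, stage, subject)`, reduced below 2³¹), so
cohorts, training and full pipeline runs are bitwise reproducible.

## Resting-state route

Every in-mask voxel is treated as a seed: its Pearson correlation with
every other in-mask voxel over the (portion of) rest data, Fisher
z-transformed with |r| clipped at 1 − 10⁻⁷, z-scored per map, is the input
to a one-hidden-layer perceptron (default 20 logistic hidden units) with
**independent logistic outputs** — one likelihood in [0, 1] per network
class, deliberately not a softmax simplex. Training inputs are correlation
maps seeded at high-membership voxels (weight ≥ 0.7) of each planted
network, 3 seeds per network per subject by default (the count is
configurable; 169 seed ROIs can be matched if desired), labels are the
seeds' networks, and fitting is full-batch gradient descent on mean binary
cross-entropy (learning rate 1.0, 500 epochs) from a seeded Glorot-style
initialization. The language channel of the classified map is
rank-uniformized over the brain — the probability integral transform
`u = (midrank − ½)/N` — making its in-mask distribution uniform on (0, 1).

The rest data are split into 3 contiguous equal portions (⌊320/3⌋ = 106
frames each, remainder discarded) to match the task run's acquisition time;
classification runs per portion.

## Task route

Voxelwise OLS on [task regressor, constant, linear drift]. The task
regressor has unit peak, so `percent = 100 · β_task / β_constant`; t
statistics use the residual variance with n − 3 df. Voxels with
non-positive baseline are flagged and carry no percent value. Activation
maps (not time series) are smoothed with a mask-normalized isotropic
Gaussian, FWHM 6 mm, then masked to the brain.

## Group comparison

Per-subject maps of both modalities are uniformized (the rest maps already
are, by construction; task maps are uniformized per subject) before SNR, so
"SNR was computed identically on distribution-matched data" has a
well-defined meaning at the subject level: SNR = voxelwise mean / sd
(n − 1) across subjects, with sd < 10⁻⁸ flagged to 0 (guards division
without masking real voxels). Rest SNR is computed per portion and
averaged over unflagged portions; a voxel flagged in all portions stays
flagged. For display, concordance and ROC, the *group-mean* maps are
matched to a common uniform distribution, the concordance map is their
product thresholded at 0.7, and ROC/AUC is computed per ROI with the
left-hemisphere non-language brain as negatives. Both a voxel-count ROC
(default; each voxel counts once) and a magnitude-weighted ROC (each voxel
contributes its response magnitude) are implemented, since either reading
of "above-threshold response magnitude summed over the ROI" is defensible;
the mode is recorded in every output. Voxel-count trapezoid AUC over the
exact step curve equals the Mann–Whitney statistic with ½ for ties, which
the tests verify against an exhaustive pairwise oracle. The paired DeLong
test uses midrank structural components (O(n log n)), a two-sided normal p
without continuity correction, and floors p at the smallest normal double
so p ∈ (0, 1] even when the tail underflows.

ROIs derive from the planted language network: the connected components of
its weight map thresholded at 0.5 containing each focus (restricted to the
left hemisphere and brain mask) are the Broca-like and Wernicke-like ROIs;
their volumes agree within a factor of two by construction.

## Cohort table

Clinical tables arrive as one-row-per-lesion TSV. Summaries follow
case-series conventions: age sd with the n − 1 denominator (the n
denominator contradicts the packaged table's printed-style values), tumor
volume statistics over per-patient lesion totals, handedness rates over
patients with handedness recorded, and "bilateral (left>right)" lesions
counted as left-hemisphere-involving. Reported means are rounded half-up
to one decimal; raw values are retained.

## Numerical and design choices

- Fisher z clipping at |r| = 1 − 10⁻⁷ keeps self-seed correlations finite;
  time series are promoted to float64 so self-correlation hits 1 exactly.
- Midrank PIT `(midrank − ½)/N`: symmetric, tie-stable, strictly inside
  (0, 1), idempotent up to tie handling.
- Portion splitting is temporally contiguous (emulates shorter
  acquisitions), not interleaved.
- The language-focus separation is at least `2⌊σ√(2 ln 2)⌋ + 2` voxels so
  the two half-max components are disjoint on the integer lattice; foci sit
  far enough from the midline that components stay in the left hemisphere.
- Threshold grids for ROC are the unique observed scores plus ±∞
  sentinels: exact step curves, no binning.
- Per-subject topographic variability is available as a focus-jitter
  parameter (rounded isotropic normal shifts of each focus, default 0 —
  off); a priori ROIs always come from the shared unjittered atlas, as a
  priori ROIs would in practice.
- The CLI `train-mlp` subcommand reconstructs the generating atlas from the
  simulation seed, since serialized cohorts carry runs and masks but seeds
  for training must come from the truth topographies.

## Problem sizes

Default analyses use a 16³ grid and cohorts of 10 subjects (35 for the
cohort-table statistics, which are data, not simulation); the directional
rest-vs-task claims are evaluated over 10–20 independent cohort seeds.
These sizes put every quantity the package reports within a few minutes of
a single CPU while leaving all group-level effects far from marginal.

## What the synthetic setting does and does not show

Passing tests establish that the implementation is internally correct and
that, *under the generative model*, the classifier recovers planted
topography (group-mean language AUC > 0.8 on 10 subjects; in practice
≈ 0.99) and the expected asymmetry appears: an expressive-only task yields
high AUC in the Broca-like ROI but unstable, usually near-or-below-chance
AUC and low SNR in the Wernicke-like ROI, while the rest route scores high
on both. One behaviour worth naming: because the unmodeled language-network
fluctuations are temporally coherent across the whole network, their
projection onto the task regressor shifts the entire Wernicke-like ROI up
or down together in any finite cohort, so the task-route Wernicke AUC is
strongly bimodal across cohorts — this inconsistency is itself the
phenomenon the SNR comparison quantifies.

The generator omits head motion, physiological noise, susceptibility
artifacts, lesion mass effects, scanner differences, surface geometry and
registration error. Absolute AUC/SNR values here therefore say nothing
about clinical performance; only the *relative* behaviour of the two
routes under controlled conditions — and the exact arithmetic of the
statistical machinery — carries over.
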