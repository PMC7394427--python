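"""Train the network classifier and map one subject's language likelihood.

Correlation maps seeded at high-membership voxels of each planted network
form the training set; the trained perceptron is then applied to every
in-brain voxel of a held-out-style subject and its language channel is
rank-uniformized.
"""

import numpy as np

import langmap as lm
from langmap import connectivity as cn

grid = lm.GridSpec()
mask = grid.brain_mask()
cohort = lm.make_cohort(5, master_seed=3, grid=grid)
atlas = cohort[0].truth_atlas

ts = cn.build_training_set(cohort, atlas, seeds_per_network=3, mask=mask, seed=11)
print(f"training set: {ts.inputs.shape[0]} correlation maps "
      f"({ts.n_seed_rois} seed ROIs x {len(cohort)} subjects), "
      f"{ts.inputs.shape[1]} voxels each")

model = cn.train_mlp(ts, hidden_units=20, seed=5)
print(f"cross-entropy loss: {model.loss_history[0]:.3f} -> "
      f"{model.loss_history[-1]:.3f} after training")

lik = cn.classify_voxelwise(cohort[0].rest_runs, model, mask)
lan_map = lik.language_volume()  # uniformized over the brain

truth = atlas[0].weight_map >= 0.5
inside = np.nanmedian(lan_map[truth & mask])
outside = np.nanmedian(lan_map[~truth & mask])
print(f"median language likelihood inside planted network: {inside:.2f}, "
      f"outside: {outside:.2f}")
# A large inside-outside gap means the classifier recovered the planted
# language topography from rest data alone.
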