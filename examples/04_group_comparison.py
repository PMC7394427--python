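"""Full group-level rest-vs-task comparison on one simulated cohort.

Runs the end-to-end pipeline (simulate -> classify -> GLM -> distribution
matching -> SNR -> ROC/DeLong) and prints the headline numbers.
"""

import langmap as lm

result = lm.run_pipeline(lm.RunConfig(n_subjects=10, master_seed=1))

for roi in ("broca", "wernicke"):
    r = result.roc_results[roi]
    print(f"{roi:9s} AUC  rest={r['auc_rs']:.3f}  task={r['auc_task']:.3f}  "
          f"DeLong z={r['delong_z']:+.1f}  p={r['delong_p']:.2e}")
for roi in ("broca", "wernicke"):
    s = result.snr_summary[roi]
    print(f"{roi:9s} mean SNR  rest={s['rs']:.1f}  task={s['task']:.1f}")

n_concordant = int((result.concordance > 0).sum())
print(f"concordance map: {n_concordant} voxels above the 0.7 product threshold")
# Rest-based mapping matches the planted language ROIs in both foci; the
# expressive-only task matches Broca but misses Wernicke, and its response
# there is far less consistent across subjects (lower SNR).
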