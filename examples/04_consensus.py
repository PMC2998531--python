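"""Median-rank consensus, per-method contribution, and best-subset selection.

Combines several predictors of varying quality on one synthetic
dataset.  The leave-one-out table shows what each member contributes;
a member that points the wrong way hurts the consensus, and the
best-subset consensus that drops it beats the naive all-methods one.
"""

import numpy as np

import corescan as cs

world = cs.SyntheticWorld(seed=42)
dataset = cs.simulate_dataset(world, 500)
labels = dataset.labels
rng = np.random.default_rng(0)

truth_scores = np.array(
    [cs.predict_peptide(world.truth, s).score for s in dataset.sequences]
)
log_truth = np.log(truth_scores)
methods = [
    cs.MethodScores("sharp", log_truth + rng.normal(0, 0.5, len(dataset))),
    cs.MethodScores("good", log_truth + rng.normal(0, 1.0, len(dataset))),
    cs.MethodScores("okay", log_truth + rng.normal(0, 2.0, len(dataset))),
    cs.MethodScores("noisy", log_truth + rng.normal(0, 4.0, len(dataset))),
    cs.MethodScores("backwards", -log_truth + rng.normal(0, 1.0, len(dataset))),
]

print("leave-one-out consensus AUC:")
print(cs.leave_one_out_consensus(methods, labels).to_string(index=False))

all5 = cs.median_rank_consensus(methods)
best3 = cs.subset_consensus(methods, ["sharp", "good", "okay"], ["noisy"])
print(f"\nconsensus of all 5 methods: AUC {cs.roc_auc(all5, labels).auc:.3f}")
print(f"consensus of best 3:        AUC {cs.roc_auc(best3, labels).auc:.3f}")
# removing the misleading member ('backwards') raises the consensus AUC:
# a bigger committee is not automatically a better one
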