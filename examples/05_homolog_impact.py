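"""Does training with homologous peptides hurt prediction of unrelated ones?

Cross-validates the trainable predictor on the full dataset (ALL) and
on its similarity-reduced subset (SR), then compares the blinded
predictions of the singular peptides (SP) — those with no similar
partner anywhere — under the two training regimes.
"""

import corescan as cs

world = cs.SyntheticWorld(seed=42)
dataset = cs.simulate_dataset(world, 1000)

result = cs.sp_impact_analysis(cs.BaselineTrainer(), dataset, k=5, seed=42)
print(result.table.to_string(index=False))
# auc_reduction = auc_all - auc_sr on the SP peptides: positive means the
# homolog-inclusive training set predicted unrelated peptides *better*,
# i.e. keeping homologs in the training data did not hurt generalization.
# peptide_reduction counts how many of the ALL peptides are not singular.
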