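"""Two-step differential testing with corrected p-values.

Simulates 5 000 features on the unbalanced design — 10% carry random batch
effects, and 250 carry a true group difference — then runs the two-step
pipeline (covariate-preserving adjustment + one-way F test) and compares
discovery counts at 5% FDR under the naive and corrected reference laws.
"""

import numpy as np

import batchaudit as ba

design = ba.design_from_counts([[3, 15], [15, 3]], groups=("A", "B"))
n_features, n_true = 5_000, 250

config = ba.SimulationConfig(
    design=design, n_features=n_features, batch_effect_fraction=0.1, seed=1
)
Y, annotation, truth = ba.simulate_dataset(config)
# add a real group difference to the first 250 features
effect = np.zeros((n_features, design.M))
effect[:n_true, 1] = 1.5
values = Y.values + effect[:, design.group_index]
Y = ba.ExpressionMatrix(values, Y.feature_ids, Y.sample_ids)

table = ba.two_step_test(Y, design, method="anova")
is_true = np.arange(n_features) < n_true
for col in ("q_naive", "q_corrected"):
    hits = table[col] < 0.05
    tp = int((hits & is_true).sum())
    fp = int((hits & ~is_true).sum())
    print(f"{col:<13} discoveries at 5% FDR: {int(hits.sum()):4d}  (true: {tp}, false: {fp})")

print()
print("Naive q-values admit a wave of false positives on this unbalanced")
print("design; the corrected reference law keeps the false discoveries near")
print("the nominal rate while retaining most true effects.")
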