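"""Find and filter correlated features, then reintroduce them.

Extracts features from simulated transcripts, removes one member of
every pair with |Pearson rho| > 0.8, retrains on the reduced set, and
adds the removed features back one at a time, printing the accuracy
trajectory.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from plantlnc import (
    Hyperparameters,
    redundancy_filter,
    reintroduction_experiment,
    simulate_dataset,
)

ds = simulate_dataset(200, 200, seed=9, length_range=(200, 500),
                      fold_backend="builtin")
idx = np.arange(len(ds))
tr, te = train_test_split(idx, test_size=0.3, stratify=ds.y, random_state=0)
train_ds, test_ds = ds.subset_rows(tr), ds.subset_rows(te)

report = redundancy_filter(train_ds.X, train_ds.feature_names,
                           threshold=0.8, seed=0)
print(f"retained {len(report.retained)} features, "
      f"{len(report.redundant)} flagged redundant at |rho| > 0.8")

hp = Hyperparameters(n_estimators=100, max_depth=5)
table = reintroduction_experiment(train_ds, test_ds, report.redundant,
                                  hp, seed=0)
print(table[["step", "added_feature", "n_features", "ACC", "F1"]]
      .round(3).to_string(index=False))

# The baseline row is the reduced feature set; each later row adds one
# redundant feature back. Accuracy stays nearly flat: the gradient-
# boosted trees are robust to correlated features, so filtering them
# mostly trades dimensionality for a negligible accuracy change.
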