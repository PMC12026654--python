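"""Balance an imbalanced dataset with SMOTE.

Builds a 4000-majority / 2000-minority feature dataset, balances it to
4000/4000 and verifies one synthetic row is an interpolation between
two real minority rows.
"""

import numpy as np

from plantlnc import LabeledDataset, smote_balance

rng = np.random.default_rng(0)
X = np.vstack([rng.normal(0, 1, (4000, 100)), rng.normal(1, 1, (2000, 100))])
y = np.array([0] * 4000 + [1] * 2000)
ds = LabeledDataset(X, y, [f"r{i}" for i in range(6000)],
                    [f"f{j}" for j in range(100)])

print("before:", ds.class_counts)
balanced, provenance = smote_balance(ds, k=5, seed=1, return_provenance=True)
print("after: ", balanced.class_counts)

p = provenance[0]
print(f"first synthetic row: base minority row {p.base}, "
      f"neighbor {p.neighbor}, interpolation weight u={p.u:.3f}")

# Each synthetic row is x_base + u * (x_neighbor - x_base): a point on
# the segment between a minority row and one of its 5 nearest minority
# neighbors, so the oversampled class stays inside its own feature
# region instead of duplicating rows.
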