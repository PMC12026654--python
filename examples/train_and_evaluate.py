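"""Train the gradient-boosted classifier end to end and score it.

Simulates 200 + 200 transcripts, splits 70/30 (stratified), trains with
the tuned default hyperparameters and prints the held-out evaluation
report plus the most frequently used features.
"""

import numpy as np
from sklearn.model_selection import train_test_split

from plantlnc import (
    evaluate_model,
    feature_importance,
    simulate_dataset,
    train,
)

ds = simulate_dataset(200, 200, seed=5, length_range=(200, 500),
                      fold_backend="builtin")
idx = np.arange(len(ds))
tr, te = train_test_split(idx, test_size=0.3, stratify=ds.y, random_state=0)

bundle = train(ds.subset_rows(tr), seed=0)
report = evaluate_model(bundle, ds.subset_rows(te))

print(f"test accuracy    {report.ACC:.2f}%")
print(f"sensitivity      {report.SN:.2f}%   (lncRNA recall)")
print(f"specificity      {report.SP:.2f}%   (mRNA recall)")
print(f"F1               {report.F1:.4f}")
print(f"MCC              {report.MCC:.4f}")
print(f"AUC              {report.AUC:.4f}")
print()
print("top 5 features by split frequency:")
for name, weight in feature_importance(bundle, top_n=5):
    print(f"  {name:15s} {weight:.0f}")

# Accuracy near 100% reflects the simulated classes' deliberate
# separability (ORF content); the importance ranking shows the model
# discovering exactly those ORF-derived features.
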