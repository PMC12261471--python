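"""Random versus cold evaluation splits.

Builds a small labelled pair table and shows the three cold protocols:
held-out entities send ALL of their interactions to the test set, so the
model must generalize to drugs/targets it has never seen in training.
"""

import numpy as np
import pandas as pd

from topolink import cold_split, random_split

rng = np.random.default_rng(0)
pairs = pd.DataFrame(
    [(f"d{i}", f"t{j}", int(rng.random() < 0.5))
     for i in range(12) for j in range(10)],
    columns=["drug_id", "target_id", "label"])
print(f"{len(pairs)} labelled pairs, {pairs.drug_id.nunique()} drugs, "
      f"{pairs.target_id.nunique()} targets")

split = random_split(pairs, (0.7, 0.1, 0.2), seed=0)
print("\nrandom split sizes:",
      {k: len(v) for k, v in split.items()})

for mode, col in [("unseen_drugs", "drug_id"), ("unseen_targets", "target_id")]:
    split = cold_split(pairs, mode, holdout_fraction=0.2, seed=1)
    held = sorted(set(split["test"][col]))
    overlap = set(split["test"][col]) & (set(split["train"][col])
                                         | set(split["val"][col]))
    print(f"\n{mode}: held-out {col}s = {held}")
    print(f"  sizes: train {len(split['train'])}, val {len(split['val'])}, "
          f"test {len(split['test'])}; entity overlap with training: {len(overlap)}")

split = cold_split(pairs, "cold_both", holdout_fraction=0.2, seed=2)
train_d, train_t = set(split["train"].drug_id), set(split["train"].target_id)
leaks = sum(d in train_d and t in train_t
            for d, t in zip(split["test"].drug_id, split["test"].target_id))
print(f"\ncold_both: test pairs whose both endpoints were seen in training: {leaks}")
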