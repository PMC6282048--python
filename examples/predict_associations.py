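"""Predicting hidden miRNA-disease associations.

We hide 15% of the known associations of the standard planted-block
dataset, run the full predictor on the masked matrix, and check where the
hidden pairs land in the ranking of all candidate (unknown) pairs.
"""

import numpy as np

from llcmda import mask_associations, predict, standard_fixture

assoc, fms, dss, _ = standard_fixture()
masked, hidden = mask_associations(assoc, 0.15, seed=5)
print(f"{assoc.n_known} known associations, {len(hidden)} hidden for the test")

scores = predict(masked, fms, dss)

# rank every pair that is unknown in the MASKED matrix (hidden pairs + true
# negatives); a good predictor pushes the hidden pairs toward the top
long = scores.to_long()
known_in_masked = {
    (masked.mirna_ids[i], masked.disease_ids[j]) for i, j in masked.known_pairs()
}
candidates = long[~long.apply(
    lambda r: (r.mirna_id, r.disease_id) in known_in_masked, axis=1
)].reset_index(drop=True)
ranks = [
    int(candidates.index[
        (candidates.mirna_id == m) & (candidates.disease_id == d)
    ][0]) + 1
    for m, d in hidden
]
print(f"candidate pool size: {len(candidates)}")
print(f"median rank of the {len(hidden)} hidden pairs: {int(np.median(ranks))}")
print(f"hidden pairs in the top 30 candidates: {sum(r <= 30 for r in ranks)}")
print("top 5 candidate predictions (mirna, disease, score):")
for _, row in candidates.head(5).iterrows():
    marker = "  <- hidden true pair" if (row.mirna_id, row.disease_id) in set(hidden) else ""
    print(f"  {row.mirna_id:>6} {row.disease_id:>6} {row.score:.4f}{marker}")
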