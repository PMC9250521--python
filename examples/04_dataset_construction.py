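"""Build a labeled dataset the way interaction corpora are constructed:
length filter, balanced random negatives (optionally compartment-disjoint),
then a stratified 5:1 train/test split.
"""

from nvdt import (SyntheticConfig, generate_dataset, filter_short,
                  sample_negatives, split)

cfg = SyntheticConfig(n_pairs=30, seq_len_nt=300, seed=3)
seqs, pairs_ = generate_dataset(cfg)
positives = [p for p in pairs_ if p.label == 1]

kept = filter_short(seqs, min_aa=50)   # CDS >= 150 nt
print(f"{len(kept)}/{len(seqs)} sequences pass the 50-aa length filter")

# balanced negatives: same count as positives, uniform over non-positive
# unordered pairs, reproducible from the seed
negatives = sample_negatives([s.id for s in kept], positives, seed=3)
print(f"sampled {len(negatives)} negatives for {len(positives)} positives")

bundle = split(positives + negatives, seed=3)
n_pos = sum(p.label for p in bundle.test)
print(f"5:1 split -> {len(bundle.train)} train / {len(bundle.test)} test "
      f"({n_pos} positives in test)")
# Train and test never share an unordered pair; the split is stratified so
# both classes appear in the test set.
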