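"""Predict a one-core non-interaction network and export it to Pajek.

A one-core network is a star: one core protein that does not interact
with its satellites.  We plant the star explicitly — the core carries
codon-usage profile 0, true non-partners carry profile 1, and a few true
partners share profile 0 — train on an independently generated dataset
with the same two profiles, predict each edge, and score per-network
accuracy.  Finally 40% of the core's edges (with their curated labels)
are moved into training and the remainder re-scored, emulating newly
measured evidence.
"""

import numpy as np

from nvdt import (SyntheticConfig, generate_dataset, ModelSpec, train,
                  NetworkGraph, predict_network, network_accuracy,
                  augment_and_retrain, export_pajek, ProteinPair,
                  GeneSequence)
from nvdt import features
from nvdt.pairs import pair_feature_matrix, split_xy
from nvdt.synthetic import make_profiles, sample_cds

SEED, LEN = 21, 450
cfg = SyntheticConfig(n_pairs=60, seq_len_nt=LEN, effect=1.0, seed=SEED)
train_seqs, train_pairs = generate_dataset(cfg)

# the star: same two latent profiles, fresh sequences with known roles
rng = np.random.default_rng(SEED)
profiles = make_profiles(2, cfg.concentration, rng)
star_seqs = [GeneSequence("core", sample_cds(profiles[0], LEN, rng=rng))]
edges = []
for i in range(10):  # true non-partners: the other profile
    star_seqs.append(GeneSequence(f"far{i}", sample_cds(profiles[1], LEN, rng=rng)))
    edges.append(ProteinPair("core", f"far{i}", 0))
for i in range(4):   # true partners: share the core's profile
    star_seqs.append(GeneSequence(f"near{i}", sample_cds(profiles[0], LEN, rng=rng)))
    edges.append(ProteinPair("core", f"near{i}", 1))

feats = features.feature_matrix(train_seqs)
X, y = split_xy(pair_feature_matrix(train_pairs, feats))
model = train(X, y, ModelSpec(kind="SVM", seed=SEED))

all_seqs = train_seqs + star_seqs
net = NetworkGraph.from_pairs(edges, core_ids=["core"])
predict_network(model, net, all_seqs)
acc, table = network_accuracy(net)
print(f"one-core network: {int(table['correct'].sum())}/{len(table)} edges "
      f"correct (accuracy {100 * acc:.2f}%)")

_, acc40 = augment_and_retrain(ModelSpec(kind="SVM", seed=SEED), all_seqs,
                               train_pairs, net, fraction=0.4, seed=SEED)
print(f"after moving 40% of core edges into training: accuracy "
      f"{100 * acc40:.2f}% on the remaining edges")

export_pajek(net, "scratch_network.net")
print("wrote Pajek file scratch_network.net "
      "(*Vertices block, then *Edges with a correctness value per edge)")
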