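"""Generate a synthetic benchmark with a planted codon-usage signal and
cross-validate the SVM-NVDT pipeline on it.

Interacting pairs share a latent codon-usage profile; non-interacting
pairs draw two distinct profiles.  With effect=1 the signal is at full
strength and the classifier should recover it almost perfectly; with
effect=0 the two classes are exchangeable and AUC sits near 0.5.
"""

from nvdt import SyntheticConfig, generate_dataset, cross_validate, ModelSpec

for effect in (1.0, 0.0):
    cfg = SyntheticConfig(n_pairs=100, seq_len_nt=450, effect=effect, seed=11)
    seqs, pairs_ = generate_dataset(cfg)
    res = cross_validate(seqs, pairs_, ModelSpec(kind="SVM", seed=11),
                         k=5, seed=11)
    print(f"effect={effect}: {res.summary()}")
# The mean±std lines report five-fold accuracy, precision, sensitivity,
# specificity, MCC and F1 (as %) plus ROC AUC.  Full signal separates
# (acc ~100%); no signal hovers at chance (acc ~50%, AUC ~0.5).
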