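# nvdt

Sequence-based prediction of protein–protein **interactions** (PPIs) and
**non-interactions** (PPNIs) from gene (CDS) sequences, using the
natural-vector representation extended with dinucleotide and
trinucleotide composition (NVDT).

Experimental interaction screens are noisy and expensive, and curated
*non*-interactions are scarcer still; sequence-based classifiers
complement them.  This package works from the coding sequence rather
than the protein: codon-scale composition carries signal (codon-usage
bias) that the amino-acid sequence hides.

## The representation and model

For a CDS `S = s_1 … s_N` over {A, C, G, T}, each nucleotide `k` gets

    n_k   — count
    mu_k  = Σ_i i·[s_i=k] / n_k                  (mean 1-based position)
    D2_k  = Σ_i (i−mu_k)²·[s_i=k] / (n_k·N)      (2nd normalized moment)

which with the 16 dinucleotide and 64 trinucleotide counts forms the
92-dimensional NVDT vector

    N(S) = (n_A…n_T, mu_A…mu_T, D2_A…D2_T, n_AA…n_TT, n_AAA…n_TTT).

A protein pair (A, B) is encoded by one of five schemes — |A−B|, A+B,
(|A−B|, A+B), A∘B, or the default juxtaposition (A, B) of 184 features —
Z-scored with training-set statistics (population σ), and classified by
an RBF-kernel SVM (grid-searched c, γ; Platt-calibrated scores,
cutoff 0.5) or a random forest.  Evaluation reports accuracy, precision,
sensitivity, specificity, MCC, F1 and ROC AUC, with k-fold results as
mean ± std.  Network-level prediction annotates candidate PPNI/PPI
graphs edge-by-edge, supports incremental retraining as evidence
arrives, and exports Pajek files.  A synthetic generator plants a
tunable codon-usage signal so the whole pipeline is testable offline.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

`examples/` holds one short script per capability.  For instance
`examples/03_synthetic_benchmark_cv.py` generates 100 interacting and
100 non-interacting pairs of 450-nt CDS (interacting partners share a
latent codon-usage profile), then five-fold cross-validates SVM on
Cod5-encoded NVDT features:

```
effect=1.0: acc=100.00±0.00% pre=100.00±0.00% sen=100.00±0.00% spe=100.00±0.00% mcc=100.00±0.00% f1=100.00±0.00% auc=1.0000±0.0000
effect=0.0: acc=53.00±9.08% pre=53.10±9.15% sen=54.00±12.94% spe=52.00±12.55% mcc=6.20±18.30% f1=53.17±9.78% auc=0.5625±0.0723
```

At full effect the planted signal is recovered perfectly; with the
signal switched off the classifier sits at chance (AUC ≈ 0.5) — the
null control that the pipeline does not manufacture signal.  And
`examples/01_natural_vectors.py` prints the NVDT vector of the toy CDS
`AATA`: `mu_A = 2.33333` (A at positions 1, 2, 4), `D2_A = 0.38889`,
and single counts for the AA/AT/TA and AAT/ATA windows.

The same pipeline is available as a CLI:

```sh
nvdt simulate --n-pairs 100 --seq-len-nt 450 --effect 1 --seed 7 --outdir sim/
nvdt cross-validate --fasta sim/sequences.fasta --pairs sim/pairs.tsv \
     --classifier SVM --k 5 --seed 7 --out cv.csv
nvdt train --fasta sim/sequences.fasta --pairs sim/pairs.tsv --seed 7 \
     --model-out model.joblib
nvdt predict-network --fasta sim/sequences.fasta --edges edges.tsv \
     --model model.joblib --outdir net/
```

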