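"""Natural-vector features of a gene sequence.

The classic 12-dimensional natural vector of a sequence ``S = s_1 ... s_N``
over {A, C, G, T} collects, per nucleotide ``k``:

* ``n_k``   — the occurrence count,
* ``mu_k``  — the mean 1-based position of ``k`` (0 when ``n_k = 0``),
* ``D2_k``  — the second normalized central moment of the positions,
  ``sum_i (i - mu_k)^2 / (n_k * N)`` over positions carrying ``k``
  (0 when ``n_k = 0``).

The NVDT extension appends the 16 overlapping dinucleotide counts and the
64 overlapping trinucleotide counts (lexicographic order, A < C < G < T),
giving 92 features that are sensitive to codon-scale composition.  Feature
variants:

====== ============================================== ====
name   blocks                                         dim
====== ============================================== ====
NV     counts, means, moments                           12
NVD    NV + dinucleotides                               28
NVT    NV + trinucleotides                              76
NVDT   NV + dinucleotides + trinucleotides              92
====== ============================================== ====

Positions are 1-based (the first nucleotide is the origin).  Non-ACGT
characters (possible under the ``mask`` validation policy) match no
nucleotide: they contribute to ``N`` but to no count, and any k-mer window
touching one is skipped.
"""

from __future__ import annotations

import logging
import warnings
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import GeneSequence

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = ["".join(p) for p in product(NUCLEOTIDES, repeat=2)]
TRINUCLEOTIDES = ["".join(p) for p in product(NUCLEOTIDES, repeat=3)]

VARIANTS = ("NV", "NVD", "NVT", "NVDT")
VARIANT_DIMS = {"NV": 12, "NVD": 28, "NVT": 76, "NVDT": 92}

_BYTE_CODES = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(NUCLEOTIDES.encode()):
    _BYTE_CODES[_b] = _i


def _codes(seq: GeneSequence | str) -> np.ndarray:
    s = seq.seq if isinstance(seq, GeneSequence) else seq
    return _BYTE_CODES[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def nucleotide_counts(seq: GeneSequence) -> np.ndarray:
    """Counts (n_A, n_C, n_G, n_T); sums to N for pure-ACGT sequences."""
    codes = _codes(seq)
    return np.bincount(codes[codes >= 0], minlength=4).astype(np.int64)


def mean_positions(seq: GeneSequence) -> np.ndarray:
    """Mean 1-based position of each nucleotide; 0 for absent nucleotides."""
    codes = _codes(seq)
    pos = np.arange(1, len(codes) + 1, dtype=np.float64)
    out = np.zeros(4)
    for k in range(4):
        mask = codes == k
        if mask.any():
            out[k] = pos[mask].mean()
    return out


def second_central_moments(seq: GeneSequence) -> np.ndarray:
    """Second normalized central moments D2_k; 0 for absent nucleotides.

    D2_k = sum over positions i with s_i = k of (i - mu_k)^2 / (n_k * N),
    with N the full sequence length.
    """
    codes = _codes(seq)
    N = len(codes)
    pos = np.arange(1, N + 1, dtype=np.float64)
    out = np.zeros(4)
    for k in range(4):
        mask = codes == k
        n_k = int(mask.sum())
        if n_k:
            mu = pos[mask].mean()
            out[k] = float(np.square(pos[mask] - mu).sum()) / (n_k * N)
    return out


def kmer_counts(seq: GeneSequence, k: int, normalize: bool = False) -> np.ndarray:
    """Overlapping k-mer counts (stride 1) in lexicographic order, k in {2, 3}.

    Windows containing a non-ACGT character are skipped.  For N < k an
    all-zero vector is returned with a warning.  With ``normalize=True``
    counts are divided by the window count N - k + 1.
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    codes = _codes(seq)
    N = len(codes)
    size = 4 ** k
    if N < k:
        warnings.warn(
            f"sequence {seq.id!r}: length {N} < k={k}; all-zero k-mer vector",
            stacklevel=2,
        )
        return np.zeros(size, dtype=np.float64 if normalize else np.int64)
    if k == 2:
        window = codes[:-1] * 4 + codes[1:]
        valid = (codes[:-1] >= 0) & (codes[1:] >= 0)
    else:
        window = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
        valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    counts = np.bincount(window[valid], minlength=size).astype(np.int64)
    if normalize:
        return counts / (N - k + 1)
    return counts


def feature_names(variant: str = "NVDT") -> list[str]:
    """Ordered feature names for a variant (n_A..D2_T, AA..TT, AAA..TTT)."""
    _check_variant(variant)
    names = (
        [f"n_{b}" for b in NUCLEOTIDES]
        + [f"mu_{b}" for b in NUCLEOTIDES]
        + [f"D2_{b}" for b in NUCLEOTIDES]
    )
    if variant in ("NVD", "NVDT"):
        names += DINUCLEOTIDES
    if variant in ("NVT", "NVDT"):
        names += TRINUCLEOTIDES
    return names


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def natural_vector(seq: GeneSequence, variant: str = "NVDT",
                   kmer_normalize: bool = False) -> np.ndarray:
    """Flattened natural vector of one sequence under a feature variant.

    Component order is fixed: counts, mean positions, D2 moments, then
    (depending on variant) the dinucleotide and trinucleotide blocks.
    """
    _check_variant(variant)
    blocks = [
        nucleotide_counts(seq).astype(np.float64),
        mean_positions(seq),
        second_central_moments(seq),
    ]
    if variant in ("NVD", "NVDT"):
        blocks.append(np.asarray(kmer_counts(seq, 2, normalize=kmer_normalize),
                                 dtype=np.float64))
    if variant in ("NVT", "NVDT"):
        blocks.append(np.asarray(kmer_counts(seq, 3, normalize=kmer_normalize),
                                 dtype=np.float64))
    return np.concatenate(blocks)


def feature_matrix(sequences: Iterable[GeneSequence], variant: str = "NVDT",
                   kmer_normalize: bool = False) -> pd.DataFrame:
    """Natural vectors for many sequences as a DataFrame indexed by id."""
    seqs = list(sequences)
    data = np.vstack([natural_vector(s, variant, kmer_normalize) for s in seqs]) \
        if seqs else np.empty((0, VARIANT_DIMS[variant]))
    df = pd.DataFrame(data, columns=feature_names(variant),
                      index=pd.Index([s.id for s in seqs], name="id"))
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
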