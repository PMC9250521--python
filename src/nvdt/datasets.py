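"""Dataset construction: length and redundancy filters, negative sampling,
train/test splitting and k-fold partitioning.

The construction rules mirror standard practice for interaction datasets
built from curated positive pairs:

* CDS shorter than 3 x 50 nt (proteins under 50 amino acids) are dropped;
* optionally, sequences over 40% pairwise identity to an already-kept one
  are removed greedily (the identity function is pluggable — the built-in
  one is a simple global-alignment stand-in, see :func:`naive_identity`);
* negatives are sampled uniformly at random from non-positive unordered
  pairs, balanced 1:1 with the positives by default, optionally restricted
  to pairs annotated to disjoint subcellular compartments;
* the labeled set splits 5:1 into train/test (stratified by default), and
  k-fold partitions are provided for cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .seqio import GeneSequence, ProteinPair


@dataclass(frozen=True)
class DatasetBundle:
    """A train/test division of labeled pairs."""

    train: list[ProteinPair]
    test: list[ProteinPair]
    seed: int
    ratio: float  # test fraction

    def __post_init__(self) -> None:
        train_keys = {p.key() for p in self.train}
        test_keys = {p.key() for p in self.test}
        if train_keys & test_keys:
            raise ValueError("train and test share pairs (unordered identity)")


def filter_short(sequences: Iterable[GeneSequence], min_aa: int = 50
                 ) -> list[GeneSequence]:
    """Keep CDS of at least ``3 * min_aa`` nucleotides (boundary inclusive)."""
    return [s for s in sequences if s.N >= 3 * min_aa]


def naive_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a basic global alignment.

    Stand-in identity function (match 1, mismatch 0, no gap penalty):
    identities / alignment length on the first optimal alignment.  Intended
    for small inputs and as the default for the pluggable redundancy hook;
    swap in a CD-HIT-style callback for production-size sets.
    """
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1.0, mismatch_score=0.0,
        open_gap_score=0.0, extend_gap_score=0.0,
    )
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    return counts.identities / aln.length if aln.length else 0.0


def filter_redundant(sequences: Sequence[GeneSequence], threshold: float = 0.40,
                     identity_fn: Callable[[str, str], float] = naive_identity
                     ) -> list[GeneSequence]:
    """Greedy redundancy removal in input order.

    A sequence is kept iff its identity to every already-kept sequence is
    at most ``threshold``.
    """
    kept: list[GeneSequence] = []
    for s in sequences:
        if all(identity_fn(s.seq, k.seq) <= threshold for k in kept):
            kept.append(s)
    return kept


def _compartments(value) -> frozenset:
    if isinstance(value, str):
        return frozenset([value])
    return frozenset(value)


def candidate_negative_pairs(protein_ids: Sequence[str],
                             positives: Iterable[ProteinPair],
                             localization: Optional[Mapping[str, object]] = None,
                             allow_self: bool = False) -> list[tuple[str, str]]:
    """Enumerate, in sorted order, every unordered pair eligible as a negative."""
    ids = sorted(set(protein_ids))
    pos_keys = {p.key() for p in positives}
    out: list[tuple[str, str]] = []
    iterator = (
        itertools.combinations_with_replacement(ids, 2) if allow_self
        else itertools.combinations(ids, 2)
    )
    for a, b in iterator:
        if (a, b) in pos_keys:
            continue
        if localization is not None:
            ca = _compartments(localization.get(a, ()))
            cb = _compartments(localization.get(b, ()))
            # unknown localization is treated as potentially shared
            if not ca or not cb or (ca & cb):
                continue
        out.append((a, b))
    return out


def sample_negatives(protein_ids: Sequence[str], positives: list[ProteinPair],
                     n: Optional[int] = None, seed: int = 0,
                     localization: Optional[Mapping[str, object]] = None,
                     allow_self: bool = False) -> list[ProteinPair]:
    """Uniform random non-positive unordered pairs, labeled 0.

    ``n`` defaults to ``len(positives)`` (a balanced dataset).  With a
    localization map only compartment-disjoint pairs are eligible.  The
    draw is without replacement and fully determined by ``seed``.
    """
    candidates = candidate_negative_pairs(protein_ids, positives,
                                          localization, allow_self)
    if n is None:
        n = len(positives)
    if n > len(candidates):
        raise ValueError(
            f"requested {n} negative pairs but only {len(candidates)} "
            f"candidates are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [ProteinPair(*candidates[i], label=0) for i in sorted(idx)]


def _require_labels(pairs: Sequence[ProteinPair]) -> None:
    if any(p.label is None for p in pairs):
        raise ValueError("all pairs must carry a 0/1 label")


def split(pairs: Sequence[ProteinPair], seed: int = 0,
          test_fraction: float = 1 / 6, stratified: bool = True) -> DatasetBundle:
    """Shuffled train/test split; the default test fraction 1/6 gives 5:1.

    Test counts are rounded to the nearest integer; under stratification
    each class contributes at least one test pair and must have at least
    two members.
    """
    _require_labels(pairs)
    rng = np.random.default_rng(seed)
    pairs = list(pairs)
    test: list[ProteinPair] = []
    train: list[ProteinPair] = []
    if stratified:
        for label in (0, 1):
            cls = [p for p in pairs if p.label == label]
            if len(cls) < 2:
                raise ValueError(
                    f"stratified split needs >= 2 pairs per class; class {label} "
                    f"has {len(cls)}"
                )
            order = rng.permutation(len(cls))
            n_test = max(1, round(len(cls) * test_fraction))
            test += [cls[i] for i in order[:n_test]]
            train += [cls[i] for i in order[n_test:]]
    else:
        order = rng.permutation(len(pairs))
        n_test = round(len(pairs) * test_fraction)
        test = [pairs[i] for i in order[:n_test]]
        train = [pairs[i] for i in order[n_test:]]
    return DatasetBundle(train=train, test=test, seed=seed, ratio=test_fraction)


def kfold(pairs: Sequence[ProteinPair], k: int = 5, seed: int = 0,
          stratified: bool = True) -> list[list[ProteinPair]]:
    """Partition pairs into k folds whose sizes differ by at most one.

    Stratification assigns each class's shuffled members round-robin with a
    running fold counter, so the overall size balance holds even when every
    class count has a remainder.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the number of pairs ({len(pairs)})")
    rng = np.random.default_rng(seed)
    folds: list[list[ProteinPair]] = [[] for _ in range(k)]
    if stratified:
        _require_labels(pairs)
        counter = 0
        for label in (1, 0):
            cls = [p for p in pairs if p.label == label]
            for i in rng.permutation(len(cls)):
                folds[counter % k].append(cls[i])
                counter += 1
    else:
        for counter, i in enumerate(rng.permutation(len(pairs))):
            folds[counter % k].append(pairs[i])
    return folds


def write_manifest(bundle: DatasetBundle, path: str | Path) -> None:
    """Dataset manifest as TSV: id_a, id_b, label, split."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\tsplit\n")
        for name, part in (("train", bundle.train), ("test", bundle.test)):
            for p in part:
                fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\t{name}\n")


def read_manifest(path: str | Path) -> DatasetBundle:
    train: list[ProteinPair] = []
    test: list[ProteinPair] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            id_a, id_b, label, part = line.rstrip("\n").split("\t")
            p = ProteinPair(id_a, id_b, int(label))
            (train if part == "train" else test).append(p)
    n = len(train) + len(test)
    return DatasetBundle(train=train, test=test, seed=-1,
                         ratio=len(test) / n if n else 0.0)
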