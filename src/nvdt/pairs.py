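"""Combine two per-protein natural vectors into one pair feature.

Five schemes are supported for partner vectors ``A`` and ``B``:

* ``Cod1`` — elementwise absolute difference ``|A - B|``
* ``Cod2`` — elementwise sum ``A + B``
* ``Cod3`` — concatenation of Cod1 and Cod2
* ``Cod4`` — elementwise product ``A * B``
* ``Cod5`` — juxtaposition ``(A, B)`` (default; the strongest in practice)

Cod1/Cod2/Cod4 are symmetric in the partners; Cod5 depends on their order,
so pairs are canonicalised (lexicographic id order) before encoding to make
features reproducible.  An optional training-time augmentation adds both
orders of each Cod5 pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import ProteinPair

SCHEMES = ("Cod1", "Cod2", "Cod3", "Cod4", "Cod5")
#: dimension multiplier relative to the per-protein vector
SCHEME_MULTIPLIER = {"Cod1": 1, "Cod2": 1, "Cod3": 2, "Cod4": 1, "Cod5": 2}


@dataclass(frozen=True)
class PairFeature:
    """An encoded protein pair: scheme plus the feature vector."""

    pair: ProteinPair
    scheme: str
    vector: np.ndarray

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def _check_scheme(scheme: str) -> None:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def encode_pair(nv_a: np.ndarray, nv_b: np.ndarray, scheme: str = "Cod5") -> np.ndarray:
    """Encode two equal-length natural vectors under one scheme."""
    _check_scheme(scheme)
    a = np.asarray(nv_a, dtype=np.float64)
    b = np.asarray(nv_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(
            f"partner vectors must share a variant/dimension, got {a.shape} vs {b.shape}"
        )
    if scheme == "Cod1":
        return np.abs(a - b)
    if scheme == "Cod2":
        return a + b
    if scheme == "Cod3":
        return np.concatenate([np.abs(a - b), a + b])
    if scheme == "Cod4":
        return a * b
    return np.concatenate([a, b])


def canonical_order(pair: ProteinPair) -> tuple[str, str]:
    """Deterministic (lexicographic) partner order for order-sensitive schemes."""
    return pair.key()


def pair_feature_columns(dim: int) -> list[str]:
    return [f"f{i}" for i in range(1, dim + 1)]


def pair_feature_matrix(pairs: list[ProteinPair], features: pd.DataFrame,
                        scheme: str = "Cod5",
                        augment_orders: bool = False) -> pd.DataFrame:
    """Encode many pairs against a per-sequence feature matrix.

    Returns a DataFrame with columns ``id_a``, ``id_b``, ``label`` and
    ``f1..fD``.  Partners are taken in canonical order; with
    ``augment_orders=True`` (intended for training data only) the reversed
    order of every pair is appended as an extra row — a no-op for the
    symmetric schemes but doubles the Cod5 rows.
    """
    _check_scheme(scheme)
    rows = []
    meta = []
    for p in pairs:
        a, b = canonical_order(p)
        for id_a, id_b in ([(a, b), (b, a)] if augment_orders and a != b else [(a, b)]):
            try:
                nv_a = features.loc[id_a].to_numpy()
                nv_b = features.loc[id_b].to_numpy()
            except KeyError as exc:
                raise KeyError(f"pair ({p.id_a}, {p.id_b}): no features for id {exc}") from exc
            rows.append(encode_pair(nv_a, nv_b, scheme))
            meta.append((id_a, id_b, p.label))
    dim = features.shape[1] * SCHEME_MULTIPLIER[scheme]
    data = np.vstack(rows) if rows else np.empty((0, dim))
    out = pd.DataFrame(data, columns=pair_feature_columns(data.shape[1]))
    out.insert(0, "id_a", [m[0] for m in meta])
    out.insert(1, "id_b", [m[1] for m in meta])
    out.insert(2, "label", [m[2] for m in meta])
    return out


def split_xy(pair_matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Feature block and label vector of an encoded pair matrix."""
    fcols = [c for c in pair_matrix.columns if c.startswith("f")]
    X = pair_matrix[fcols].to_numpy(dtype=np.float64)
    if pair_matrix["label"].isna().any():
        raise ValueError("pair matrix contains unlabeled rows")
    y = pair_matrix["label"].to_numpy(dtype=np.int64)
    return X, y
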