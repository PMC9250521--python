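"""Z-score standardization of pair-feature matrices.

Statistics are fitted on the training pairs only — per feature ``l`` the
mean ``mu(l)`` and the *population* (1/n) standard deviation ``sigma(l)`` —
and the same state transforms any later matrix:

    d'(l) = (d(l) - mu(l)) / sigma(l)

Zero-variance features (possible for rare k-mers in small sets) transform
to 0 and are flagged rather than raising.  The fitted state serialises to
JSON for reuse at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


@dataclass
class Standardizer:
    """Per-feature Z-score state fitted on training data."""

    means: Optional[np.ndarray] = None
    stds: Optional[np.ndarray] = None
    n_fit: int = 0
    feature_names: Optional[list[str]] = None
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def is_fitted(self) -> bool:
        return self.means is not None

    def fit(self, X: np.ndarray, feature_names: Optional[Sequence[str]] = None
            ) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("fit requires a 2-D matrix with at least one row")
        self.means = X.mean(axis=0)
        self.stds = X.std(axis=0, ddof=0)  # population definition
        self.zero_variance = self.stds == 0.0
        self.n_fit = X.shape[0]
        self.feature_names = list(feature_names) if feature_names is not None else None
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise ValueError("standardizer is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.means.shape[0]:
            raise ValueError(
                f"dimension mismatch: state has {self.means.shape[0]} features, "
                f"matrix has {X.shape[1] if X.ndim == 2 else 'ndim!=2'}"
            )
        denom = np.where(self.zero_variance, 1.0, self.stds)
        out = (X - self.means) / denom
        out[:, self.zero_variance] = 0.0
        return out

    def fit_transform(self, X: np.ndarray,
                      feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
        return self.fit(X, feature_names).transform(X)

    # -- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "n_fit": self.n_fit,
            "feature_names": self.feature_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.means = np.asarray(d["means"], dtype=np.float64)
        s.stds = np.asarray(d["stds"], dtype=np.float64)
        s.zero_variance = s.stds == 0.0
        s.n_fit = int(d["n_fit"])
        s.feature_names = d.get("feature_names")
        return s

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Standardizer":
        return cls.from_dict(json.loads(Path(path).read_text()))
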