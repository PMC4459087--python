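"""Pairwise distance matrices (percent) and their combination across loci."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of observed pairwise distances in percent (0-100)."""

    labels: tuple
    values: np.ndarray
    locus: str = ""

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("distances must lie in [0, 100] percent")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.locus)

    @staticmethod
    def weighted_mean(
        mats: Sequence["DistanceMatrix"], weights: Sequence[float] | None = None
    ) -> "DistanceMatrix":
        """Weight-averaged distances across loci sharing the same taxa.

        With weights proportional to locus lengths this is equivalent to the
        p-distance of the concatenated alignment.
        """
        if not mats:
            raise ValueError("no distance matrices to combine")
        labels = mats[0].labels
        if weights is None:
            weights = np.ones(len(mats))
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(mats):
            raise ValueError("one weight per matrix required")
        acc = np.zeros_like(mats[0].values)
        for m, w in zip(mats, weights):
            if m.labels != labels:
                m = m.subset(labels)
            acc += w * m.values
        return DistanceMatrix(labels, acc / weights.sum(), locus="combined")
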