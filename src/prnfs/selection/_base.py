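"""Shared feature-selection types and ranking conventions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["FeatureSet", "rank_order", "top_k"]


@dataclass
class FeatureSet:
    """An ordered feature selection with per-feature scores.

    ``scores`` are non-increasing; ties are broken lexicographically by
    feature id (stable everywhere in the package, so outputs are
    bit-reproducible).
    """

    features: list[str]
    scores: list[float]
    algorithm: str
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.scores):
            raise ValueError("features and scores differ in length")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in FeatureSet")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.features)


def rank_order(ids: Sequence[str], scores: np.ndarray) -> list[int]:
    """Indices ordering features by score desc, feature id asc on ties."""
    return sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))


def top_k(
    ids: Sequence[str], scores: np.ndarray, k: int, algorithm: str, **context
) -> FeatureSet:
    """Top-``k`` FeatureSet under the package ranking convention."""
    order = rank_order(ids, np.asarray(scores, dtype=float))[: max(k, 0)]
    return FeatureSet(
        features=[ids[i] for i in order],
        scores=[float(scores[i]) for i in order],
        algorithm=algorithm,
        context=context,
    )
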