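"""Prognostic association-rule mining.

Signature features are discretized to high/low at their per-feature mean;
each labeled sample becomes one transaction holding one state item per
feature plus its prognosis class item.  Apriori enumerates frequent
feature itemsets levelwise (support anti-monotonicity prunes candidates)
and emits rules X => {class} meeting the support and confidence floors.

Metrics follow the classical definitions: support(X) is the fraction of
transactions containing X, confidence(X=>Y) = supp(X u Y)/supp(X), and
lift(X=>Y) = supp(X u Y)/(supp(X) supp(Y)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import PrognosisLabels

__all__ = [
    "TransactionDB", "Rule", "binarize_by_mean", "build_transactions",
    "apriori", "score_rule", "rules_to_frame",
]


@dataclass
class TransactionDB:
    """Binary transactions: one per sample, items as strings."""

    items: tuple[str, ...]
    transactions: list[frozenset[str]]

    def __post_init__(self) -> None:
        universe = set(self.items)
        for t in self.transactions:
            if not t <= universe:
                raise ValueError(f"transaction holds unknown items: {t - universe}")

    def __len__(self) -> int:
        return len(self.transactions)

    def support(self, itemset: Iterable[str]) -> float:
        s = frozenset(itemset)
        unknown = s - set(self.items)
        if unknown:
            raise KeyError(f"unknown items: {sorted(unknown)}")
        return sum(1 for t in self.transactions if s <= t) / len(self.transactions)


@dataclass(frozen=True)
class Rule:
    """Association rule X => Y with its interest metrics."""

    lhs: frozenset[str]
    rhs: str
    support: float
    confidence: float
    lift: float

    def sort_key(self):
        return (-self.confidence, -self.lift, -self.support,
                tuple(sorted(self.lhs)), self.rhs)


def binarize_by_mean(X: pd.DataFrame) -> pd.DataFrame:
    """high/low discretization at the per-feature mean (ties map to low)."""
    flat = X.columns[X.std(axis=0, ddof=0) == 0]
    if len(flat):
        warnings.warn(f"constant features binarized to all-low: {list(flat)}")
    return X.gt(X.mean(axis=0)).astype(bool)


def build_transactions(
    binary_by_level: Mapping[str, pd.DataFrame],
    labels: PrognosisLabels,
) -> TransactionDB:
    """Assemble transactions from per-level binarized frames and labels.

    Items are ``feature_LEVEL=high|low``; the class item is
    ``prognosis=good|poor``.  Excluded samples are dropped.
    """
    lab = labels.label[labels.label != "excluded"]
    items: set[str] = set()
    rows: list[frozenset[str]] = []
    frames = {
        lv: frame.loc[frame.index.intersection(lab.index)]
        for lv, frame in binary_by_level.items()
    }
    common = lab.index
    for frame in frames.values():
        common = common.intersection(frame.index)
    for lv, frame in frames.items():
        for col in frame.columns:
            items.add(f"{col}_{lv}=high")
            items.add(f"{col}_{lv}=low")
    items.update({"prognosis=good", "prognosis=poor"})
    for s in common:
        t = {f"prognosis={lab[s]}"}
        for lv, frame in frames.items():
            for col in frame.columns:
                state = "high" if bool(frame.at[s, col]) else "low"
                t.add(f"{col}_{lv}={state}")
        rows.append(frozenset(t))
    if not rows:
        raise ValueError("no labeled samples shared across levels")
    return TransactionDB(tuple(sorted(items)), rows)


def apriori(
    db: TransactionDB,
    min_support: float = 0.1,
    min_confidence: float = 0.8,
    rhs_classes: Sequence[str] = ("prognosis=good", "prognosis=poor"),
    max_lhs: int = 3,
) -> list[Rule]:
    """Class-consequent rules meeting the support and confidence floors.

    Frequent feature itemsets are grown levelwise; a candidate of size k is
    kept only if all its (k-1)-subsets are frequent (anti-monotonicity).
    Output is sorted by (confidence desc, lift desc, support desc,
    lexicographic itemset).
    """
    if not 0 < min_support <= 1 or not 0 < min_confidence <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    m = len(db.transactions)
    rhs = [c for c in rhs_classes if c in set(db.items)]
    feature_items = sorted(set(db.items) - set(rhs_classes))
    # counts for single items
    def count(itemset: frozenset[str]) -> int:
        return sum(1 for t in db.transactions if itemset <= t)

    class_count = {c: count(frozenset([c])) for c in rhs}
    frequent: dict[frozenset[str], int] = {}
    level = []
    for it in feature_items:
        s = frozenset([it])
        c = count(s)
        if c / m >= min_support:
            frequent[s] = c
            level.append(s)
    rules: list[Rule] = []

    def emit(xset: frozenset[str], x_count: int) -> None:
        supp_x = x_count / m
        for y in rhs:
            xy_count = count(xset | {y})
            supp_xy = xy_count / m
            if supp_xy < min_support or xy_count == 0:
                continue
            conf = supp_xy / supp_x
            if conf < min_confidence:
                continue
            lift = supp_xy / (supp_x * (class_count[y] / m))
            rules.append(Rule(xset, y, supp_xy, conf, lift))

    size = 1
    while level and size <= max_lhs:
        for xset in level:
            emit(xset, frequent[xset])
        size += 1
        if size > max_lhs:
            break
        # candidate generation: join + prune
        seen = set()
        nxt = []
        for a, b in combinations(level, 2):
            cand = a | b
            if len(cand) != size or cand in seen:
                continue
            seen.add(cand)
            if any(cand - {x} not in frequent for x in cand):
                continue
            c = count(cand)
            if c / m >= min_support:
                frequent[cand] = c
                nxt.append(cand)
        level = nxt
    return sorted(rules, key=Rule.sort_key)


def score_rule(db: TransactionDB, rule: Rule) -> tuple[float, float, float]:
    """Recompute (support, confidence, lift) of a rule by direct counting."""
    supp_x = db.support(rule.lhs)
    supp_y = db.support([rule.rhs])
    supp_xy = db.support(set(rule.lhs) | {rule.rhs})
    if supp_x == 0:
        raise ValueError("rule antecedent absent from all transactions")
    if supp_y == 0:
        raise ValueError("rule consequent absent from all transactions")
    conf = supp_xy / supp_x
    return supp_xy, conf, supp_xy / (supp_x * supp_y)


def rules_to_frame(rules: Sequence[Rule]) -> pd.DataFrame:
    """Long-format table: lhs items ';'-joined, rhs, support, confidence, lift."""
    return pd.DataFrame(
        {
            "lhs": [";".join(sorted(r.lhs)) for r in rules],
            "rhs": [r.rhs for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
        }
    )
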