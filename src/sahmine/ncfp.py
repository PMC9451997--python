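"""NCFP-growth: FP-growth with a per-item interest-degree weight and a
second admission threshold ``min_up`` applied during tree construction.

An item enters the item table L — and hence the tree and every mined
itemset — only if it is both frequent (support >= min_sup) and
interesting (weight >= min_up).  With ``min_up = 0`` and non-negative
weights the filter admits everything and NCFP-growth reduces exactly to
FP-growth; raising ``min_up`` can only remove itemsets and rules, which
is the pruning the method exists for.

The interest-degree measure itself is user-supplied: by default every
item weighs 1.0, and :func:`class_lift_weights` offers a convenience
weighting oriented toward classification — an item's weight is the best
lift it achieves toward any class label, so items carrying no class
signal weigh about 1 and can be pruned with ``min_up`` slightly above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict

from .itemset_core import (
    Item,
    MiningParams,
    TransactionDB,
    as_fraction,
    support_count,
)
from .miners import FPTree, build_fp_tree, fp_growth_mine


@dataclass(frozen=True)
class InterestWeights:
    """Per-item interest-degree weights; unlisted items get the default."""

    weights: Dict[Item, float] = field(default_factory=dict)
    default_weight: float = 1.0

    def __post_init__(self):
        for item, w in self.weights.items():
            if not (math.isfinite(w) and w >= 0):
                raise ValueError(f"weight for {item} must be finite and >= 0")
        if not (math.isfinite(self.default_weight) and self.default_weight >= 0):
            raise ValueError("default_weight must be finite and >= 0")

    def weight(self, item: Item) -> float:
        return self.weights.get(item, self.default_weight)


@dataclass(frozen=True)
class NCFPParams:
    """min_sup (support threshold), min_up (interest threshold), weights."""

    min_sup: Fraction
    min_up: float = 0.0
    weights: InterestWeights = field(default_factory=InterestWeights)

    def __post_init__(self):
        object.__setattr__(self, "min_sup", as_fraction(self.min_sup))
        if not (0 < self.min_sup <= 1):
            raise ValueError("min_sup must lie in (0, 1]")
        if self.min_up < 0:
            raise ValueError("min_up must be >= 0")

    def passes(self, item: Item) -> bool:
        return self.weights.weight(item) >= self.min_up

    def mining_params(self) -> MiningParams:
        # min_conf is irrelevant for itemset mining; use 1 as a placeholder
        return MiningParams(self.min_sup, 1)


def weighted_frequent_items(db: TransactionDB, params: NCFPParams) -> list:
    """The item table L: (item, support count) pairs for items with
    support >= min_sup AND weight >= min_up, sorted by descending support
    (ties by canonical item order).  Items outside L are excluded from
    every subsequent structure."""
    db.require_nonempty()
    counts: dict = {}
    for t in db.transactions:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    min_count = max(1, math.ceil(params.min_sup * db.n))
    admitted = {
        item: c
        for item, c in counts.items()
        if c >= min_count and params.passes(item)
    }
    return sorted(admitted.items(), key=lambda kv: (-kv[1], kv[0]))


def build_ncfp_tree(db: TransactionDB, params: NCFPParams) -> FPTree:
    """NCFP-tree: the FP-tree restricted to the items of table L.

    Each transaction's surviving items are inserted in L's order; an
    existing child's count is incremented, a new node is chained into its
    item's header chain.  With min_up = 0 the result is identical to the
    plain FP-tree.
    """
    return build_fp_tree(db, params.mining_params(), item_filter=params.passes)


def ncfp_mine(db: TransactionDB, params: NCFPParams) -> frozenset:
    """FP-growth mining over the NCFP-tree.

    Equals brute-force mining restricted to itemsets whose every member
    item passes the weight filter; never larger than the plain FP-growth
    output at the same min_sup.
    """
    return fp_growth_mine(db, params.mining_params(), item_filter=params.passes)


def class_lift_weights(
    db: TransactionDB,
    class_attribute: str = "Class",
) -> InterestWeights:
    """Convenience interest weighting: weight(item) = max over class
    labels c of confidence(item -> c) / fraction(c).

    Lift near 1 means the item says nothing about any class; lift well
    above 1 marks a diagnostically interesting item.  Class items
    themselves are assigned the maximum weight seen so that a min_up
    threshold never strips the consequents needed for classification
    rules.
    """
    db.require_nonempty()
    class_items = sorted(i for i in db.alphabet if i.attribute == class_attribute)
    if not class_items:
        raise ValueError(f"no items with attribute {class_attribute!r} in database")
    class_counts = {c: support_count(db, [c]) for c in class_items}
    weights: Dict[Item, float] = {}
    for item in db.alphabet:
        if item.attribute == class_attribute:
            continue
        sigma_i = support_count(db, [item])
        best = 0.0
        for c in class_items:
            if class_counts[c] == 0:
                continue
            conf = Fraction(support_count(db, [item, c]), sigma_i)
            lift = conf / Fraction(class_counts[c], db.n)
            best = max(best, float(lift))
        weights[item] = best
    top = max(weights.values(), default=1.0)
    for c in class_items:
        weights[c] = max(top, 1.0)
    return InterestWeights(weights=weights, default_weight=1.0)
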