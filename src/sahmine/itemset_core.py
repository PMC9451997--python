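"""Item/transaction data model and exact support/confidence accounting.

Items are Boolean ``attribute=value`` tokens; a transaction is a set of
items; a transaction database is an ordered list of transactions over a
finite alphabet.  Support thresholds are compared with exact rational
arithmetic so that boundary cases on small databases (count/n exactly at
min_sup) are decided deterministically, never by float rounding.

``brute_force_mine`` enumerates every nonempty subset of the alphabet and
is the correctness oracle for all the tree- and candidate-based miners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import chain, combinations
from typing import Iterable, NamedTuple, Union

Number = Union[int, float, str, Fraction]

BRUTE_FORCE_MAX_ITEMS = 20


class Item(NamedTuple):
    """An atomic ``attribute=value`` token, ordered lexicographically."""

    attribute: str
    value: str

    def __str__(self) -> str:
        return f"{self.attribute}={self.value}" if self.value else self.attribute

    @classmethod
    def parse(cls, token: str) -> "Item":
        """Parse ``"attr=value"``; a bare token becomes ``Item(token, "")``."""
        attribute, sep, value = token.partition("=")
        return cls(attribute, value if sep else "")


Itemset = frozenset  # of Item; canonical order = sorted(itemset)


def itemset(*tokens: Union[str, Item]) -> Itemset:
    """Build an itemset from ``"attr=value"`` strings or Item instances."""
    return frozenset(t if isinstance(t, Item) else Item.parse(t) for t in tokens)


def canonical(items: Iterable[Item]) -> tuple:
    """Canonical sorted-tuple form of an itemset (for stable output)."""
    return tuple(sorted(items))


def as_fraction(x: Number) -> Fraction:
    """Exact threshold conversion; floats go through their decimal repr.

    ``Fraction(0.2)`` would be the binary value 0.200000000000000011...,
    silently excluding a support of exactly 2/10.  Routing floats through
    ``str`` preserves the decimal the caller wrote.
    """
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


class ZeroSupportError(ValueError):
    """Confidence is undefined when the antecedent never occurs."""


@dataclass(frozen=True)
class TransactionDB:
    """Ordered bag of itemsets over a finite item alphabet."""

    transactions: tuple
    alphabet: frozenset = field(init=False)

    def __post_init__(self):
        txns = tuple(frozenset(t) for t in self.transactions)
        object.__setattr__(self, "transactions", txns)
        object.__setattr__(self, "alphabet", frozenset(chain.from_iterable(txns)))

    @property
    def n(self) -> int:
        return len(self.transactions)

    def require_nonempty(self) -> None:
        if self.n < 1:
            raise ValueError("mining requires at least one transaction")


@dataclass(frozen=True, order=True)
class SupportedItemset:
    """An itemset with its exact support count over a database of size n."""

    itemset_key: tuple = field(compare=True)
    count: int = field(compare=True)
    n: int = field(compare=True)

    @classmethod
    def make(cls, items: Iterable[Item], count: int, n: int) -> "SupportedItemset":
        return cls(canonical(items), count, n)

    @property
    def itemset(self) -> Itemset:
        return frozenset(self.itemset_key)

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.count, self.n)


@dataclass(frozen=True)
class AssociationRule:
    """``antecedent -> consequent`` with exact support and confidence."""

    antecedent: tuple
    consequent: tuple
    support: Fraction
    confidence: Fraction

    def __post_init__(self):
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be nonempty")
        if set(self.antecedent) & set(self.consequent):
            raise ValueError("antecedent and consequent must be disjoint")


@dataclass(frozen=True)
class MiningParams:
    min_sup: Fraction
    min_conf: Fraction

    def __post_init__(self):
        object.__setattr__(self, "min_sup", as_fraction(self.min_sup))
        object.__setattr__(self, "min_conf", as_fraction(self.min_conf))
        if not (0 < self.min_sup <= 1) or not (0 < self.min_conf <= 1):
            raise ValueError("min_sup and min_conf must lie in (0, 1]")


def support_count(db: TransactionDB, items: Iterable[Item]) -> int:
    """Number of transactions containing ``items`` as a subset.

    The empty itemset is a subset of every transaction, so its count is n.
    Items absent from the alphabet are allowed and simply never match.
    """
    query = frozenset(items)
    return sum(1 for t in db.transactions if query <= t)


def rule_metrics(
    db: TransactionDB, antecedent: Iterable[Item], consequent: Iterable[Item]
) -> AssociationRule:
    """Exact support and confidence of ``antecedent -> consequent``.

    support = sigma(S u T)/n and confidence = sigma(S u T)/sigma(S), both
    as exact rationals.  A never-occurring antecedent raises
    :class:`ZeroSupportError` rather than returning 0 or NaN.
    """
    ante = frozenset(antecedent)
    cons = frozenset(consequent)
    if not ante:
        raise ValueError("antecedent must be nonempty")
    if ante & cons:
        raise ValueError("antecedent and consequent must be disjoint")
    db.require_nonempty()
    sigma_s = support_count(db, ante)
    if sigma_s == 0:
        raise ZeroSupportError(f"antecedent {sorted(ante)} has zero support")
    sigma_st = support_count(db, ante | cons)
    return AssociationRule(
        antecedent=canonical(ante),
        consequent=canonical(cons),
        support=Fraction(sigma_st, db.n),
        confidence=Fraction(sigma_st, sigma_s),
    )


def brute_force_mine(db: TransactionDB, params: MiningParams) -> frozenset:
    """Exhaustive frequent-itemset miner: the oracle for every other miner.

    Enumerates all nonempty subsets of the alphabet, so it refuses
    alphabets above ``BRUTE_FORCE_MAX_ITEMS`` items.
    """
    db.require_nonempty()
    alpha = sorted(db.alphabet)
    if len(alpha) > BRUTE_FORCE_MAX_ITEMS:
        raise ValueError(
            f"brute force guard: {len(alpha)} items > {BRUTE_FORCE_MAX_ITEMS}"
        )
    out = []
    for k in range(1, len(alpha) + 1):
        for combo in combinations(alpha, k):
            c = support_count(db, combo)
            if Fraction(c, db.n) >= params.min_sup:
                out.append(SupportedItemset(combo, c, db.n))
    return frozenset(out)
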