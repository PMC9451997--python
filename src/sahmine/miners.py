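"""The four classical frequent-itemset miners: Apriori, DHP, Partition,
FP-growth.

All four are contractually equivalent to
:func:`sahmine.itemset_core.brute_force_mine`: identical (itemset, count)
output on every database.  They differ only in how they search.

* Apriori — level-wise candidate generation (join on a shared (k-1)-prefix,
  then prune candidates with an infrequent k-subset) and a full database
  scan per level.
* DHP — Apriori plus a hash-bucket filter: while counting level-k
  candidates, every (k+1)-subset of each transaction is hashed; a
  candidate whose bucket total is below the minimum support count cannot
  be frequent and is dropped before the next scan.
* Partition — two database scans: mine each contiguous segment at a local
  threshold, union the local frequent sets into a global candidate set,
  then recount the candidates against the whole database.  Any globally
  frequent itemset is locally frequent in at least one segment, so the
  union is a superset of the answer.
* FP-growth — compress the database into a prefix tree of support-sorted
  transactions (FP-tree) with per-item node chains, then mine recursively
  over conditional pattern bases, never materialising candidate sets.

The FP machinery is shared with the NCFP-growth variant in
:mod:`sahmine.ncfp` via an optional per-item admission filter.
"""

from __future__ import annotations

import json
import math
from itertools import combinations
from typing import Callable, Iterable, Optional

from .itemset_core import (
    Item,
    MiningParams,
    SupportedItemset,
    TransactionDB,
    canonical,
)

DEFAULT_BUCKET_COUNT = 1024
_HASH_BASE = 131


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

def apriori_gen(frequent_k: Iterable) -> frozenset:
    """Candidate (k+1)-itemsets from the frequent k-itemsets.

    Join: two k-itemsets identical except in their last (canonical-order)
    item merge into one (k+1)-candidate.  Prune: a candidate with any
    k-subset outside ``frequent_k`` is discarded (anti-monotonicity).
    """
    tuples = sorted(canonical(s) for s in frequent_k)
    if not tuples:
        return frozenset()
    sizes = {len(t) for t in tuples}
    if len(sizes) != 1:
        raise ValueError(f"mixed itemset sizes {sorted(sizes)} in apriori_gen")
    frequent = set(tuples)
    candidates = set()
    for i, a in enumerate(tuples):
        for b in tuples[i + 1:]:
            if a[:-1] != b[:-1]:
                break  # sorted order: no later b shares the prefix
            cand = a + (b[-1],)
            if all(
                tuple(cand[:j] + cand[j + 1:]) in frequent
                for j in range(len(cand))
            ):
                candidates.add(cand)
    return frozenset(frozenset(c) for c in candidates)


def _min_count(params: MiningParams, n: int) -> int:
    """Smallest integer count c with c/n >= min_sup (exact rational)."""
    return max(1, math.ceil(params.min_sup * n))


def _count_candidates(db: TransactionDB, candidates: Iterable[tuple]) -> dict:
    counts = {c: 0 for c in candidates}
    for t in db.transactions:
        for cand in counts:
            if t.issuperset(cand):
                counts[cand] += 1
    return counts


def apriori_mine(
    db: TransactionDB,
    params: MiningParams,
    stats: Optional[dict] = None,
    _bucket_filter: Optional[Callable] = None,
) -> frozenset:
    """Level-wise Apriori mining; output equals ``brute_force_mine``.

    ``stats``, if given, is filled with ``candidates_per_level``:
    the number of candidate itemsets counted at each level k >= 1.
    ``_bucket_filter`` is the DHP hook: called as
    ``filter(k, candidates, transactions, min_count)`` and returns the
    surviving candidates before the level-(k+1) scan.
    """
    db.require_nonempty()
    min_count = _min_count(params, db.n)
    candidate_sizes = []

    singles = {}
    for t in db.transactions:
        for it in t:
            singles[(it,)] = singles.get((it,), 0) + 1
    candidate_sizes.append(len(singles))
    frequent = {c: cnt for c, cnt in singles.items() if cnt >= min_count}
    result = dict(frequent)

    k = 1
    while frequent:
        level_sets = [frozenset(c) for c in frequent]
        candidates = {canonical(c) for c in apriori_gen(level_sets)}
        if _bucket_filter is not None:
            candidates = _bucket_filter(k + 1, candidates, db, min_count)
        candidate_sizes.append(len(candidates))
        counts = _count_candidates(db, candidates)
        frequent = {c: cnt for c, cnt in counts.items() if cnt >= min_count}
        result.update(frequent)
        k += 1

    if stats is not None:
        stats["candidates_per_level"] = candidate_sizes
    return frozenset(SupportedItemset(c, cnt, db.n) for c, cnt in result.items())


# ---------------------------------------------------------------------------
# DHP
# ---------------------------------------------------------------------------

def _bucket_hash(index_tuple: tuple, bucket_count: int) -> int:
    h = 0
    for idx in index_tuple:
        h = (h * _HASH_BASE + idx) % bucket_count
    return h


def dhp_mine(
    db: TransactionDB,
    params: MiningParams,
    bucket_count: int = DEFAULT_BUCKET_COUNT,
    stats: Optional[dict] = None,
) -> frozenset:
    """Apriori with direct-hashing-and-pruning of candidate sets.

    The bucket count for a (k+1)-subset is an upper bound on its support,
    so pruning by ``bucket total < min support count`` removes only
    infrequent candidates: the mined output is identical to Apriori's.
    """
    if bucket_count < 1:
        raise ValueError("bucket_count must be >= 1")
    db.require_nonempty()
    index = {item: i for i, item in enumerate(sorted(db.alphabet))}

    def bucket_filter(k, candidates, database, min_count):
        buckets = [0] * bucket_count
        for t in database.transactions:
            for sub in combinations(sorted(t), k):
                buckets[_bucket_hash(tuple(index[i] for i in sub), bucket_count)] += 1
        return {
            c for c in candidates
            if buckets[_bucket_hash(tuple(index[i] for i in c), bucket_count)]
            >= min_count
        }

    return apriori_mine(db, params, stats=stats, _bucket_filter=bucket_filter)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

def partition_segments(n: int, segment_count: int) -> list:
    """Contiguous, order-preserving [start, stop) boundaries covering n rows."""
    if not 1 <= segment_count <= n:
        raise ValueError("segment_count must be in [1, n]")
    base, extra = divmod(n, segment_count)
    bounds, start = [], 0
    for s in range(segment_count):
        stop = start + base + (1 if s < extra else 0)
        bounds.append((start, stop))
        start = stop
    return bounds


def partition_mine(
    db: TransactionDB,
    params: MiningParams,
    segment_count: int,
) -> frozenset:
    """Two-scan Partition mining.

    Phase 1 mines each segment at the local threshold
    ``ceil(min_sup * segment_size)`` and unions the local frequent sets;
    the ceiling keeps the union a superset of the global answer.  Phase 2
    recounts every candidate against the full database.
    """
    db.require_nonempty()
    candidates = set()
    for start, stop in partition_segments(db.n, segment_count):
        segment = TransactionDB(db.transactions[start:stop])
        local = apriori_mine(segment, params)
        candidates.update(s.itemset_key for s in local)
    counts = _count_candidates(db, candidates)
    min_count = _min_count(params, db.n)
    return frozenset(
        SupportedItemset(c, cnt, db.n)
        for c, cnt in counts.items()
        if cnt >= min_count
    )


# ---------------------------------------------------------------------------
# FP-tree construction and FP-growth mining
# ---------------------------------------------------------------------------

class FPNode:
    """One prefix-tree node: an item with the count of transactions whose
    support-sorted form passes through it."""

    __slots__ = ("item", "count", "parent", "children", "next")

    def __init__(self, item: Optional[Item], count: int, parent: Optional["FPNode"]):
        self.item = item
        self.count = count
        self.parent = parent
        self.children: dict = {}
        self.next: Optional[FPNode] = None  # node chain of the same item


class FPTree:
    """Prefix tree over support-sorted transactions with header node chains.

    ``item_order`` lists admitted items by descending support count
    (ties broken by canonical item order); ``header[item]`` heads the
    chain threading every node that holds ``item``.
    """

    def __init__(self, item_order: list, item_counts: dict):
        self.root = FPNode(None, 0, None)
        self.item_order = list(item_order)
        self.item_counts = dict(item_counts)
        self.header: dict = {}
        self._rank = {item: r for r, item in enumerate(item_order)}

    def insert(self, items: Iterable[Item], count: int = 1) -> None:
        """Insert admitted items of one transaction, sorted in tree order."""
        path = sorted((i for i in items if i in self._rank), key=self._rank.get)
        node = self.root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, count, node)
                node.children[item] = child
                # prepend onto the item's node chain
                child.next = self.header.get(item)
                self.header[item] = child
            else:
                child.count += count
            node = child

    def node_chain(self, item: Item):
        node = self.header.get(item)
        while node is not None:
            yield node
            node = node.next

    def node_count(self) -> int:
        """Number of item-bearing nodes (root excluded)."""
        return sum(1 for item in self.header for _ in self.node_chain(item))

    def prefix_path(self, node: FPNode) -> tuple:
        """Items on the root-to-parent path of ``node`` (nearest first)."""
        path = []
        p = node.parent
        while p is not None and p.item is not None:
            path.append(p.item)
            p = p.parent
        return tuple(path)


def build_tree(
    weighted_transactions: list,
    min_count: int,
    item_filter: Optional[Callable[[Item], bool]] = None,
) -> FPTree:
    """Build an FP-tree from (items, weight) pairs.

    Items below ``min_count`` weighted occurrences — or rejected by
    ``item_filter`` — are dropped before insertion.  ``item_filter`` is
    how NCFP-growth applies its interest-weight threshold.
    """
    counts: dict = {}
    for items, w in weighted_transactions:
        for it in items:
            counts[it] = counts.get(it, 0) + w
    admitted = {
        it: c
        for it, c in counts.items()
        if c >= min_count and (item_filter is None or item_filter(it))
    }
    order = sorted(admitted, key=lambda it: (-admitted[it], it))
    tree = FPTree(order, admitted)
    for items, w in weighted_transactions:
        tree.insert(items, w)
    return tree


def build_fp_tree(
    db: TransactionDB,
    params: MiningParams,
    item_filter: Optional[Callable[[Item], bool]] = None,
) -> FPTree:
    """FP-tree of the database at ``params.min_sup`` (all-infrequent
    databases yield a bare root)."""
    db.require_nonempty()
    weighted = [(t, 1) for t in db.transactions]
    return build_tree(weighted, _min_count(params, db.n), item_filter)


def _mine_tree(tree: FPTree, min_count: int) -> list:
    """Candidate-free mining over conditional pattern bases.

    Runs on an explicit work stack (not Python recursion) so tree depth —
    bounded by the longest transaction — never hits the interpreter's
    call-depth limit even for alphabets in the thousands.
    """
    results = []
    stack = [(tree, ())]
    while stack:
        current, suffix = stack.pop()
        # ascending support order: least frequent item first, as in the
        # classical formulation; output is order-independent either way
        for item in reversed(current.item_order):
            count = sum(node.count for node in current.node_chain(item))
            new_suffix = (item,) + suffix
            results.append((canonical(new_suffix), count))
            base = [
                (current.prefix_path(node), node.count)
                for node in current.node_chain(item)
                if node.parent is not None and node.parent.item is not None
            ]
            if base:
                conditional = build_tree(base, min_count)
                if conditional.item_order:
                    stack.append((conditional, new_suffix))
    return results


def fp_growth_mine(
    db: TransactionDB,
    params: MiningParams,
    item_filter: Optional[Callable[[Item], bool]] = None,
) -> frozenset:
    """FP-growth mining; output equals ``brute_force_mine`` exactly."""
    tree = build_fp_tree(db, params, item_filter)
    mined = _mine_tree(tree, _min_count(params, db.n))
    return frozenset(SupportedItemset(c, cnt, db.n) for c, cnt in mined)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def itemsets_to_json(mined: Iterable[SupportedItemset]) -> str:
    """Canonical JSON for a mined frequent-itemset collection.

    Sorted by (size, canonical items); byte-identical output across the
    five miners is itself an equivalence check.
    """
    records = sorted(
        (
            {
                "items": [str(i) for i in s.itemset_key],
                "count": s.count,
                "support": s.count / s.n,
            }
            for s in mined
        ),
        key=lambda r: (len(r["items"]), r["items"]),
    )
    return json.dumps(records, indent=None, separators=(",", ":"))
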