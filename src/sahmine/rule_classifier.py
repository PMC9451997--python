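"""Association-rule generation, classification association rules (CARs),
classifier construction by database-coverage pruning, and k-fold
cross-validation.

Rule generation follows the classical two-step scheme: mine the frequent
itemsets, then for every frequent itemset T and nonempty proper subset S
emit S -> (T - S) when sigma(T)/sigma(S) >= min_conf.  CARs are the rules
whose consequent is a single class item and whose antecedent carries no
class item; ranked by (confidence desc, support desc, antecedent size
asc, canonical antecedent order), they feed a CBA-style greedy coverage
pruner: walk the ranked list, keep a rule iff it correctly classifies at
least one still-uncovered training record, and mark every record it
matches as covered.  Prediction is first-match over the retained list
with a majority-class default.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional

from .itemset_core import (
    AssociationRule,
    Item,
    MiningParams,
    SupportedItemset,
    TransactionDB,
    as_fraction,
    brute_force_mine,
    canonical,
    support_count,
)
from .miners import (
    DEFAULT_BUCKET_COUNT,
    apriori_mine,
    dhp_mine,
    fp_growth_mine,
    partition_mine,
)
from .ncfp import NCFPParams, ncfp_mine

MINERS = ("brute", "apriori", "dhp", "partition", "fp", "ncfp")


@dataclass(frozen=True)
class CAR:
    """A classification association rule: antecedent -> one class item."""

    rule: AssociationRule

    def __post_init__(self):
        if len(self.rule.consequent) != 1:
            raise ValueError("CAR consequent must be a single class item")

    @property
    def class_item(self) -> Item:
        return self.rule.consequent[0]

    @property
    def antecedent(self) -> tuple:
        return self.rule.antecedent

    def sort_key(self):
        return (
            -self.rule.confidence,
            -self.rule.support,
            len(self.rule.antecedent),
            self.rule.antecedent,
        )

    def matches(self, record: frozenset) -> bool:
        return record.issuperset(self.rule.antecedent)


@dataclass(frozen=True)
class Classifier:
    """Ordered CAR list plus a default class; prediction is first-match."""

    rules: tuple
    default_class: Item

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return sum(self.fold_accuracies) / len(self.fold_accuracies)


def generate_rules(
    frequent: Iterable[SupportedItemset],
    db: TransactionDB,
    min_conf,
) -> frozenset:
    """All strong rules S -> (T - S) over the complete frequent set.

    ``frequent`` must be complete for its min_sup so that every subset's
    support count (the confidence denominator) is available — guaranteed
    by anti-monotonicity for any of the miners here.
    """
    min_conf = as_fraction(min_conf)
    counts = {s.itemset_key: s.count for s in frequent}
    rules = []
    for key, count_t in counts.items():
        if len(key) < 2:
            continue
        # iterate over nonempty proper subsets via bitmasks
        m = len(key)
        for mask in range(1, (1 << m) - 1):
            s = tuple(key[i] for i in range(m) if mask >> i & 1)
            sigma_s = counts.get(s)
            if sigma_s is None:  # subset filtered out (e.g. weight-pruned)
                sigma_s = support_count(db, s)
            conf = Fraction(count_t, sigma_s)
            if conf >= min_conf:
                t_minus_s = tuple(key[i] for i in range(m) if not mask >> i & 1)
                rules.append(
                    AssociationRule(
                        antecedent=s,
                        consequent=t_minus_s,
                        support=Fraction(count_t, db.n),
                        confidence=conf,
                    )
                )
    return frozenset(rules)


def mine_frequent(
    db: TransactionDB,
    params: MiningParams,
    miner: str = "fp",
    *,
    ncfp_params: Optional[NCFPParams] = None,
    segment_count: int = 3,
    bucket_count: int = DEFAULT_BUCKET_COUNT,
) -> frozenset:
    """Dispatch to one of the five miners (or the brute-force oracle)."""
    if miner not in MINERS:
        raise ValueError(f"unknown miner {miner!r}; choose from {MINERS}")
    if miner == "brute":
        return brute_force_mine(db, params)
    if miner == "apriori":
        return apriori_mine(db, params)
    if miner == "dhp":
        return dhp_mine(db, params, bucket_count=bucket_count)
    if miner == "partition":
        return partition_mine(db, params, min(segment_count, db.n))
    if miner == "fp":
        return fp_growth_mine(db, params)
    if ncfp_params is None:
        ncfp_params = NCFPParams(min_sup=params.min_sup)
    return ncfp_mine(db, ncfp_params)


def generate_cars(
    db: TransactionDB,
    params: MiningParams,
    miner: str = "fp",
    *,
    class_attribute: str = "Class",
    ncfp_params: Optional[NCFPParams] = None,
    segment_count: int = 3,
    bucket_count: int = DEFAULT_BUCKET_COUNT,
) -> frozenset:
    """Classification association rules mined with the chosen miner.

    These are exactly the strong rules whose consequent is a single
    ``class_attribute`` item and whose antecedent is class-free.
    """
    if not any(i.attribute == class_attribute for i in db.alphabet):
        raise ValueError(f"database has no {class_attribute!r} attribute")
    frequent = mine_frequent(
        db,
        params,
        miner,
        ncfp_params=ncfp_params,
        segment_count=segment_count,
        bucket_count=bucket_count,
    )
    counts = {s.itemset_key: s.count for s in frequent}
    cars = []
    for key, count_t in counts.items():
        class_items = [i for i in key if i.attribute == class_attribute]
        if len(class_items) != 1 or len(key) < 2:
            continue
        cons = class_items[0]
        ante = tuple(i for i in key if i != cons)
        sigma_s = counts.get(ante)
        if sigma_s is None:
            sigma_s = support_count(db, ante)
        conf = Fraction(count_t, sigma_s)
        if conf >= params.min_conf:
            cars.append(
                CAR(
                    AssociationRule(
                        antecedent=ante,
                        consequent=(cons,),
                        support=Fraction(count_t, db.n),
                        confidence=conf,
                    )
                )
            )
    return frozenset(cars)


def rank_cars(cars: Iterable[CAR]) -> List[CAR]:
    """Total, deterministic CAR order: confidence desc, support desc,
    antecedent size asc, canonical antecedent order asc."""
    return sorted(cars, key=CAR.sort_key)


def _split_record(t: frozenset, class_attribute: str):
    class_items = [i for i in t if i.attribute == class_attribute]
    if len(class_items) != 1:
        raise ValueError(
            f"record must carry exactly one {class_attribute!r} item, got {class_items}"
        )
    return t - {class_items[0]}, class_items[0]


def _majority_class(labels: Iterable[Item]) -> Item:
    tally: dict = {}
    for c in labels:
        tally[c] = tally.get(c, 0) + 1
    # majority count; ties resolved by canonical item order
    return min(tally, key=lambda c: (-tally[c], c))


def build_classifier(
    cars: Iterable[CAR],
    db: TransactionDB,
    class_attribute: str = "Class",
) -> Classifier:
    """Greedy database-coverage pruning of the ranked CAR list.

    A rule is retained iff it correctly classifies at least one training
    record not yet covered; every record the retained rule matches is
    then marked covered.  The default class is the majority class of the
    uncovered records (global majority once everything is covered).
    """
    db.require_nonempty()
    records = [_split_record(t, class_attribute) for t in db.transactions]
    uncovered = set(range(len(records)))
    kept = []
    for car in rank_cars(cars):
        if not uncovered:
            break
        matched = [i for i in uncovered if car.matches(records[i][0])]
        if any(records[i][1] == car.class_item for i in matched):
            kept.append(car)
            uncovered.difference_update(matched)
    if uncovered:
        default = _majority_class(records[i][1] for i in uncovered)
    else:
        default = _majority_class(c for _, c in records)
    return Classifier(rules=tuple(kept), default_class=default)


def predict(classifier: Classifier, record: frozenset) -> Item:
    """First matching rule's class, else the default class.

    ``record`` is an itemset of attribute=value items without a class
    item."""
    for car in classifier.rules:
        if car.matches(record):
            return car.class_item
    return classifier.default_class


def accuracy(classifier: Classifier, db: TransactionDB, class_attribute="Class"):
    """Micro accuracy (correct/total) of the classifier on ``db``."""
    records = [_split_record(t, class_attribute) for t in db.transactions]
    correct = sum(1 for attrs, c in records if predict(classifier, attrs) == c)
    return correct / len(records)


def stratified_folds(
    labels: List[Item], folds: int, seed: int
) -> List[List[int]]:
    """Class-stratified fold assignment: indices of each class are
    shuffled with the seed and dealt round-robin into the folds."""
    by_class: dict = {}
    for i, c in enumerate(labels):
        by_class.setdefault(c, []).append(i)
    for c, idx in sorted(by_class.items()):
        if len(idx) < folds:
            raise ValueError(
                f"class {c} has {len(idx)} records, fewer than {folds} folds"
            )
    rng = random.Random(seed)
    assignment: List[List[int]] = [[] for _ in range(folds)]
    for c in sorted(by_class):
        idx = list(by_class[c])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[pos % folds].append(i)
    return assignment


def cross_validate(
    db: TransactionDB,
    params: MiningParams,
    miner: str = "fp",
    folds: int = 10,
    seed: int = 0,
    *,
    class_attribute: str = "Class",
    ncfp_params: Optional[NCFPParams] = None,
    segment_count: int = 3,
    bucket_count: int = DEFAULT_BUCKET_COUNT,
) -> CVResult:
    """Stratified k-fold cross-validation of the full CAR pipeline.

    Each fold mines CARs on the training split, builds the coverage-
    pruned classifier, and scores micro accuracy on the held-out split.
    """
    labels = [
        _split_record(t, class_attribute)[1] for t in db.transactions
    ]
    assignment = stratified_folds(labels, folds, seed)
    fold_acc = []
    for test_idx in assignment:
        test_set = set(test_idx)
        train = TransactionDB(
            tuple(t for i, t in enumerate(db.transactions) if i not in test_set)
        )
        cars = generate_cars(
            train,
            params,
            miner,
            class_attribute=class_attribute,
            ncfp_params=ncfp_params,
            segment_count=segment_count,
            bucket_count=bucket_count,
        )
        clf = build_classifier(cars, train, class_attribute)
        correct = 0
        for i in test_idx:
            attrs, c = _split_record(db.transactions[i], class_attribute)
            if predict(clf, attrs) == c:
                correct += 1
        fold_acc.append(correct / len(test_idx))
    return CVResult(fold_accuracies=tuple(fold_acc), seed=seed)
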