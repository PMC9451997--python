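"""Binary attribute tables in the CT screening schema, feature
discretization, and the clinical diagnostic rule.

The schema has one row per imaging case:

    PN  record identifier (never an item)
    PD  clinician's prediagnosis bit
    H-M six binary attributes derived from the case (texture-feature
        bits and/or confirmation bits)
    Class  final diagnosis bit (1 = subarachnoid hemorrhage)

The diagnostic rule encoded here: a case is Class 1 iff the clinical
prediagnosis is positive (PD = 1) AND at least two of the K, L, M bits
are 1.  On the bundled ten-row reference fragment the rule reproduces
the recorded Class on 9 of 10 rows — the deviating row (PN 67) is a
confirmed hemorrhage that failed the initial criteria, which is exactly
the kind of case rule mining is meant to surface.

The bundled fragment ships as packaged CSV data; in its source the row
identifier printed "6667" is case 67.
"""

from __future__ import annotations

import csv
import io
import logging
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple, Union

from .itemset_core import Item, TransactionDB

logger = logging.getLogger(__name__)

SCHEMA: Tuple[str, ...] = ("PN", "PD", "H", "I", "J", "K", "L", "M", "Class")
FEATURE_COLUMNS: Tuple[str, ...] = ("H", "I", "J", "K", "L", "M")


@dataclass(frozen=True)
class FeatureRecord:
    """One case before discretization: id, prediagnosis, six texture
    feature values, and (for training data) the outcome bit."""

    pn: str
    pd: int
    features: Tuple[float, ...]
    class_: Optional[int] = None

    def __post_init__(self):
        if self.pd not in (0, 1):
            raise ValueError("PD must be 0 or 1")
        if len(self.features) != len(FEATURE_COLUMNS):
            raise ValueError(f"expected {len(FEATURE_COLUMNS)} feature values")
        if self.class_ not in (None, 0, 1):
            raise ValueError("Class must be 0, 1 or None")


@dataclass(frozen=True)
class BinaryRow:
    """One fully binarized row under the table schema."""

    pn: str
    bits: Dict[str, int]

    def __post_init__(self):
        expected = set(SCHEMA[1:])
        if set(self.bits) != expected:
            raise ValueError(f"bits must cover exactly {sorted(expected)}")
        for col, v in self.bits.items():
            if v not in (0, 1):
                raise ValueError(f"{col} must be 0 or 1, got {v!r}")

    def __getitem__(self, col: str) -> int:
        return self.bits[col]


@dataclass(frozen=True)
class BinaryTable:
    """Binarized records plus the per-feature thresholds that made them."""

    rows: Tuple[BinaryRow, ...]
    thresholds: Optional[Dict[str, float]] = field(default=None)

    def __post_init__(self):
        pns = [r.pn for r in self.rows]
        if len(set(pns)) != len(pns):
            raise ValueError("PN identifiers must be unique")

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(SCHEMA)
        for r in self.rows:
            w.writerow([r.pn] + [r.bits[c] for c in SCHEMA[1:]])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "BinaryTable":
        reader = csv.reader(io.StringIO(text))
        header = next(reader, None)
        if header is None or tuple(header) != SCHEMA:
            raise ValueError(f"header must be {','.join(SCHEMA)}, got {header}")
        rows = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells:
                continue
            if len(cells) != len(SCHEMA):
                raise ValueError(f"line {lineno}: expected {len(SCHEMA)} cells")
            try:
                bits = {c: int(v) for c, v in zip(SCHEMA[1:], cells[1:])}
            except ValueError as e:
                raise ValueError(f"line {lineno}: non-integer cell ({e})") from None
            rows.append(BinaryRow(pn=cells[0], bits=bits))
        return cls(rows=tuple(rows))

    def to_transactions(self) -> TransactionDB:
        """Attribute-table dialect: every non-PN cell v becomes item
        ``col=v``; PN is dropped."""
        txns = [
            frozenset(Item(c, str(r.bits[c])) for c in SCHEMA[1:])
            for r in self.rows
        ]
        return TransactionDB(tuple(txns))


def discretize_features(
    records: Sequence[FeatureRecord],
    thresholds: Union[str, Dict[str, float]] = "median-split",
) -> BinaryTable:
    """Binarize continuous feature records into the table schema.

    Feature bit = 1 iff value > threshold (ties go to 0).  With
    ``"median-split"`` each feature's threshold is its median over the
    records, so a constant feature yields an all-zero column (warned,
    not an error).  The six feature bits fill columns H..M; PD and Class
    are carried through.
    """
    if not records:
        raise ValueError("need at least one record")
    if thresholds == "median-split":
        thresholds = {
            col: float(statistics.median(r.features[k] for r in records))
            for k, col in enumerate(FEATURE_COLUMNS)
        }
        for k, col in enumerate(FEATURE_COLUMNS):
            values = {r.features[k] for r in records}
            if len(values) == 1:
                logger.warning(
                    "feature %s is constant; median-split yields all zeros", col
                )
    elif not isinstance(thresholds, dict):
        raise ValueError("thresholds must be 'median-split' or a per-column dict")
    missing = [c for c in FEATURE_COLUMNS if c not in thresholds]
    if missing:
        raise ValueError(f"missing thresholds for {missing}")
    rows = []
    for r in records:
        if r.class_ is None:
            raise ValueError(f"record {r.pn}: Class required to build the table")
        bits = {"PD": r.pd, "Class": r.class_}
        for k, col in enumerate(FEATURE_COLUMNS):
            bits[col] = int(r.features[k] > thresholds[col])
        rows.append(BinaryRow(pn=r.pn, bits=bits))
    return BinaryTable(rows=tuple(rows), thresholds=dict(thresholds))


def apply_diagnostic_rule(record: Union[BinaryRow, Dict[str, int]]) -> int:
    """Clinical screening rule: 1 iff PD = 1 and at least two of K, L, M
    are 1; monotone in PD and in each of K, L, M."""
    get = record.__getitem__
    return int(get("PD") == 1 and (get("K") + get("L") + get("M")) >= 2)


def table1_fixture() -> BinaryTable:
    """The bundled ten-row reference fragment (cases 60-69), byte-stable."""
    text = (
        resources.files("sahmine").joinpath("data/table1.csv").read_text()
    )
    return BinaryTable.from_csv(text)
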