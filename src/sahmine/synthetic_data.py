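"""Seeded generators standing in for the (unavailable) hospital CT
database: two-class textured images and planted-rule transaction
databases.

Texture images
--------------
Normal slices are emulated as smoothed low-contrast Gaussian noise.
Abnormal slices share the same background but carry a few bright,
irregular blobs — random-walk-dilated masks rather than discs, so their
edges are ragged and the local gray-level distribution becomes uneven,
the qualitative signature of hemorrhage texture.  With ``blob_contrast
= 0`` the two classes are drawn from the same distribution, giving a
no-signal control.

Planted-rule transactions
-------------------------
Each planted rule ``antecedent -> class`` is realized in
``round(support * n)`` transactions: the antecedent items appear there
and nowhere else, and the class item equals the rule's class with the
requested confidence.  All transactions additionally pick up
independent background noise items at ``noise_rate``.  Empirical
support/confidence therefore match the request up to binomial sampling
error, and are exact when confidence is 1 and noise is 0.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .feature_table import BinaryTable, FeatureRecord, discretize_features
from .glcm_features import GLCMParams, extract_image_features
from .itemset_core import Item, TransactionDB, itemset


# ---------------------------------------------------------------------------
# Textured images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one class of synthetic CT-like texture."""

    label: str  # "normal" or "abnormal"
    base_intensity: float = 100.0
    noise_scale: float = 15.0
    blob_count: int = 5
    blob_size: int = 40  # random-walk steps per blob
    blob_contrast: float = 90.0
    smoothing_radius: float = 1.2
    shape: Tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self):
        if self.label not in ("normal", "abnormal"):
            raise ValueError("label must be 'normal' or 'abnormal'")
        if self.blob_count < 0 or self.blob_size < 1:
            raise ValueError("blob_count >= 0 and blob_size >= 1 required")


def _blob_mask(rng: np.random.Generator, shape, count: int, size: int):
    """Union of random-walk traces, dilated once: irregular-edged blobs."""
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    for _ in range(count):
        r = int(rng.integers(rows))
        c = int(rng.integers(cols))
        for _ in range(size):
            mask[r, c] = True
            dr, dc = rng.integers(-1, 2, size=2)
            r = int(np.clip(r + dr, 0, rows - 1))
            c = int(np.clip(c + dc, 0, cols - 1))
    return ndimage.binary_dilation(mask, iterations=1)


def gen_texture_images(spec: TextureSpec, count: int):
    """``count`` images drawn from ``spec``; returns (images, labels).

    Identical (spec, count) always yields identical pixel arrays.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(spec.seed)
    images: List[np.ndarray] = []
    for _ in range(count):
        img = spec.base_intensity + spec.noise_scale * rng.standard_normal(spec.shape)
        img = ndimage.gaussian_filter(img, sigma=spec.smoothing_radius)
        if spec.label == "abnormal" and spec.blob_count > 0:
            mask = _blob_mask(rng, spec.shape, spec.blob_count, spec.blob_size)
            img = img + spec.blob_contrast * mask
        images.append(np.clip(np.round(img), 0, 255).astype(np.int64))
    return images, [spec.label] * count


# ---------------------------------------------------------------------------
# Planted-rule transaction databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRule:
    """One rule to realize: antecedent tokens -> class value."""

    antecedent: Tuple[str, ...]  # e.g. ("A=1", "B=1")
    class_value: str  # e.g. "1"
    confidence: float
    support: float


@dataclass(frozen=True)
class PlantedRuleSpec:
    rules: Tuple[PlantedRule, ...]
    n: int = 500
    alphabet_size: int = 6  # independent background noise items
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.rules:
            raise ValueError("at least one planted rule is required")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must lie in [0, 1]")
        for r in self.rules:
            if not 0 < r.confidence <= 1:
                raise ValueError("rule confidences must lie in (0, 1]")
            if r.support * self.n < 1:
                raise ValueError("each rule needs support * n >= 1")
        if sum(round(r.support * self.n) for r in self.rules) > self.n:
            raise ValueError("requested supports exceed the database size")


def default_planted_spec(seed: int = 0, n: int = 500) -> PlantedRuleSpec:
    """Two deterministic rules (one per class) covering the database,
    plus light background noise — the regime in which an associative
    classifier should recover the planted structure essentially
    perfectly."""
    return PlantedRuleSpec(
        rules=(
            PlantedRule(("A=1", "B=1"), "1", confidence=1.0, support=0.5),
            PlantedRule(("C=1", "D=1"), "0", confidence=1.0, support=0.5),
        ),
        n=n,
        alphabet_size=6,
        noise_rate=0.05,
        seed=seed,
    )


def gen_transactions(spec: PlantedRuleSpec) -> TransactionDB:
    """Realize the planted rules as a transaction database (see module
    docstring for the construction and its guarantees)."""
    rng = np.random.default_rng(spec.seed)
    class_values = sorted({r.class_value for r in spec.rules})
    noise_items = [Item("N%d" % k, "1") for k in range(spec.alphabet_size)]

    transactions: List[frozenset] = []
    for rule in spec.rules:
        n_rule = round(rule.support * spec.n)
        ante = itemset(*rule.antecedent)
        for _ in range(n_rule):
            if rng.random() < rule.confidence or len(class_values) == 1:
                cls = rule.class_value
            else:
                others = [c for c in class_values if c != rule.class_value]
                cls = others[int(rng.integers(len(others)))]
            transactions.append(ante | {Item("Class", cls)})
    while len(transactions) < spec.n:
        cls = class_values[int(rng.integers(len(class_values)))]
        transactions.append(frozenset({Item("Class", cls)}))

    noisy = []
    for t in transactions:
        extra = {it for it in noise_items if rng.random() < spec.noise_rate}
        noisy.append(t | extra)
    order = rng.permutation(len(noisy))
    return TransactionDB(tuple(noisy[i] for i in order))


# ---------------------------------------------------------------------------
# End-to-end labeled dataset: images -> features -> binary table
# ---------------------------------------------------------------------------

def _prediagnosis_statistic(img: np.ndarray) -> float:
    """Crude reader stand-in: conspicuousness of bright regions,
    measured as the gap between the 99th percentile and the median."""
    return float(np.percentile(img, 99) - np.percentile(img, 50))


def gen_labeled_dataset(
    normal_spec: TextureSpec,
    abnormal_spec: TextureSpec,
    count_normal: int,
    count_abnormal: int,
    glcm_params: Optional[GLCMParams] = None,
    discretization="median-split",
) -> BinaryTable:
    """Full front half of the screening pipeline on synthetic images:
    generate both classes, extract the six texture features per image,
    derive the prediagnosis bit from a bright-region readout of the
    image (median split over the cohort), and binarize into the table
    schema with Class = the generator's label (abnormal = 1)."""
    if glcm_params is None:
        glcm_params = GLCMParams()
    images, labels = gen_texture_images(normal_spec, count_normal)
    more, more_labels = gen_texture_images(abnormal_spec, count_abnormal)
    images += more
    labels += more_labels

    stats = [_prediagnosis_statistic(img) for img in images]
    pd_threshold = float(np.median(stats))
    records = []
    for k, (img, label) in enumerate(zip(images, labels)):
        feats = extract_image_features(img, glcm_params)
        records.append(
            FeatureRecord(
                pn=str(k),
                pd=int(stats[k] > pd_threshold),
                features=feats.as_tuple(),
                class_=int(label == "abnormal"),
            )
        )
    return discretize_features(records, discretization)
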