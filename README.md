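# sahmine

Associative classification for subarachnoid-hemorrhage (SAH) screening
from CT texture.

SAH — bleeding into the subarachnoid space — is hard to read off a CT
slice by eye. This package implements a classical data-mining route to
computer-assisted screening: describe each slice by gray-level
cooccurrence matrix (GLCM) texture features, binarize the features into
an attribute table, mine **classification association rules** (CARs)
from that table, and use the ranked, coverage-pruned rule list as a
classifier. It is aimed at researchers studying associative
classification on medical imaging features, and at anyone who wants
carefully cross-checked reference implementations of the classical
frequent-itemset miners.

## What is inside

**Texture features.** For a quantized image and displacement
`(d, θ)`, the GLCM `M(i, j)` counts cooccurrences of gray levels `i`
and `j`. The default counting convention counts each *unordered*
adjacent pair once (mirrored off-diagonal), so a single contiguous
`(1,1)` pair gives `M(1,1) = 1`; the textbook add-transpose
(`ordered-symmetric`) mode is also available. From the normalized
matrix `p` six features are computed:

    energy          Σ p²                  contrast   Σ (i−j)² p
    entropy         −Σ p log₂ p           mean       Σ i · pᵢ
    local stability Σ p / (1 + (i−j)²)    correlation Σ (i−μᵢ)(j−μⱼ)p / σᵢσⱼ

**Frequent-itemset miners.** Five miners over Boolean
`attribute=value` transactions, all verified equivalent to an
exhaustive brute-force oracle: Apriori, DHP (hash-bucket candidate
pruning), Partition (two-scan segment mining), FP-growth, and
**NCFP-growth** — FP-growth extended with a per-item interest-degree
weight and a second threshold `min_up` applied during tree
construction. An item enters the tree only if `support ≥ min_sup`
*and* `weight ≥ min_up`; with `min_up = 0` NCFP-growth reduces exactly
to FP-growth, and raising `min_up` can only shrink the rule set.

**Classifier.** Rules `S → (T − S)` with `σ(T)/σ(S) ≥ min_conf` are
generated from the frequent sets; CARs (single class-item consequent)
are ranked by confidence, support, antecedent size, and pruned by
CBA-style database coverage. Evaluation is stratified 10-fold
cross-validation at the reference operating point (1% minimum support,
50% minimum confidence).

**Synthetic data.** Because no clinical image database ships with the
package, seeded generators provide (i) two-class textured images —
smooth noise vs. the same background plus bright irregular
(random-walk) blobs — and (ii) transaction databases with planted
association rules of chosen support and confidence.

## Worked example

The bundled ten-case screening fragment (cases 60–69, attributes
`PN, PD, H..M, Class`):

```python
from sahmine import (table1_fixture, support_count, itemset,
                     MiningParams, generate_cars, build_classifier, rank_cars)

table = table1_fixture()
db = table.to_transactions()
print("cases:", db.n, " distinct items:", len(db.alphabet))
print("sigma(PD=1) =", support_count(db, itemset("PD=1")))
print("sigma(PD=1, Class=1) =", support_count(db, itemset("PD=1", "Class=1")))

cars = generate_cars(db, MiningParams(min_sup=0.01, min_conf=0.5), miner="ncfp")
clf = build_classifier(cars, db)
print("CARs mined:", len(cars), " rules retained:", len(clf.rules))
top = rank_cars(cars)[0]
print("top-ranked CAR:", " & ".join(map(str, top.antecedent)), "->",
      top.class_item, f"(conf {top.rule.confidence}, supp {top.rule.support})")
```

prints

```
cases: 10  distinct items: 16
sigma(PD=1) = 7
sigma(PD=1, Class=1) = 6
CARs mined: 858  rules retained: 4
top-ranked CAR: I=1 & PD=1 -> Class=1 (conf 1, supp 2/5)
```

Seven of ten cases have a positive prediagnosis, six of those are
confirmed hemorrhages, so the rule `{PD=1} → {Class=1}` holds with
confidence 6/7 ≈ 0.857. At 1% support / 50% confidence the miner finds
858 CARs on this tiny fragment; database-coverage pruning keeps a
4-rule classifier. The top rule says every case with a positive
prediagnosis and feature bit I set was a confirmed hemorrhage
(confidence 1, support 2/5).

There is also a command-line surface (`sahmine features | mine |
rules | classify | cv | simulate`), e.g.:

```sh
sahmine mine transactions.csv --miner ncfp --min-sup 0.01 --min-up 1.05 \
        --weighting class_lift
```

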