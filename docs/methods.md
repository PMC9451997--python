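# Methods

This note records the models, conventions, parameter choices and known
limitations behind `sahmine`, in the order the pipeline runs.

## Transactions, support, confidence

Records are sets of Boolean `attribute=value` items (quantitative
features enter only after discretization). For an itemset X,
`support(X) = σ(X)/n` where σ is the number of transactions containing
X; a rule `S → T−S` over a frequent itemset T has
`confidence = σ(T)/σ(S)`. All threshold comparisons are done in exact
rational arithmetic: a float threshold like `0.2` is interpreted
through its decimal literal (1/5), never its binary value, so a
support of exactly 2/10 passes `min_sup = 0.2`. On small tables
boundary cases like this are common, and float comparison would make
mining results depend on representation noise.

Canonical item order is lexicographic on `(attribute, value)`; mined
output serializes in canonical order so that equal results are
byte-equal across miners.

## The miners

`brute_force_mine` enumerates every nonempty subset of the alphabet
(guarded at 20 items) and is the oracle every other miner is tested
against — it is deliberately naive and independent of the tree and
candidate machinery.

* **Apriori**: level-wise join on a shared (k−1)-prefix plus
  subset-pruning, one full scan per level.
* **DHP**: identical output; while counting level-k candidates it
  hashes every (k+1)-subset of each transaction into
  `bucket_count` buckets (stable polynomial hash of canonical item
  indices, base 131, default 1024 buckets — the hash is a free choice,
  fixed for determinism). A candidate whose bucket total is below the
  minimum support count cannot be frequent, so pruning is sound for
  any bucket count; `bucket_count = 1` degenerates to plain Apriori.
* **Partition**: contiguous, order-preserving segments; each segment
  is mined at the local absolute threshold
  `ceil(min_sup · segment_size)`. The ceiling is what makes "globally
  frequent ⇒ locally frequent somewhere" airtight under integer
  counts; the union of local results is recounted in a second full
  scan.
* **FP-growth**: transactions are inserted into a prefix tree in
  descending global support order (ties broken by canonical item
  order — the tie-break is a free choice fixed for reproducible
  trees), then mined over conditional pattern bases. Mining runs on an
  explicit work stack rather than Python recursion, so pattern depth —
  bounded by the longest transaction — never approaches the
  interpreter's call-depth limit even with alphabets in the thousands.

## NCFP-growth

NCFP-growth adds a per-item *interest-degree weight* and a second
threshold `min_up` to FP-tree construction: an item enters the item
table L (and therefore the tree, every conditional tree, and every
mined itemset) only if it is frequent **and** its weight is at least
`min_up`. Three properties define the implementation and are tested
directly:

1. **Reduction**: `min_up = 0` with non-negative weights is exactly
   FP-growth (identical serialized trees and identical mined sets).
2. **Oracle**: the mined set equals brute-force mining restricted to
   itemsets whose every member passes the weight filter.
3. **Monotone pruning**: raising `min_up` never adds itemsets, rules
   or classifier rules; the NCFP tree never has more nodes than the FP
   tree at the same `min_sup`.

The interest measure itself is not prescribed by the method, so
weights are user-supplied (default 1.0 per item). A convenience
weighting, `class_lift`, is provided for classification use:
`weight(i) = max_c confidence(i → c) / fraction(c)` — roughly "how
much more often than chance does this item travel with its best
class". Items carrying no class signal score near 1, so a threshold
slightly above 1 (e.g. 1.05) strips noise-born rules while keeping
informative ones. Class items themselves receive the maximum weight
seen so that a `min_up` threshold cannot strip the consequents the
classifier needs.

## Rules and the classifier

All strong rules are generated by subset-splitting each frequent
itemset; confidence denominators come from the (complete,
anti-monotone) frequent set, falling back to a direct count for
weight-pruned subsets under NCFP. CARs are the rules with a single
class-item consequent and a class-free antecedent.

The classifier construction is CBA-M1-style database coverage, a
standard design for associative classifiers: rank CARs by
(confidence desc, support desc, antecedent size asc, canonical
antecedent order), walk the list, keep a rule iff it correctly
classifies at least one still-uncovered training record, and mark all
records it matches as covered. The default class is the majority class
of the uncovered remainder (global majority when everything is
covered; ties resolve in canonical item order). Prediction is
first-match. Accuracy is micro accuracy (correct/total), pooled per
fold and averaged over stratified, seed-shuffled folds; folds are
dealt round-robin per class, and classes with fewer records than folds
raise an error rather than silently degrading stratification.

Default experimental settings are 1% minimum support, 50% minimum
confidence, 10 folds.

## GLCM and features

Quantization maps the occupied gray range uniformly onto
`[0, L−1]` (`floor((v − vmin)·L / span)`), so a full-range 8-bit image
at `L = 256` is untouched and a constant image maps to level 0.

The default counting convention counts each *unordered* pixel pair at
the offset once, mirrored off-diagonal: `{a, b}` with `a ≠ b`
increments `M(a,b)` and `M(b,a)`; `{a, a}` increments `M(a,a)` once.
One contiguous (1,1) pair therefore yields `M(1,1) = 1`, which is what
distinguishes this convention from the textbook add-transpose matrix
(`M(1,1) = 2`); the latter is available as `ordered-symmetric` and is
cross-checked against `skimage.feature.graycomatrix`. Both conventions
give symmetric matrices and identical results for all features that
depend only on the off-diagonal mass ratioed against the total.

Angle offsets in `(row, col)` with row 0 at top: 0°→(0, d),
45°→(−d, d), 90°→(−d, 0), 135°→(−d, −d). Defaults are `L = 16`,
`d = 1`, all four angles, features averaged arithmetically over angles
as a rotation-robust summary. Smaller L and larger d make the matrix
cheaper but lose information; L = 16 keeps 256 cells per matrix, which
is well-resolved for 64×64 and larger slices while keeping every cell
populated enough to estimate probabilities.

Of the six features, two names need fixing to formulas: "mean" is the
row-marginal mean μᵢ of the normalized matrix, and "local stability"
is the inverse difference moment `Σ p/(1+(i−j)²)` — the standard
Haralick quantities closest to those names. Correlation is undefined
when either marginal has zero variance; the default flags it 0
(configurable to raise), which keeps constant-texture images usable in
the pipeline. Entropy uses log base 2 with `0·log 0 = 0`.

Preprocessing (cropping, denoising, enhancement) is reduced to
optional center-crop and median-filter hooks; no segmentation is
performed anywhere in the pipeline.

## Binary table and diagnostic rule

The attribute schema is `PN, PD, H, I, J, K, L, M, Class`: record id
(never an item), prediagnosis bit, six binary attributes, outcome bit.
Discretization sets feature bit = 1 iff value > threshold, ties to 0;
`median-split` uses each feature's cohort median (a constant feature
becomes an all-zero column with a logged warning). Which texture
feature maps to which column is positional (energy→H … correlation→M);
nothing downstream depends on the assignment.

The clinical screening rule is `Class = 1 iff PD = 1 and at least two
of K, L, M are 1`. On the bundled ten-case reference fragment it
reproduces the recorded outcome on 9 of 10 cases; the deviating case
(PN 67) is a confirmed hemorrhage that failed the initial criteria —
precisely the kind of record that motivates mining the table instead
of trusting the hand rule.

## Synthetic data

The generators are pure functions of (spec, seed) and define the
study conditions for all stochastic tests.

*Images* (64×64 by default): normal = Gaussian noise (σ = 15 around
base 100) smoothed with a Gaussian kernel (σ = 1.2); abnormal = the
same background plus `blob_count = 5` bright blobs (contrast +90)
built as dilated random-walk traces of 40 steps — ragged edges and
uneven local gray structure rather than clean discs. These choices
give a strong but not saturated texture contrast at L = 16.
`blob_contrast = 0` is the null control: the two classes become
draws from the same distribution.

*Transactions*: each planted rule `antecedent → class` occupies
`round(support·n)` transactions; its antecedent items appear nowhere
else, and the class item matches the rule's class with the requested
confidence. Background noise items are added independently at
`noise_rate` to every transaction. Empirical support/confidence
therefore match the request to within binomial error, exactly when
confidence = 1 and noise = 0. The default spec plants two
confidence-1.0 rules (one per class, support 0.5 each) over six noise
items at noise rate 0.05 and n = 500 — a regime in which an
associative classifier should recover the planted structure
essentially perfectly, and in which class-lift weighting separates
informative items (lift ≈ 2) from noise items (lift ≈ 1).

The prediagnosis bit for generated image cohorts comes from a crude
"reader" stand-in: the gap between the 99th-percentile and median
intensity, median-split over the cohort. With visible blobs this
correlates with the label; with `blob_contrast = 0` it is chance, so
the null pipeline collapses to ≈ 0.5 accuracy rather than being
propped up by an artificially informative PD column.

**What passing on synthetic data does and does not show.** The
generators validate the machinery end to end — that texture contrast
propagates through GLCM features, discretization, mining and coverage
pruning into cross-validated accuracy. They do not emulate anatomy,
scanner physics, partial-volume effects, class imbalance of a real
screening population, or inter-reader variability of the prediagnosis;
accuracy figures on synthetic cohorts say nothing quantitative about
clinical CT.

## Problem sizes

Randomized oracle suites use databases of up to 12 items and 64
transactions (where exhaustive enumeration is still exact and fast)
with support thresholds in [0.05, 0.5]; image experiments use 100
64×64 slices at L = 16. These sizes make every stochastic check
re-runnable in seconds while keeping all code paths (multi-level
candidate generation, conditional-tree recursion, stratified folds)
exercised.

## Known limitations

* The interest-degree weight is an interface, not a learned quantity;
  `class_lift` is one reasonable instantiation, not a claim about the
  best one.
* Coverage pruning is greedy; it guarantees no worse training error
  than the unpruned ranked list, not optimality.
* The default unordered-pair GLCM departs from the common add-transpose
  definition (see above); use `ordered-symmetric` when comparing
  against other texture toolkits.
* Basket-dialect items are single tokens; attribute-table input is
  fixed to the nine-column screening schema.
* No volumetric (3-D) cooccurrence, no DICOM I/O, no segmentation.
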