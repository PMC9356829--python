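# Methods

## Model

`miforest` classifies small labeled sensor panels with an improved random
forest (IRF): a bootstrap CART forest whose trees are pruned by
mutual-information (MI) redundancy grouping on a validation set and
combined by per-class accuracy-weighted voting.

### CART trees

Trees are grown greedily on bootstrap row draws.  At each internal node,
`d` features are drawn without replacement (default ⌈√D⌉, Breiman's
convention) and every (feature, threshold) pair over them is scored by the
size-weighted Gini impurity

    Gini(V)      = 1 − Σ_i s_i²
    Gini(V, β)   = |V₁|/|V| · Gini(V₁) + |V₂|/|V| · Gini(V₂)

with thresholds at midpoints between consecutive sorted distinct values
and the boundary assigned left (`value ≤ threshold`).  Growth stops at
purity, `min_samples_split` (default 2), an optional depth cap (default
none — fully grown trees, the classic forest choice), or when no
candidate feature admits a two-sided split.  Leaves predict their majority
class.  All tie-breaks are deterministic: equal-Gini splits prefer the
smallest feature index then the smallest threshold; leaf majority ties
and vote ties prefer the smallest class code.  Tree i draws from the rng
stream `(seed, i)`, so a forest is bit-reproducible from its seed and
independent of construction order.

The split search is vectorized: per feature, class counts are accumulated
by cumulative sum over the sorted rows, so the weighted Gini of every
threshold is computed from integer prefix counts in one pass.  An
exhaustive brute-force scorer is kept in the test suite as the
independent oracle for this path.

### Information-theoretic pruning

Each tree's predicted-label vector on the validation set is a discrete
variable; all estimators are plug-in (empirical frequencies, no
smoothing, 0·log 0 := 0) in bits.  Log base is a pure rescaling of the
threshold ε, so one convention is fixed.  MI is computed through
H(X₁) + H(X₂) − H(X₁, X₂) and clamped at zero against floating-point
residue.  Raw (unnormalized) MI is used; a normalized variant would
change only the scale on which ε lives.

Grouping follows the sequential greedy rule: scanning trees in index
order, the first ungrouped tree seeds a group and absorbs every
still-ungrouped tree whose MI with the *seed* (not with all members)
is strictly greater than ε; the scan repeats until all trees are grouped.
This is deliberately order-dependent and deterministic — a graph-
clustering alternative would be a different algorithm, not a cleaner
version of this one.  Per group, the tree maximizing MI against the true
labels is kept (ties: smallest index); the kept list is sorted ascending.

**ε default.** No principled absolute value exists a priori: pairwise MI
lives on a scale set by the ensemble's output entropy, which varies with
class count and panel difficulty.  The default is therefore the 75th
percentile of the off-diagonal pairwise MI (so roughly the most redundant
quarter of pairs is eligible for merging), with an absolute override
(`--epsilon`).  Raising ε never decreases the number of groups; ε above
the maximum pairwise MI disables pruning entirely.

### Accuracy-weighted voting

The accuracy matrix A (rows = classes g, columns = kept trees c) holds
per-class validation recall: a_gc = fraction of validation samples of
true class g that tree c labels g.  "Correctness of each tree for each
class" is read as recall rather than precision because it conditions on
the running state g, and it is well-defined for every tree.  The weight
matrix is the identity mapping Q = A, kept as a separate operation so
alternative accuracy-to-weight transforms stay pluggable.  A probe's
score for class g is Σ_c q_gc·1[tree c votes g]; the argmax wins, ties
to the smallest class code.  If every score is zero (possible only when
an entire accuracy row is zero), the vote falls back to unweighted
majority with a warning.  With Q ≡ 1 the weighted vote reduces exactly
to plain majority voting — a reduction asserted in the tests.

### Validation split

The procedure needs a validation set X′ both for MI estimation and for A.
When the caller does not supply one, `ImprovedRandomForest.fit()` takes a
seeded stratified 75/25 split of the training panel.  The benchmark
protocol splits data 60/40 (stratified, seeded) into train/test first,
with the validation split taken inside the training portion; an optional
stratified k-fold mode is exposed as well, since small-panel studies
commonly report both.

## Synthetic panels

Real vinegar measurements behind the published study are not public, so
the generator emulates them.  `vinegar_spec()` encodes the published
per-class mean ± SD of five physicochemical indices (total soluble sugar,
total acid, salt, sugar-acid ratio, pH) for five vinegar classes, plus
three extra synthetic sensors (default separation 1 SD between adjacent
class means) to reach the study's eight channels — the study collected
eight sensors but quantified only five.  The "±" values are read as
standard deviations; the sugar-acid-ratio column is internally consistent
with the quotient of the printed sugar and acid means, which fixes its
reading as a ratio of means.  One misprinted SD cell ("± 091") is read
as 0.91.

Within a class, features are drawn independently — the published table
gives only marginal mean ± SD, so independence is the only defensible
model; a covariance hook would require information the table does not
contain.  Concentrations, the ratio and pH are truncated at zero by
rejection resampling (at most 1000 rounds, then clamp with a warning).
Study-scale defaults are 60 samples per class (300 × 8 total).

What this generator does *not* emulate: sensor drift, within-class
correlation between indices, non-Gaussian tails, and batch effects.
Passing accuracy floors on these panels therefore demonstrates that the
algorithm is implemented correctly and behaves sensibly under the stated
class geometry — not that it reaches any particular accuracy on real
electronic-tongue data.

Difficulty presets: `easy` (adjacent class means 6 SD apart on all 8
features — Bayes error well below 1%, used for accuracy-floor tests),
`paper-like` (the vinegar spec; aged and balsamic vinegar overlap
heavily, so ~100% test accuracy is not attainable and is not asserted),
`hard` (1 SD separation).

## Metrics

Confusion-table metrics follow the binary definitions accuracy,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R).  Multiclass
aggregation is macro-averaged precision and recall with F1 computed from
the *aggregated* P and R — this is the convention under which every F1
cell of the published five-model comparison is exactly reproduced from
its printed precision and recall at 2-decimal rounding, which validates
the choice.  Zero denominators score 0 with a warning.  Values are
fractions internally and percentages (2 decimals) in reports.  Relative
improvement of a over baseline b is (a − b)/b.

## Numerical and design notes

- Problem sizes in the test suite and acceptance script are study-scale
  (5 classes, 60/40 per-class train/test, forests of 50–100 trees),
  chosen to match the emulated design.
- The split search uses integer prefix counts, so threshold scores are
  exact up to one final division; oracle-equivalence tests compare at
  1e-12.
- Model serialization is JSON (nested tree nodes, row-major Q and A,
  class vocabulary, hyperparameters, seed); round-trip is lossless and
  byte-stable, so seeded pipelines produce byte-identical artifacts.
- Degenerate inputs: empty label vectors, one-sided partitions,
  single-class training panels, empty validation sets and nonpositive
  acid means raise `ValueError`; a validation set missing a class zeroes
  that accuracy row with a logged warning.

## Known limitations

- Pruning quality depends on the validation split; on tiny panels the MI
  estimates are coarse (plug-in bias is not corrected).
- The greedy seed-absorption grouping is order-dependent by design;
  representatives of different groups may still be pairwise redundant.
- Weighted voting with Q = A can be dominated by a single high-recall
  tree on rare classes; no per-class normalization is applied, matching
  the identity weighting.
- On panels with genuinely overlapping classes (aged/balsamic), the
  pruned weighted ensemble is not guaranteed to beat plain majority
  voting on every seed; only parity within a small margin is asserted.
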