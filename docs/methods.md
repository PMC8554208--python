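# Methods

`fntstack` implements a nonlinear stacking ensemble for virtual-screening
style binary classification (active compounds vs decoys): nine heterogeneous
base classifiers emit positive-class confidences, and a *flexible neural
tree* (FNT), trained by evolutionary search, combines the nine confidences
into a single score.

## The model

### Flexible neural tree

An FNT is a tree whose leaves are input variables (here the confidences
`c1..c9`) and whose internal nodes are *flexible neuron operators*.  An
operator of arity `i` with weights `w_1..w_i`, center `a` and width `b`
computes

    net = Σ_j w_j · o_j            (o_j = output of child j)
    out = exp(−((net − a) / b)²)

so every internal node emits a value in `(0, 1]` (numerically, the far
Gaussian tail may underflow to exactly 0 in double precision).  Because the
root is constrained to be an operator, the model output is directly usable
as a probability-like score; classification thresholds it at 0.5.

Design rules:

* **Root must be an operator.**  A bare-leaf model would just copy one base
  learner and could leave the `(0, 1]` range; the serializer can be asked to
  accept a leaf root (`allow_leaf_root`) for inspection tooling only.
* **Width floor** `|b| ≥ 1e−6`: the operator divides by `b`; a smaller width
  is treated as a degenerate parameterisation and rejected.
* Variables may appear in several leaves or not at all — the tree performs
  implicit input selection, and the learned trees are usually sparse in the
  nine inputs.
* Allowed operator arities default to `{2, 3, 4, 5}`.
* Trees are small (depth cap 4 by default), so evaluation is a direct
  recursive computation vectorised over rows; no caching is needed outside
  the annealer.

### Training: genetic-programming search + simulated annealing

Structure and parameters are learned jointly:

* a generational GP loop (population 50, 100 generations by default) with
  tournament selection (size 3, ties broken toward smaller trees), subtree
  crossover (rate 0.8, offspring repaired to the depth cap by truncating
  over-deep subtrees to leaves), four equiprobable mutation kinds (fresh
  random subtree, leaf re-indexing, arity change with child/weight padding
  or truncation, Gaussian jitter of one node's parameters), and one-elite
  survival;
* simulated annealing refines the champion's continuous parameters each
  generation.  One uniformly chosen scalar is perturbed per step with a
  Gaussian of scale `step_scale · T`; worsening moves are accepted with
  probability `exp(−Δ/T)` under geometric cooling.

Fitness is the RMSE between the tree output and the 0/1 labels plus a
parsimony penalty of `1e−3` per node; lower is better.  Elitism makes the
per-generation best fitness non-increasing, and all randomness flows from a
single seeded generator, so runs are exactly reproducible.

**Annealing schedule.**  The loss is an RMSE bounded in `[0, 1]`, so typical
move deltas are of order `0.01–0.1`; an initial temperature near 1 would
accept essentially every worsening move and perform no optimisation.  The
defaults are therefore `T0 = 0.02`, cooling `0.97` down to `1e−4` with 15
steps per temperature and proposal scale `20 · T` (i.e. from ≈0.4 down to
≈0.002), chosen by a robustness study on a parameter-recovery task (fit a
frozen single-operator tree to data generated from known `(w, a, b)`); with
three reannealing cycles — each cycle reheats and restarts from the best
parameters found — recovery succeeded on 45/45 random initialisations.
Standalone `anneal_parameters` uses 3 cycles; inside `evolve` each champion
polish uses a single cycle, because the generational loop already provides
restarts.

### Base learners and stacking

The nine base classifiers, fixed in the column order `c1..c9`: gcForest,
SVM (RBF), random forest, AdaBoost, CART decision tree, gradient-boosted
trees, k-nearest neighbours, logistic regression, Gaussian naive Bayes.
The eight scikit-learn members run with library-default hyperparameters
("confidence" = positive-class probability; the SVM margin is converted by
Platt scaling).  The deep forest is implemented in-package (below).

The FNT is trained on **out-of-fold** confidences by default: a stratified
`k_inner`-fold (default 5) split, keyed to stable row ids, in which row *i*
is only ever scored by models that never saw row *i*.  Resubstitution
stacking (`protocol="resub"`) is available for comparison; on
label-independent data it visibly inflates the confidence–label correlation
while the out-of-fold matrix stays at the class prior — that contrast is the
package's leakage guard.  For deployment the nine learners are refit on the
full training table.

### Deep forest (gcForest)

Multi-grained scanning slides windows of `k` contiguous features
(`s = m − k + 1` sub-vectors per window; default windows `⌈m/4⌉` and
`⌈m/2⌉`), scoring each sub-vector with a completely-random forest
(one uniformly random candidate feature per split, grown to purity —
realised as extremely randomised trees with `max_features=1`) and a
Gini random forest; the class-probability pairs splice into a `4s`-wide
block per window.  The cascade stacks layers of the same two forest kinds;
layer `t ≥ 2` receives the scanned representation concatenated with layer
`t−1`'s class vectors, and prediction averages the final layer's vectors
(argmax label, ties to the positive class).  Scanning and cascade
probabilities used during fitting are generated out-of-fold (3-fold, with a
sample's sub-vectors confined to its fold); growth stops when internal CV
accuracy stops improving (patience 1) or at 10 layers, and the model is
trimmed to the best depth.  Defaults: 30 trees per scanning forest, 100 per
cascade forest — all configurable.

Two readings of the scanned representation size are possible ("2s vectors"
per forest as a count or as a dimension); this implementation takes
2 forests × s sub-vectors × 2 class probabilities = `4s` values per window,
the standard deep-forest construction.

The cascade consumes the scanned representation only (not the raw features
appended to it); raw-feature cascades are a known variant but the scanned
output is the documented input here.

### Baseline ensembles

For comparison: the *averaged* ensemble (arithmetic mean of the nine
confidences, thresholded at 0.5) and the *voting* ensemble (majority of the
nine hard labels; nine voters never tie).

## Evaluation harness

Confusion-based metrics (TPR, FPR, precision, specificity, F1; conventions:
precision = 1 with no positive predictions, F1 = 0 when precision and TPR
are both 0), ROC curves from a full threshold sweep whose trapezoidal AUC
equals the Mann–Whitney statistic with ties counted ½, and stratified
k-fold cross-validation for `k ∈ {2, 4, 6, 8, 10, 15}`.  Fold assignment is
keyed to row ids (permuting the table permutes nothing), per-class fold
sizes differ by at most one, and reported CV numbers are *pooled*: the
confusion is summed over folds and the ROC computed on the concatenated
held-out scores — matching published tables whose single row per fold count
is consistent with integer pooled confusion ratios.  Mean-of-folds metrics
remain available via the per-fold results.

## Synthetic benchmark data

The screening dataset the method targets (88 curated actives, 264 DUD·E
style decoys, descriptor features) is not publicly deposited, so the
package generates statistically comparable tables (default 88/264, 50
continuous descriptors):

* `blobs` — mean shift of 2.5 sd on 10 random features; separable for every
  learner family (used for smoke and sanity checks).
* `complementary` — three disjoint signal blocks: six features with a weak
  0.4 sd linear shift, two XOR-style feature pairs (±1.2 sd quadrant
  pattern with matched marginals — invisible to linear models), and a
  local-cluster block (actives in four tight pockets, sd 0.5, inside a
  broad 1.6 sd decoy cloud), plus pure-noise features.  The block strengths
  were chosen so that no single learner family is near-ceiling and the
  family AUC profile is genuinely spread (roughly 0.6–0.9); under these
  conditions a reference stacker (logistic regression on the same
  out-of-fold confidences) consistently beats the best single learner,
  i.e. the complementarity is real and exploitable.
* `null` — labels independent of features; the end-to-end leakage canary.

Because the XOR quadrants and cluster centers are drawn per table, train and
test data must come from the *same* generated table to share signal
geometry.  Benchmark evaluations therefore generate one large table per
seed, train on a study-sized 88/264 subset and hold out the (3–4× larger)
remainder, which measures generalisation with small AUC standard error
(~0.02) instead of the ~0.05 of a one-third split.

What the generator does **not** emulate: real descriptor marginals
(counts, heavy tails, block correlations), property matching between
actives and decoys, activity-cliff structure, or any chemistry.  Passing
benchmarks here show the pipeline's statistical machinery works as
designed, not that the method attains any particular accuracy on real
screening data.

## Problem sizes in the shipped tests

The test suite runs the full pipeline at reduced but honest sizes chosen to
keep a laptop run comfortable: the dominance benchmark uses 20 seeds with a
5-fold stacking split, the default evolution budget and a slim deep forest
(10-tree scanning forests, 25-tree cascade forests, at most 5 layers); the
evolution sanity suite uses the full default budget across 20 seeds; the
null canary averages 10 seeds.  Reducing compute budgets makes these checks
harder, not easier, to pass.

## Known limitations

* The RMSE fitness is a surrogate; the tree is not trained to maximise AUC
  or F1 directly.
* SA and GP budgets are desk-scale; very deep trees (depth > 5) would need
  larger populations and a cleverer annealer.
* The deep forest targets two-class problems (2-dimensional class vectors)
  as used here.
* `load_results` restores prediction but not training-time diagnostics
  (history, stacking matrix).
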