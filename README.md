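# fntstack

Nonlinear stacking for virtual-screening classification: nine heterogeneous
base classifiers score each compound, and an evolved **flexible neural
tree** (FNT) combines the nine confidence scores into a single
active/decoy prediction.

## The problem

Early drug-discovery screens ask a simple question of a compound table:
which rows behave like known actives and which like decoys?  Different
classifier families see different parts of the signal in molecular
descriptor space — linear margins, axis-aligned interactions, local
neighbourhood structure — and no single family dominates.  Stacked
generalization exploits this: train the nine base models, collect their
positive-class confidences `c = (c1, …, c9)`, and learn a combining
function on top.

Here the combiner is a flexible neural tree: leaves are the confidences
`c1..c9`, internal nodes are Gaussian *flexible neuron operators*

    +i :  net = Σ_{j=1..i} w_j · x_j ,   out = exp(−((net − a) / b)²),

and both the tree's structure and its parameters `(w, a, b)` are learned by
a hybrid of genetic-programming search and simulated annealing.  The root
operator's output in `(0, 1]` is the ensemble confidence; `≥ 0.5` calls a
compound active.

The base roster (column order `c1..c9`): multi-grained cascade forest
(gcForest, implemented in-package), SVM, random forest, AdaBoost, decision
tree, gradient-boosted trees, KNN, logistic regression, naive Bayes — all
with library-default hyperparameters.  Stacking confidences are produced
out-of-fold so the meta-learner never trains on leaked in-sample scores.
Averaged and majority-voting ensembles are included as classical baselines,
and an evaluation harness provides confusion metrics (TPR, FPR, precision,
specificity, F1), ROC/AUC, and pooled stratified k-fold cross-validation
for k ∈ {2, 4, 6, 8, 10, 15}.

Because the original screening table (88 curated actives vs 264 generated
decoys) is not deposited, the package ships a synthetic-data module that
emulates its shape: 1:3 imbalanced descriptor tables with configurable
dimensionality and three signal layouts (`blobs`, `complementary`, `null`).
See `docs/methods.md` for the model, the training algorithm and every
default.

## Worked example

```python
import numpy as np
from fntstack import (DatasetSpec, generate_dataset, FNTStackingModel,
                      StackingConfig, EvolutionConfig, roc_auc)

table = generate_dataset(DatasetSpec(structure="complementary", seed=7))
model = FNTStackingModel(
    table.features, table.labels, row_ids=table.ids,
    evolution_config=EvolutionConfig(seed=7),
    stacking_config=StackingConfig(k_inner=5, seed=7),
)
results = model.fit()
print(results.summary())
```

```
FNT stacking ensemble
=====================================================
training rows:          352 (88 active / 264 decoy)
stacking protocol:      oof (k_inner=5, seed=7)
evolution budget:       population 50, 100 generations, seed 7
fitness evaluations:    5150
best fitness (RMSE+pc): 0.300439
tree size:              8 nodes, depth 2
training accuracy:      0.8977 (threshold 0.5)
meta-learner tree:
  (+3 w=2.672634078866075,6.708977602751941,-3.7999045342693063 a=-1.009875511824043 b=3.2772366752349464 (+2 w=2.5473453457326305,-6.45648239842236 a=1.2546752445722318 b=-0.716052465086759 (c6) (c7)) (+2 w=1.328797017541547,0.8360245191035544 a=-0.5005268904745025 b=1.477195889740281 (c1) (c2)) (c7))
base learner columns:   c1=gcforest, c2=svm, c3=rf, c4=adaboost, c5=dtree, c6=gbdt, c7=knn, c8=logreg, c9=nbayes
```

The summary shows the stacking protocol, the evolved tree (as an
s-expression over `c1..c9`), its size, and the training fit: `best fitness`
is the RMSE of the tree's output against the 0/1 labels plus a small
parsimony penalty, and `training accuracy` is the fraction of training
compounds classified correctly at the 0.5 threshold.  Scoring new
compounds:

```python
conf, labels = results.predict(new_features)   # confidence in (0, 1], 0/1 label
results.save("model_dir")                      # tree.sexp + learners + manifest
```

The same pipeline is scriptable from the shell:

```sh
fntstack simulate --out data.csv --structure complementary --seed 7
fntstack train    --input data.csv --out model/ --seed 7
fntstack predict  --model model/ --input data.csv --out scores.csv
fntstack evaluate --input data.csv --out eval/ --folds 2,4,6,8,10,15
fntstack compare  --input data.csv --out cmp/  --folds 10
```

`evaluate` writes one CSV per fold count with TPR, FPR, Precision,
Specificity, F1 and AUC for the stacker and each of the nine single
learners; `compare` adds the averaged and voting ensembles.

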