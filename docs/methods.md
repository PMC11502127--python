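# Methods

## Data model and preprocessing

An `ExpressionMatrix` is a samples × genes real matrix with unique gene
IDs and binary labels (1 = disease/positive). The loader rejects missing
or non-numeric cells and non-binary labels, naming the offending cell.

Normalisation is per-gene standard scaling to mean 0 and standard
deviation 1, using the population (divide-by-n) convention. Constant
genes map to all-zeros rather than NaN so downstream correlation code
always sees finite values. In the default pipeline order the scaling
statistics are estimated on the training split only and re-applied to the
test split; the split itself is stratified by label (with tens of samples
per dataset an unstratified 80:20 split too easily produces a one-class
test set). The training fraction defaults to 0.8.

## CFS merit and search

Correlations are Pearson product-moment; the class correlation is the
point-biserial form (labels treated as 0/1 numbers). Both the
feature–class term μ_ic and the feature–feature term μ_ii average
*absolute* correlations: signed averaging would let an anti-correlated
(equally predictive) gene cancel a correlated one. The correlation of a
constant vector is defined as 0.

The subset score is M(S) = i·μ_ic / √(i + i(i−1)·μ_ii). The search is
greedy forward selection: start empty, add the gene maximising the merit
of the augmented subset, stop when the best merit has not improved for
`patience` (default 5) consecutive additions or when `max_features`
(default 50) is reached, and return the subset at the best merit seen.
Ties break toward the lower gene index, making the search deterministic.
Greedy forward search is not exact, but on enumerable instances (≤ 10
genes) its merit stays within 5% of the exhaustive-subset optimum in the
test suite; exact search is infeasible at 10⁴ genes. The implementation
maintains incremental sums of absolute correlations so each step is one
vectorised pass over the remaining genes.

## IGWO

The continuous core follows the standard grey-wolf update. For wolf
position Z and leader Z_l (l ∈ {α, β, δ}, the three best solutions),
draw r1, r2 ~ U[0,1]^d fresh per leader and set B = 2a·r1 − a, E = 2·r2,
D_l = |E·Z_l − Z|, cand_l = Z_l − B·D_l; the candidate position is the
mean of the three cand_l, clamped to the box. The exploration parameter
decays linearly, a = 2(1 − t/T).

Two modifications define the "improved" variant here:

* **Chaotic initialisation.** Initial positions come from chaotic-map
  trajectories (logistic x ← 4x(1−x) by default; tent, singer and
  piecewise-linear maps are selectable), one independently-seeded stream
  per wolf, scaled into the bounds. Fixed points of each map are rejected
  as starting values.
* **Dual-candidate greedy update.** Each non-leader wolf draws two
  independent candidates per iteration (fresh coefficient vectors for
  each) and moves only to the fitter of {current, candidate 1,
  candidate 2}. Combined with explicit retention of the best solution
  ever evaluated, the global-best trace is non-increasing by
  construction — a property plain GWO lacks, and the package's tests
  assert it on every run.

Defaults: 30 wolves, 100 iterations. Leaders are ranked by fitness with a
stable sort, so ties break by wolf index. A non-finite objective value
raises immediately, naming the position.

## Binary wrapper

For feature selection the optimisation dimension equals the candidate-set
size (normally the CFS output, tens of genes). Positions live in
[−4, 4]^d, where the sigmoid spans (0.018, 0.982); a bit is on iff its
coordinate is strictly positive, and an all-off mask is repaired by
switching on the largest coordinate. The objective is

fitness(mask) = w·(1 − cv_acc(mask)) + (1 − w)·|mask|/d,  w = 0.99,

with cv_acc the stratified 5-fold cross-validated accuracy of a
5-nearest-neighbour classifier on the masked genes (folds fixed once per
run, so the objective is deterministic). The 5-NN evaluation is a
vectorised distance/majority-vote computation; a unit test pins it to
scikit-learn's `KNeighborsClassifier` on identical folds. The fold count
adapts downward when a class has fewer members than folds.

The weight w = 0.99 keeps accuracy dominant and uses subset size only as
a tie-breaker among equally accurate masks. A direct consequence: when CV
accuracy saturates (strong signal, many informative genes), the optimum
is a *minimal* accurate subset, not the full informative set. The wrapper
is a parsimony device, not a recovery device — with 20 informative genes
at effect size 2 it typically keeps 3–5 genes that classify perfectly,
and recovery of the full planted set must be read off the CFS stage
instead. On instances where every informative gene still improves CV
accuracy (e.g. 5 informative among 50), the wrapper keeps the informative
genes and discards most noise, and the tests verify exactly that.

## Base learners and ensembles

Roster and fixed order (used for every tie-break): LR, KNN, SVM, DT, ELM,
MLP, AdaBoost. Six delegate to scikit-learn with fixed defaults
(logistic regression with L2; 5-NN; RBF SVM with C=1; Gini decision tree;
AdaBoost with 50 stumps; MLP with one hidden layer of 100). The MLP uses
the full-batch lbfgs solver with a small L2 penalty (α=1e-3): at the
tens-of-samples scale this package targets, minibatch training with an
early-stopping split of a handful of samples is erratic, while lbfgs is
stable and deterministic per seed.

The extreme learning machine is implemented in-package: hidden weights
and biases are drawn once from U[−1,1] and never trained; the output
weights solve the ridge-regularised least squares
(HᵀH + λI)β = Hᵀy with λ = 1e-6 (pseudo-inverse fallback if the solve is
singular). Scores are the clipped network outputs in [0,1]; 100 hidden
units and sigmoid activation by default.

Learners are ranked on a stratified inner validation split (default 20%
of the training data) that the fits never see; ranking on the held-out
test set would leak. The top 3 (ties by roster order) are combined by
majority vote — member count kept odd so no tie is possible — and by
weighted averaging of positive-class scores with weights proportional to
validation accuracy (uniform if all accuracies are zero). The decision
threshold is 0.5, with the boundary assigned to class 1. SVM exposes
indicator {0,1} scores, as it has no native calibrated probability;
the other six supply probabilities.

## Metrics

ACC, SEN, SPE, PRE, F1 and the Matthews correlation coefficient are
computed from the confusion tally with class 1 positive. Any ratio with a
zero denominator is defined as 0 so degenerate predictors still produce
finite reports.

## Synthetic generator

The generator emulates the microarray regime: tens of samples, hundreds
to ~12,500 genes, binary labels, a small planted set of class-informative
genes, redundant noisy copies of them, and pure-noise genes. Informative
genes are N(0,1) in class 0 and N(δ,1) in class 1; redundant genes are a
parent informative gene plus N(0, noise_sd); everything else is N(0,1)
independent of the label. Defaults: 100 samples, 500 genes, 20
informative, 10 redundant, δ = 2, noise_sd = 0.5, balanced classes —
a strong-but-not-trivial signal regime in which single genes overlap
between classes but small subsets separate well. Class counts are exact
(round(n·balance), seeded shuffle of positions) so both classes are
always present. Gene roles land at randomly permuted column positions.

This model deliberately omits batch effects, heavy-tailed noise, probe
saturation and gene–gene interaction structure; passing tests demonstrate
correct mechanics and recovery under the Gaussian planted model, not
performance on real microarrays.

Recovery of a selection mask is the fraction of informative genes present,
with a redundant copy counting for its parent when the parent is absent.

## Pipeline order and leakage

The default order is split → scale (train statistics) → CFS → IGWO →
train → evaluate, so held-out samples influence nothing before the final
metrics. The alternative order — selection on the full matrix before the
split — is available behind `paper_order=True` for comparison, but it
lets test labels inform selection. The null control (δ = 0) exists to
police this: with the default order, ensemble test accuracy on pure-noise
data stays in the chance band.

## Problem sizes and determinism

The test-suite and acceptance studies use 100 samples × 500 genes with
five to ten seeded repetitions, and optimizer benchmarks at dimension 5
(sphere) and ≤ 12 (exhaustive wrapper enumeration) — sizes at which
exhaustive oracles are computable and full runs finish in seconds while
preserving the few-samples / many-genes character of the domain. Every
stochastic component (generator, splits, optimiser, hidden ELM weights)
is seeded; a fixed configuration reproduces its run directory byte for
byte.

## Known limitations

* Binary classification only; multi-class panels are out of scope.
* Greedy CFS has no optimality guarantee; the stall-based stopping rule
  exposes `max_features` rather than inferring a retained dimensionality.
* Wrapper fitness is tied to a 5-NN evaluator; subsets optimal for 5-NN
  are not necessarily optimal for every downstream learner.
* The wrapper's size penalty makes selected subsets minimal, so it under-
  reports the full informative set under strong signal (see above).
* No missing-value imputation or raw-chip normalisation; inputs are
  assumed to be numeric expression summaries.
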