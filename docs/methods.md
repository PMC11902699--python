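# Methods

## Problem setting

We study pool-based active learning for hard-parameter-sharing multitask
classifiers. A dataset holds a shared feature matrix `x ∈ R^{n×D}` and `T`
integer label columns `y(i)`, one per task `t_i` with `C_i` classes. Training
starts from a tiny uniformly drawn seed pool `L_n` (default `n_seed = 3`, with
no class-coverage guarantee — missing classes at seed time are part of the
protocol) and an unlabeled pool `U_m` covering the rest of the training split.
Each iteration spends `b` oracle queries (default 20) until the budget `B` is
exhausted; accuracy is always evaluated on a fixed held-out test split (20%).

The objective is the weighted multitask cross-entropy
`Σ_i α_i · CE_i + l2·‖W‖²`, with `CE_i` the mean cross-entropy of task i over
the batch and `α_i ≥ 0` task weights (default 1). The budget enters as a hard
constraint on total queries, not as a term in the loss.

## Query strategies

All informativeness measures are normalised to "higher = more informative":
least confidence `1 − max p` (range `[0, 1−1/C]`), margin `−(p₁−p₂)` (range
`[−1, 0]`), entropy `−Σ p ln p` (natural log; range `[0, ln C]`; probabilities
clamped to `≥ 1e−12` inside the log, `0·log 0 = 0`). The argmin forms of
least-confidence and margin sampling are recovered exactly as argmax of the
converted scores; the log base affects scale only, never a ranking.

*One-sided* selection needs a reference task. The rule used is maximum
combined correlation: `t* = argmax_i Σ_{j≠i} corr(t_i, t_j)`, where `corr` is
the absolute Pearson correlation of the integer-coded label columns (codes in
the dataset's declared class order). Pearson is the default because the
published worked values for this statistic are plain scalar correlations
between categorical codings; Cramér's V is available as an alternative that is
invariant to relabeling. Constant columns contribute zero association (with a
warning) rather than raising. Ties break to the lowest task index. The
reference task is resolved once per run from the training-split labels —
mirroring the dataset-level correlation analysis the rule comes from — rather
than from the (initially 3-sample) labeled pool, where correlation estimates
are degenerate.

*Alternating* selection uses reference task `k mod T` at iteration `k`,
starting from task 0. *Rank combination* ranks each task's entropy column
(rank 1 = highest entropy; ties get average/fractional ranks so sums are
permutation-stable) and selects the smallest rank sums `R_i = Σ_k r_i(k)`.
Any remaining tie in a score or rank sum breaks to the lowest sample index,
making every batch reproducible.

## Clustered Stratified Sampling

CSS partitions the *current* unlabeled pool with k-means (Euclidean, 10
seeded restarts; re-clustered every iteration since the pool shrinks) and
fills the batch with equal per-cluster quotas of the most informative members
— least confidence on the reference task for reference-based strategies,
smallest combined rank for RC. Cluster count: `C_i` of the reference task, or
`C_max = max_i C_i` for RC. For alternating selection the cluster count
follows the rotating reference task by default (`rotate_k=False` pins it at
`C_max`).

Quota arithmetic for batch `b` and `k` clusters: every cluster owes
`⌊b/k⌋`; the `b mod k` remainder goes one-by-one to clusters in decreasing
order of their best candidate's informativeness (ties → lowest cluster id); a
cluster smaller than its quota contributes everything and the deficit is
redistributed in the same order. Consequences verified by tests: per-cluster
counts differ by ≤ 1 whenever every cluster is large enough, the total is
always `min(b, |U_m|)`, and `k = 1` reduces CSS exactly to plain top-b
selection.

## The loop

The driver retrains the model from scratch each iteration (the alternative —
warm starting — couples iterations and makes runs harder to reproduce; the
per-iteration model seed is derived deterministically from the model seed and
the iteration number). The classic loop guard `while k·b < B` overshoots the
budget when `b ∤ B`; since the budget is a hard cap, the default
`budget_mode="capped"` clamps the final batch to exhaust `B` exactly, with
`"literal"` preserving the classic overshoot for comparison. The non-iterative
control trains on the seed, selects all `B` samples with that single model,
and retrains once — one oracle interaction regardless of budget. The oracle is
simulated by ground-truth lookup and refuses indices outside `U_m`.

Accuracy at multiple budgets is read from the per-iteration records of a
single run (checkpoint reading); per-budget independent runs are available by
running grids with different budgets. Comparison grids derive every cell's
seeds from (master seed, strategy name, CSS flag, repeat index), so adding a
strategy or budget never perturbs existing cells.

## The reference classifier

A numpy MLP: shared ReLU trunk (default one hidden layer of 32 units) and one
`C_i`-way softmax head per task, trained with Adam (lr 0.01, minibatch 32,
150 epochs, l2 factor 0.01 on weight matrices, optional inverted dropout and
inverse-frequency class weights, both off by default). The defaults are sized
for retraining hundreds of times inside desk-scale experiments; the query
machinery only consumes the fit/predict-probability contract, so heavier
backbones can be substituted without touching the strategies. Heads always
carry their full `C_i`-way softmax; classes unobserved in the labeled pool
simply receive no label gradient, which is what makes 3-sample seeds trainable.

## Synthetic benchmarks

The generator emulates the structure of windowed sensor data, not its raw
signal: each of `n_fine` fine-grained latent classes (≈ activities) is an
isotropic unit-variance Gaussian blob, and every task is a many-to-one
coarse-graining of the fine class. `separation` is the **minimum** pairwise
distance between class centers in within-class standard deviations — the
worst-case class gap, so `separation = 6` means essentially separable classes
(≈ `Φ(−3)` pairwise Bayes error) and `separation = 0` collapses all classes.
Counts follow the requested class proportions exactly (largest-remainder
rounding); everything is bit-reproducible under a seed.

Two default benchmarks bracket the task-congruence axis:

* **ku-like** (high congruence): n = 3000, D = 16, 18 fine classes, three
  3-class tasks whose coarse-grainings mirror an activity-type / intensity /
  stress split of 18 activities. Centers are placed hierarchically — group
  centers (one per intensity band) at minimum distance 6, fine centers offset
  within a group at minimum distance 3 — so activities of similar intensity
  produce similar features and feature-space clusters align with coarse
  classes, the regime CSS is designed for. These separations put full-data
  multitask test accuracy near 0.95 and the pairwise label correlations near
  (0.77, 0.92, 0.76), matching the regime the strategies were characterised
  in; the intensity task emerges as the reference task.
* **deap-like** (low congruence): n = 2000, D = 70, 8 fine classes at
  separation 3, three binary tasks reading the three bits of the fine-class
  code, with the all-agree corners over-weighted to induce weak positive
  association. Used chiefly to exercise the `C_max = 2` cluster-count rule and
  the low-correlation regime.

What the blobs do **not** emulate: temporal structure, within-class manifold
geometry, label noise, and — importantly — the slow learning curves of real
sensor models. A 3-class mixture of well-separated blobs is learned to within
a few points of its ceiling from ~200 examples, so budget-200 experiments on
these benchmarks sit close to the full-data ceiling. Directional findings
(iterative ≫ non-iterative; CSS's class balance) transfer; *magnitudes* of
accuracy differences between uncertainty strategies at a fixed budget are
ceiling-compressed and should not be read as predictions for real data. In
particular, CSS's balance advantage measurably improves labeled-pool class
uniformity here while leaving mean accuracy statistically unchanged — on real
data with more headroom the balance effect is the mechanism by which accuracy
gains were reported.

## Numerical and design choices

* Indices are 0-based everywhere, including reports and serialized results.
* Probability rows must sum to 1 within 1e−6; violations raise rather than
  renormalise silently.
* Train/test split and seed pool are drawn with numpy's PCG64; every derived
  seed (per-iteration model seed, per-cell grid seeds, per-iteration cluster
  seeds) comes from `SeedSequence` over structured keys and stays below 2³¹.
* Datasets serialize to a CSV (`f0..f{D-1}, task0..task{T-1}[, fine]`, header
  row) plus a JSON sidecar (task specs, generator config, split); run traces
  to JSON plus a flat one-row-per-iteration CSV.
* Degenerate inputs: batch sizes above `|U_m|` truncate with a warning; `k`
  above the pool size is reduced with a warning; empty pools raise
  `EmptyPoolError`; oracle queries outside `U_m` raise `InvalidQueryError`.

## Known limitations

* The capacity-growth schedule real deployments use (growing the network as
  the pool grows) is simplified to a fixed configuration for reproducibility.
* k-means is the only bundled clustering backend (the selection contract
  accepts any `ClusterAssignment`, so alternatives plug in).
* The oracle is noiseless ground truth; annotator error is out of scope.
* Wall-clock benchmarking of strategies is out of scope; complexity is only
  asserted qualitatively (later iterations are never cheaper than the first).
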