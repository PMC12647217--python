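# Methods

`dgqfs` implements a quantum-inspired feature-selection procedure for
high-dimensional feature matrices (the motivating use case is deep-feature
vectors extracted from fetal ultrasound standard-plane images, but nothing in
the library is image-specific past the preprocessing module). This note
records the model, the parameters that matter, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## The selection procedure

Given an n × d feature matrix X with class labels, the pipeline runs five
stages.

**1. Correlation graph.** Pairwise Pearson coefficients are computed
column-wise; the feature graph has an undirected edge (i, j) with weight
|r_ij| whenever |r_ij| > τ strictly (default τ = 0.5). Pearson's ratio is
invariant to the (n−1) vs n variance convention; we use the (n−1) form
throughout. Zero-variance columns correlate as 0 (with a warning) rather
than NaN so degenerate inputs keep the graph well defined.

**2. Entanglement scoring.** Each edge is scored by a simulated two-qubit
data re-uploading circuit. The two feature columns are min-max scaled to
[0, 1]; each selected row contributes one circuit execution in which value v
enters as a rotation RY(πv) on its qubit. A layer consists of data
re-encoding, a block of per-qubit trainable RY rotations, and a CNOT (or CZ)
entangling chain; the default depth is L = 3 layers. The trainable angles
are seeded constants drawn uniformly from [0, 2π) — the procedure defines no
training loss for them, and a fixed seed makes every score reproducible.
The per-row entanglement is either the von Neumann entropy of one qubit's
reduced density matrix, −Tr(ρ log₂ ρ), normalized by its 1-bit maximum, or
the Wootters concurrence of the pure two-qubit state; the edge score E_ij
is the mean over a seeded subsample of rows (default batch 64). Base-2
logarithms are used so the single-qubit entropy maximum is exactly 1, which
is what makes the [0, 1] normalization exact. Pair order is canonicalized
(the lower-index feature always drives qubit 0) so the score is symmetric
despite the directed CNOT chain. Only τ-surviving edges are scored, keeping
the cost O(|E|·batch) rather than O(d²·batch).

An experimental block mode runs one joint circuit over groups of
`n_qubits` (default 6) connected features and scores in-block pairs by the
entropy of their two-qubit reduced state (normalized by 2 bits); it is
exposed behind `score_all_edges(..., mode="block")` and is not the default
because the per-pair mode is cheaper, better characterized, and sufficient
for every property the tests check.

**3. Edge update.** The fidelity factor β ∈ [0, 1] blends the classical
weight with the quantum score: w ← β·w + (1−β)·E. The convex form is the
default because it keeps every weight in [0, 1], which is what makes the
subsequent threshold pruning meaningful; the unbounded additive form
w ← w + (1−β)·E is preserved behind `literal_update=True` for fidelity to
the alternative reading of the update rule. The default β = 0.8 was chosen
once, a priori: entanglement scores concentrate well below typical
correlation weights (on the benchmark most fall in 0.1–0.4), so a low β
would drag every edge under the pruning threshold within a few cycles and
empty the graph, while β near 1 would make the quantum signal inert. 0.8
preserves the validated correlation structure while letting the
entanglement scores reorder marginal edges.

**4. Pruning and centrality.** Weights strictly below τ_prune are zeroed
(weights equal to the threshold survive); τ_prune defaults to the
construction τ since the procedure reuses one symbol for both. Features are
then ranked by eigenvector centrality, the principal eigenvector of the
weighted adjacency (Ac = λc), computed by power iteration. Two numerical
guards are applied to the iteration matrix A → A + εJ + sI:

- ε = 1e-8 times the all-ones matrix J makes the matrix irreducible, so the
  Perron vector is unique on disconnected graphs and isolated nodes receive
  a well-defined ε-scale centrality instead of an arbitrary one.
- the spectral shift s = max row sum leaves the eigenvectors unchanged but
  makes the dominant eigenvalue strictly largest in magnitude. Without it,
  bipartite graphs (a 3-node path already) carry a −λ_max eigenvalue and
  the iteration oscillates forever.

Convergence is successive-iterate L∞ difference below `power_tol`
(default 1e-9, capped at 100 000 iterations — block-structured graphs with
near-degenerate component eigenvalues converge slowly, and a matrix-vector
product at d ≈ 128 is cheap). The reported eigenvalue is the Rayleigh
quotient with respect to A + εJ, so it carries an O(ε) offset from the
eigenvalue of A itself; at the defaults this is below every tolerance used.

**5. Iteration.** Score → update → prune → centrality → top-k repeats up to
`max_cycles` (default 5) and stops early when two consecutive cycles select
the same set — "stable set" is otherwise undefined, and set equality is the
strictest cheap criterion. Ties in the ranking break by ascending feature
index. Because a pair's score depends only on the data, circuit spec and
row sample, scores are memoized across cycles. An optional per-cycle hook
receives the current selection (the pipeline can wire it to classifier
retraining); selection is fully usable standalone.

## Classifier and evaluation

The evaluation classifier is a (256, 128, 64) ReLU MLP trained with
mini-batch SGD (batch 64, initial learning rate 0.01, L2 penalty 5e-4, at
most 500 iterations), inputs standardized to zero mean and unit variance by
a scaler fitted on the training partition only. "Adaptive" learning rate
means divide by 5 whenever the validation score stalls; early stopping
monitors a stratified 10% validation split with patience 10. The engine is
scikit-learn's `MLPClassifier`, whose semantics match this configuration
exactly; the cross-entropy loss is its standard multiclass choice. It does
not accept per-sample loss weights, so `class_weighting=True` is realized
as seeded oversampling of minority classes to the majority count, which is
equivalent in expectation to n/(C·n_c) class weights.

Metrics are computed from the confusion matrix alone (one-vs-rest TP/FP/FN
per class), so any report can be reconstructed from its own confusion
matrix; scikit-learn's implementations serve as an independent cross-check
in the tests. Macro and support-weighted averages are both reported;
headline comparisons default to weighted. A class never predicted has
precision reported as 0 with a warning. Feature-set diagnostics are the
histogram plug-in mutual information between a feature and the labels
(16 equal-width bins on the feature, labels as-is, base 2), the binned
Shannon entropy, and the redundancy index (mean absolute off-diagonal
pairwise correlation of the selected set). The set-level MI figure is the
mean over selected features of MI(feature; label), and is labelled as such.

## Preprocessing

The image module mirrors the preparation applied to ultrasound scans:
box/area resampling to a target size (224 × 224 in the motivating
application), per-image min-max scaling to [0, 1] over all channels jointly
(a constant image maps to zeros with a warning rather than failing a
batch), and blur screening. The blur score is the variance of the 3×3
Laplacian response on the grayscale image (reflect boundary) — the standard
scalar sharpness measure compatible with a "score below 100 is excluded"
rule; records scoring strictly below the threshold are excluded before
splitting. RGB→gray uses the equal-weight channel mean since no colorimetric
standard applies to ultrasound data. The split is stratified per class with
train count = floor(train_frac · class size) (train_frac default 0.75) and
one child random stream per class, and class weights are
total/(C · class_count) so they sum against class counts to the retained
total.

## The synthetic benchmark

`benchmark_default()` draws n = 1200 samples over 6 classes with
proportions (0.057, 0.249, 0.084, 0.139, 0.131, 0.340) — a realistic
screening-archive imbalance in which a miscellaneous class dominates — and
d = 128 features: per class, a block of 8 equicorrelated Gaussians
(pairwise ρ = 0.6) whose mean shifts by 1 SD for that class's samples;
16 redundant features (a seeded informative parent plus N(0, 0.5²) noise);
64 i.i.d. standard-normal noise columns. Equicorrelated blocks are the
right stress test because the method's first stage is Pearson-based:
planted correlation structure directly exercises graph construction,
pruning and centrality, and the known informative set makes recovery
measurable. The generator is deterministic per seed, with one spawned
stream per component.

What passing tests show: the pipeline concentrates centrality mass on
correlated, class-informative structure and excludes independent noise, and
the selected set supports better downstream accuracy than a random set of
equal size. What they do not show: performance on real deep-feature
distributions, which are neither Gaussian nor equicorrelated, carry
nonlinear dependencies the Pearson graph cannot see, and whose informative
structure is not block-aligned. The benchmark's class-conditional signal
(1 SD shift on correlated blocks) is deliberately moderate, so absolute
accuracies on it sit near 55%, far below what separable real feature
spaces yield; only orderings and recovery rates are meaningful, not the
absolute numbers.

## Problem sizes and degenerate inputs

The acceptance computations use the benchmark scale (n = 1200, d = 128,
~300 edges, 5 repeat seeds), chosen so the full suite and the acceptance
script each complete in well under a minute of refinement work while still
exercising multi-component graphs, pruning dynamics and imbalanced classes.
Degenerate inputs are handled, not rejected, wherever a batch pipeline
could plausibly encounter them: constant images (zeros + warning), constant
feature columns (zero correlation / zero encoding angle + warning), empty
graphs mid-refinement (uniform ε-centrality + warning, selection by index
order). Hard errors are reserved for contract violations: self-pair
scores, score keys off the edge set, β outside [0, 1], k > d,
single-class training data, dimension mismatches at prediction.

## Known limitations

- Entanglement scores are not calibrated measures of statistical
  dependence; with seeded (untrained) circuit parameters they act as a
  reproducible nonlinear re-weighting of the correlation graph, and their
  ranking value is validated empirically on the benchmark, not derived.
- The statevector simulator is dense and capped at 12 qubits by design.
- Pearson edges miss non-monotone dependencies entirely; features
  informative only through such dependencies never enter the graph.
- The redundancy index of a selected set is reported, not optimized;
  nothing in the procedure explicitly penalizes selecting the redundant
  copies of an informative parent.
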