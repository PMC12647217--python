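# dgqfs — dynamic graph-based quantum-inspired feature selection

`dgqfs` selects informative, non-redundant features from high-dimensional
labeled feature matrices — the kind produced by deep feature extractors over
medical images, where the motivating application is classifying fetal
ultrasound standard planes (brain, thorax, abdomen, femur, maternal cervix,
other) from pretrained-CNN activations. Redundant and noisy activations
degrade a downstream classifier; this library ranks features by combining
classical correlation structure with entanglement scores from simulated
quantum circuits.

## Method

For an n × d feature matrix X with labels:

1. **Correlation graph.** Features are nodes; edge (i, j) carries weight
   |Corr(x_i, x_j)| when that magnitude strictly exceeds a threshold τ
   (default 0.5).
2. **Entanglement scoring.** Each edge is scored by a two-qubit data
   re-uploading circuit: min-max scaled values enter as RY(πv) rotations,
   re-encoded at each of L = 3 layers, interleaved with seeded trainable
   rotations and a CNOT/CZ entangling chain. The score E_ij ∈ [0, 1] is the
   mean over sampled rows of the von Neumann entropy of one qubit's
   reduction, −Tr(ρ log₂ ρ) (normalized to 1 bit), or alternatively the
   Wootters concurrence.
3. **Edge update.** w_ij ← β·w_ij + (1−β)·E_ij with fidelity factor
   β ∈ [0, 1] blending classical and quantum information (β = 0.8 default).
4. **Prune + rank.** Weights below τ_prune are zeroed; features are ranked
   by eigenvector centrality (the principal eigenvector of Ac = λc,
   computed by power iteration) and the top-k are selected.
5. **Iterate.** Steps 2–4 repeat (≤ 5 cycles) until the selected set is
   stable. A (256, 128, 64) ReLU MLP trained with SGD, adaptive learning
   rate and early stopping evaluates the selection.

The statevector circuit simulator (RY / CNOT / CZ, partial trace, von
Neumann entropy, Wootters concurrence) is part of the package and is checked
in the tests against brute-force matrix-product oracles. A synthetic
generator plants known informative / redundant / noise structure so the
whole pipeline is testable without any external data. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import numpy as np
from dgqfs import (
    CircuitSpec, RefinementConfig, benchmark_default, build_adjacency,
    graph_stats, pearson_correlation, refine,
)

features, truth = benchmark_default()          # n=1200, d=128, 48 planted informative
graph = build_adjacency(pearson_correlation(features), tau=0.5)
print(f"graph: {graph_stats(graph)['edge_count']} edges over {features.n_features} features")

result = refine(features, graph, CircuitSpec(param_seed=1),
                RefinementConfig(k=64, sample_seed=1))
recovered = len(set(result.selected) & set(truth.informative_idx))
print(f"top-64 contains {recovered}/48 planted informative features")
print(f"per-cycle edge counts: {[s['edge_count'] for s in result.per_cycle_graph_stats]}")
print(f"leading eigenvalue trace: {[round(c.eigenvalue, 3) for c in result.per_cycle_centrality]}")
```

prints

```
graph: 307 edges over 128 features
top-64 contains 48/48 planted informative features
per-cycle edge counts: [307, 307, 307, 306, 305]
leading eigenvalue trace: [6.385, 6.276, 6.19, 6.138, 6.126]
```

The thresholded graph contains exactly the planted correlated structure
(6 informative blocks plus their redundant copies; the 64 noise features are
isolated), the refined top-64 recovers all 48 planted informative features,
and the eigenvalue trace shows the entanglement updates gently reshaping
edge weights across cycles while pruning removes a couple of marginal edges.

## Command line

```bash
dgqfs synth --seed 1 --n-samples 1200 --out bench.csv   # matrix + ground-truth JSON
dgqfs graph bench.csv --tau 0.5 --out edges.csv
dgqfs select bench.csv --k 64 --seed 1 --out selection.json
dgqfs run --config config.yaml                          # full pipeline into a run dir
dgqfs compare --methods dgqfs,random,mi --out ablation.csv
dgqfs preprocess images_dir/ --out manifest.csv         # blur screen + 75/25 split
```

`dgqfs run` writes the selection trace, trained model archive, metrics
(accuracy, macro and weighted precision/recall/F1, per-class table,
confusion matrix), feature-set diagnostics (mean mutual information,
entropy, redundancy index), per-stage timings, and a config snapshot that
reproduces the run bit-for-bit.

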