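# netard

Inference of sparse gene networks with hub genes from expression data, via
automatic-relevance-determination (ARD) estimates of partial correlations.

## The problem

Large-scale gene networks are sparse, but a few *hub* genes (transcription
factors, master regulators) interact with many partners. Under a Gaussian
graphical model the network is the support of the precision matrix
Ω = Σ⁻¹: genes k′ and k interact when the partial correlation

π<sub>k′k</sub> = −ω<sub>k′k</sub> / √(ω<sub>k′k′</sub> ω<sub>kk</sub>)

is nonzero. Standard sparse estimators (graphical lasso and relatives)
penalize all edges alike and tend to flatten hubs. This package estimates
edge weights w<sub>k′k</sub> = |π<sub>k′k</sub>| through p coupled sparse
Bayesian (ARD) regressions whose Gamma hyperpriors are *adapted* between
iterations: an edge's prior precision rate is updated as

r ← λ / ((1−ξ)·φ(w<sub>k′k</sub>) + ξ·φ(v<sub>k′</sub>)) + ½,  s = r²,

where v<sub>k</sub> = (1/p)Σ<sub>j</sub> w<sub>jk</sub> is node
connectivity and φ is a strictly increasing map. Weak edges earn stronger
shrinkage and strong edges weaker ("the strong get stronger"); the mixing
weight ξ ∈ [0, 1] shifts the signal from individual edge weights toward
node connectivity, biasing recovery toward hub topology. The graph support
found this way is re-fit by graph-constrained maximum likelihood
(covariance selection) and the regularization scale λ is selected by an
extended BIC. When hub genes are known a priori (`hubs=`), pairs not
touching a hub are shrunk each iteration — with shrinkage constant 0 they
are removed outright.

Around the estimator the package provides:

* `simulate` — hub-network generator (Ω = A + (0.1 − λ<sub>min</sub>(A))·I,
  Gaussian sampling) reproducing the benchmark topology (sparsity ≈ 0.97,
  degree centralization ≈ 0.33 for 100 genes / 4 hubs),
* `evaluate` — recall/fall-out/precision, exact ROC/PR sweeps with
  AUROC/AUPR, sparsity level and hub level (Freeman degree centralization),
* `gnce` — co-expression extension of a core network: cluster genes by
  1 − |correlation| with an adaptive (dynamic) tree cut, run the
  hub-constrained estimator inside every cluster containing core genes,
  merge the inferred edges into the core network,
* a graphical-lasso benchmark harness and a thin `netard` CLI
  (`simulate | infer | evaluate | gnce | benchmark`).

## Worked example

`examples/01_simulate_and_infer.py` simulates a 100-gene network with 4 hub
genes, draws 60 expression samples from the corresponding Gaussian model,
and runs the full inference:

```
simulated network: 149 edges, hubs at [45, 50, 74, 95]
  sparsity level 0.970, hub level 0.340

selected lambda 754.1 (EBIC 75.42); 93 edges
  estimated sparsity level 0.981, hub level 0.496

edge recovery: AUROC 0.706, AUPR 0.407
  at the selected graph: recall 41.6%, precision 66.7%, fall-out 0.65%

top-5 genes by estimated degree: [95, 74, 50, 31, 48] (true hubs: [45, 50, 74, 95])
```

Reading the numbers: of the 149 true interactions the selected 93-edge
graph recovers 41.6% with two-thirds precision, at a false-edge rate of
0.65% of all non-interacting pairs; AUROC/AUPR summarize the full
weight-threshold sweep. The estimated graph is hub-concentrated (hub level
0.50 vs 0.34 in truth), and three of the four true hubs head the degree
ranking. `examples/02_hub_constrained_inference.py` shows the variant with
declared hubs; `examples/03_extend_core_network.py` extends a 3-gene core
network through co-expression clusters.

The same flow from the shell:

```bash
netard simulate --p 100 --hubs 4 --n 60 --seed 1 --out sim/
netard infer --expr sim/expression.tsv --xi 0.1 --gamma 0 --out result/
netard evaluate --weights result/weights.csv --truth sim/true_edges.tsv --out eval.json
```

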