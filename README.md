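# gba-bias

Multifunctionality and node-degree bias diagnostics for guilt-by-association
(GBA) gene function prediction.

## The problem

GBA methods predict a gene's function from the functions of the genes it
associates with — in protein interaction, coexpression or genetic
interaction networks.  Cross-validated performance of such methods is often
impressive, but much of it can be explained without any pair-specific
association information at all.  The key observation is that some genes are
*multifunctional*: they belong to many annotation groups, so placing them at
the top of a single fixed candidate list yields good performance for
essentially every function.  Whenever the data used for prediction is
correlated with multifunctionality, an algorithm can look accurate while
learning nothing function-specific.

This package implements the machinery to measure, exploit and control for
that bias.  It is aimed at computational biologists who run or benchmark
network-based gene function prediction and want to know how much of their
performance survives a degree-aware control.

## The core quantities

**Multifunctionality score.**  For gene *g* over annotation groups *i* with
in-group size `Num_in_i` and out-group size `Num_out_i`:

    MF(g) = Σ_{i : g ∈ group i}  1 / (Num_in_i · Num_out_i)

Ranking genes by decreasing MF is the *optimal gene ranking*: the single
fixed gene ordering that maximizes the mean ROC area (AUC) across all
groups.  (Exchanging adjacent genes g, h in any order changes the
group-mean AUC by a quantity proportional to MF(g) − MF(h), so descending
MF admits no improving transposition.)  A greedy analogue optimizing mean
precision in the top k (PPV@k) is also provided.

**Node degree and the IPN.**  Under a model where each gene carries an
interaction propensity *p_i* and pair (i, j) is linked with probability
proportional to *p_i p_j*, the row sums (node degree, `A_i`) recover the
propensity ranking, and the rank-one matrix built from the degree vector is
the best least-squares approximation of the network.  Thresholding the
self-outer product `A Aᵀ` to the original's sparsity (self-pairs included
in the budget, then discarded) gives the *individual property network*
(IPN): a network with no pair-specific information.  Degree rankings and
IPNs are the computational controls — any performance they achieve is
attributable to multifunctionality structure alone.

**Neighbor voting.**  The reference GBA predictor: a candidate gene is
scored by the sum of its association ranks to a group's training genes
divided by the sum of its ranks to all non-training genes, evaluated by
k-fold cross-validation with AUC / ROC50 / PPV@k / AUP / CCR.

**Degree-preserving null.**  Double-edge-swap randomization keeps every
gene's exact degree; re-running a predictor on many replicates yields a
per-group null distribution of performance "from multifunctionality alone"
and an add-one empirical p-value, far more conservative than the usual
label-permutation null.

## Worked example

Generate a synthetic benchmark in which interaction propensity is
rank-coupled (ρ = 0.9) to multifunctionality — bias, but no true
association signal — and audit it:

```python
import gba_bias as gb

c = gb.SynthConfig(n_genes=600, n_groups=60, size_min=30, size_max=120,
                   mf_skew=2.0, rho=0.9, sparsity=0.05,
                   propensity_sigma=1.5, seed=42)
a = gb.generate_annotations(c)
mf = gb.multifunctionality_scores(a)
net = gb.generate_network(c, mf)
result = gb.audit(net, a, seed=42, folds=10)
for k, v in result.summary().items():
    print(f"{k:35s} {v:.3f}")
```

prints

```
mean_degree_auc                     0.859
mean_real_auc                       0.842
mean_ipn_auc                        0.841
spearman_degree_mf                  0.855
spearman_degree_auc_vs_real_auc     0.808
n_learnable_groups                  60.000
```

Read: the "real" cross-validated neighbor-voting performance (0.842) is
matched by the degree-only ranking (0.859) and by the information-free IPN
(0.841), and per-group performance tracks the degree ranking (ρ = 0.81) —
exactly the signature of multifunctionality-driven performance.  On a
network with genuine, degree-free module signal the same audit shows the
real network far ahead of its IPN.

The same workflow is available from the shell:

```
gba-bias synth --preset pipj-biased --seed 42 -o data/
gba-bias audit data/network.tsv data/sets.gmt --seed 42 -o report/
gba-bias mf rank data/sets.gmt -o ranking.tsv
```

`gba-bias audit` writes per-gene MF scores, the optimal ranking, a
per-group table (degree AUC, real AUC, IPN AUC, optional degree-preserving
empirical p-values) and a JSON summary, each with a reproducibility
manifest.

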