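# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `gba_bias`, and what the synthetic benchmarks do and do
not establish.

## Multifunctionality score and optimal rankings

For an annotation matrix over a universe of N genes, the
multifunctionality score of gene g is

    MF(g) = Σ_{i : g ∈ group i} 1 / (Num_in_i · Num_out_i)

Groups that are empty or span the whole universe are excluded from the sum
(Num_out = 0 would make the term undefined) with a logged warning, rather
than clamped — this keeps the formula exact.

Descending MF order maximizes the group-averaged AUC over all fixed gene
orderings.  The argument is a transposition one: the group-mean AUC is a
sum of pairwise terms, and swapping adjacent genes g, h changes it by a
quantity proportional to MF(g) − MF(h) (groups containing both or neither
cancel).  Consequently all tie resolutions of equal-MF genes achieve the
same mean AUC; the package's exhaustive tests verify this on every
instance of up to 7 genes.

Tie policy: the default is "average" — tied genes share the mean of their
positions in metric computations, implemented by passing raw scores to
metrics that average ties.  "stable" resolves ties by universe order for
byte-reproducible emitted lists.  Nothing in the optimality result depends
on the choice.

The PPV-optimized ranking is a greedy forward selection: positions are
filled in order, each time choosing the gene with the largest marginal
gain in mean PPV@k.  Because a gene's gain at any position within the top
k reduces to its raw annotation count divided by k·(number of groups),
the greedy order is annotation count descending, ties broken by MF then
gene id; positions beyond k (zero gain) are ordered by MF then gene id.
This construction is one admissible reading of "PPV-optimized"; it is
validated against exhaustive search over all orderings on small instances,
not asserted as the only possible definition.

## Networks

Networks are dense symmetric non-negative matrices with zero diagonal.
Desk-scale universes (≤ a few thousand genes) make dense storage the
simplest correct choice; edge-list TSV and MatrixMarket I/O are provided.

Sparsification conventions, used everywhere a threshold appears:

* kept count = floor(sparsity × C(N, 2)) unordered off-diagonal pairs;
* candidates ranked by value descending, ties broken by lexicographic
  (i, j) pair order — outputs are bit-identical across runs;
* zero-valued (and missing) pairs are never selected: sparsification
  cannot create edges, and a fixed positive threshold cannot admit a zero
  score.

Top-overlap sparsification keeps an edge iff each endpoint is within the
other's top floor(per_gene_sparsity × (N−1)) partners — the mutual
nearest-neighbor rule.  It narrows the degree *range* but tends to
preserve degree *ranks*, which is why it fails as a bias correction.

Coexpression: Pearson correlation over pairwise-complete samples (minimum
overlap 3, else the pair is missing); edges from the positive tail by
default (`absolute=True` ranks by |r|); an optional one-sided
Fisher-transform p-value cut is intersected with the sparsity cut, so the
more stringent criterion wins.  Constant genes have no defined
correlations and contribute no edges.

IPN: score every pair (i, j), i ≤ j, *including self-pairs*, by
degree(i)·degree(j); keep the top (|E| + N) pairs — the original's edge
count plus one identity relationship per gene — then discard self-pairs.
Reading the sparsity budget as "after the addition of identity
relationships" literally means self-pairs compete for budget slots and do
not always win them (a mid-degree gene's self-product can rank below a
hub–leaf product); `count_self_pairs=False` removes them from the budget
for sensitivity analysis.  The IPN depends on the input only through its
degree vector, which is asserted as a property test.

The shared-function stress network adds edges greedily by annotation
overlap, weighting each shared group by 1/(1 + times already used); this
spreads edges across groups and reproduces the construction used to show
that mean precision-recall area rewards a handful of multifunctional genes.

## Neighbor voting

For a target group with training positives T, candidate c scores

    score(c) = Σ_{t ∈ T} rank_c(t)  /  Σ_{g ∉ T, g ≠ c} rank_c(g)

where rank_c(·) ranks the association weights of c across all other genes
(ties averaged, higher weight = higher rank; self-association excluded).
For binary networks the ranks are affine in the adjacency row — with
degree k and N' = N − 1, absent partners share rank (N'−k+1)/2 and present
partners share (N'−k) + (k+1)/2 — giving a closed-form fast path that the
tests check against the generic rankdata path.  Since the per-candidate
rank total is the constant N'(N'+1)/2, the denominator is that constant
minus the numerator, and the score is a monotone function of the summed
ranks to the training set.

Cross-validation: seeded round-robin assignment of shuffled positives to
folds (sizes differ by ≤1); negatives are never split.  Hidden positives
are evaluated against all non-member genes; the per-group value is the
unweighted mean over folds and dataset summaries are unweighted means over
groups.  Groups with fewer positives than folds are skipped and logged.

CCR follows the balanced-pool protocol: non-members are partitioned into
random blocks of the group's size (last block padded by resampling), each
balanced pool is classified at the top half, and the CCR is averaged over
blocks.

Metric conventions: AUC is the Mann–Whitney pair statistic with half-credit
ties.  ROC50 counts pairwise wins against only the 50 highest-scoring
negatives (boundary ties among negatives broken by input position),
normalized by 50·P; with ≤50 negatives it equals AUC.  PPV@k uses the
expected true-positive count when a tie block straddles rank k.  AUP is
average precision after stable tie resolution.

## Degree-preserving null and diagnostics

Randomization performs swap_factor × |E| *attempted* double-edge swaps
(default 100×): two random edges (a,b), (c,d), randomly oriented, are
rewired to (a,d), (c,b) unless a self-loop or multi-edge would result.
Multi-edges and self-loops are forbidden throughout.  Degenerate graphs
with no admissible swap (triangle, perfect star) are returned unchanged.
The inner loop is numba-compiled with a pure-Python fallback.

Empirical p-values use the add-one estimator (1 + #{samples ≥ observed}) /
(1 + replicates) — one-sided, performance ≥ null — with
Benjamini–Hochberg adjustment reported alongside raw values.  When many
groups are tested against the same network, the replicate networks are
shared across groups, making the cost linear in replicates.

The bias report tabulates, per group, the degree-ranking AUC, the real
predictor's AUC and the extremity |degree AUC − 0.5| (predictable groups
have members that are unusually multi- OR mono-functional — the
triangular dependence), plus the global Spearman correlations
degree-vs-MF and degree-AUC-vs-real-AUC.

## Semantic similarity

Link quality without a learning step: endpoint term-set overlap as Dice
2|T1∩T2|/(|T1|+|T2|) (default), Jaccard |T1∩T2|/|T1∪T2|, raw overlap
count, and the literal "half-Dice" |T1∩T2|/(|T1|+|T2|).  The field's
"Dice-Jaccard" usage is ambiguous between these normalizations, so the
measure name always travels with the result and no single reading is
asserted.  Termless genes score 0.  The random baseline samples unordered
non-self pairs with replacement.

## Synthetic study conditions

The generators are pure functions of (config, seed); independent
substreams are derived per generator from a single seed.

* **Annotations**: group sizes log-uniform in [size_min, size_max]
  (annotation sizes are heavy-tailed); members drawn without replacement
  with propensity ∝ exp(mf_skew · z), z ~ N(0,1) per gene.  Skew 0 is
  exchangeable; skew 2 puts over half of all memberships in the top decile
  of genes — the concentration regime where bias is strong.
* **Networks**: propensity-product model.  Per-gene propensity
  p = exp(σ·u) with u a Gaussian-copula blend of the MF ranks (weight ρ)
  and independent noise; the copula makes ρ a rank-correlation target
  regardless of marginals.  Edge probability min(1, s·p_i·p_j) with s
  solved by bisection so the expected edge count hits the target sparsity;
  an exact-count mode samples a fixed |E|.  σ = 1 by default (broad,
  log-normal degree heterogeneity); the bias benchmark uses σ = 1.5 for
  heavier-tailed degrees.
* **Planted modules** overwrite within-group pairs at a stated density
  (1.0 = clique).  The degree-free signal condition uses groups that
  *partition* the universe into equal blocks, every block planted as a
  clique on a uniform-propensity background — total degree is then nearly
  uniform, so the IPN carries no usable information.
* **Expression**: latent-factor model, module genes load λ on a shared
  factor plus unit noise.

Benchmark problem sizes (chosen as realistic desk-scale analogues of the
published regimes): the bias condition uses 1000 genes, 100 groups of
50–200, sparsity 5% (mean degree ≈ 50, comparable connectivity to a
15k-gene network at the conventional 0.5%), skew 2, ρ = 0.9, 10-fold CV;
the signal condition uses 500 genes in twenty 25-gene planted cliques on a
2% background; null calibration uses 1000 genes at 0.5% sparsity, 50
groups, 200 replicates.  At much sparser settings neighbor voting becomes
edge-count-noise dominated and its per-group AUC decouples from the degree
ranking even when the underlying propensities are fully degree-driven —
the bias is still present but the desk-scale correlation signature needs
adequate connectivity to be visible.

What the synthetic results do **not** show: real annotation corpora have
ontology structure (nested, correlated groups), inspection bias, and
platform-dependent missingness that the generators do not emulate; passing
the synthetic signatures demonstrates the machinery's correctness and
calibration, not the magnitude of bias in any particular real dataset.

## Known limitations

* Degree-preserving rewiring requires binary networks; weighted networks
  must be binarized or label-permuted (weighted degree-preserving
  rewiring is out of scope).
* The double-edge-swap chain is run for a fixed attempt budget, not to a
  certified mixing bound; the default 100×|E| is the conventional choice
  and empirically moves well over half of all edges on the fixtures.
* The neighbor-voting denominator excludes the candidate's
  self-association; including it is a near-constant shift and does not
  change rankings materially, but is not offered as an option.
* Gene identifiers are matched by exact string (optional case folding);
  no alias resolution.
* Dense network storage bounds practical universes to a few thousand
  genes — adequate for the audits and benchmarks the package targets.
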