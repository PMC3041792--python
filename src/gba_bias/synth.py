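"""Synthetic annotation matrices, networks and expression data.

The generators reproduce the statistical structure the bias diagnostics
are about, with controllable knobs:

* annotations with a tunable concentration of memberships on a few genes
  (``mf_skew``: per-gene membership propensity proportional to
  exp(mf_skew * z), z standard normal -- skew 0 is exchangeable, skew 2
  concentrates most memberships in the top decile);
* networks from the propensity product model: each gene carries a
  propensity p_i and pair (i, j) is linked with probability proportional
  to p_i * p_j, scaled to a target sparsity -- the model under which node
  degree recovers the propensity ranking and rank-one structure explains
  the network.  ``rho`` couples the propensities to multifunctionality
  through a Gaussian copula on ranks, so rho is interpretable as a target
  rank correlation whatever the marginals;
* planted modules: chosen groups get their within-group pairs overwritten
  to a stated density (cliques at density 1.0) -- genuine, degree-free
  association signal for power checks;
* expression matrices from a latent-factor model, so coexpression
  construction can be exercised end to end.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from .annotations import AnnotationMatrix, GeneUniverse
from .multifunctionality import MultifunctionalityScores
from .networks import ExpressionMatrix, Network

__all__ = [
    "SynthConfig",
    "generate_annotations",
    "generate_network",
    "partition_annotations",
    "plant_modules",
    "generate_expression",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Group sizes are drawn log-uniformly between ``size_min`` and
    ``size_max`` (annotation group sizes are heavy-tailed in real
    ontologies).  ``propensity_sigma`` sets the spread of the log-normal
    interaction propensities (1.0 gives the broad degree heterogeneity
    typical of association networks).  ``planted_modules`` maps group ids
    to within-group edge densities.
    """

    n_genes: int = 1000
    n_groups: int = 100
    size_min: int = 20
    size_max: int = 100
    mf_skew: float = 1.0
    rho: float = 0.0
    sparsity: float = 0.005
    propensity_sigma: float = 1.0
    planted_modules: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_groups < 1:
            raise ValueError("need at least 2 genes and 1 group")
        if not (1 <= self.size_min <= self.size_max):
            raise ValueError("require 1 <= size_min <= size_max")
        if self.size_max > self.n_genes:
            raise ValueError("size_max exceeds n_genes")
        if self.mf_skew < 0:
            raise ValueError("mf_skew must be >= 0")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if not (0.0 < self.sparsity < 1.0):
            raise ValueError("sparsity must be in (0, 1)")
        for gid, dens in self.planted_modules.items():
            if not (0.0 <= dens <= 1.0):
                raise ValueError(f"module density for {gid!r} must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream per generator, derived from the one seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _gene_ids(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"g{i:0{width}d}" for i in range(n))


def _group_ids(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"G{j:0{width}d}" for j in range(n))


def generate_annotations(c: SynthConfig) -> AnnotationMatrix:
    """Annotation matrix with concentration-controlled memberships.

    Each group's size is log-uniform in [size_min, size_max]; its members
    are drawn without replacement with per-gene probability proportional
    to exp(mf_skew * z_g), z_g standard normal per gene.  mf_skew = 0
    gives exchangeable (uniform) membership.
    """
    rng = c.rng(1)
    z = rng.standard_normal(c.n_genes)
    propensity = np.exp(c.mf_skew * z)
    propensity /= propensity.sum()
    universe = GeneUniverse(_gene_ids(c.n_genes))
    membership = np.zeros((c.n_genes, c.n_groups), dtype=bool)
    log_sizes = rng.uniform(np.log(c.size_min), np.log(c.size_max), size=c.n_groups)
    sizes = np.clip(np.round(np.exp(log_sizes)).astype(int), c.size_min, c.size_max)
    for j in range(c.n_groups):
        members = rng.choice(c.n_genes, size=sizes[j], replace=False, p=propensity)
        membership[members, j] = True
    return AnnotationMatrix(universe, _group_ids(c.n_groups), membership)


def partition_annotations(c: SynthConfig) -> AnnotationMatrix:
    """Annotation groups that partition the universe into equal blocks.

    Uses ``size_min`` as the block size (``size_min == size_max`` required)
    and ignores ``n_groups``/``mf_skew``: every gene lands in exactly one
    group, so planting every group as a module yields a network with
    (near-)uniform degrees -- the degree-free signal fixture.
    """
    if c.size_min != c.size_max:
        raise ValueError("partition requires size_min == size_max")
    size = c.size_min
    n_groups = c.n_genes // size
    if n_groups < 1:
        raise ValueError("block size exceeds universe")
    rng = c.rng(5)
    perm = rng.permutation(c.n_genes)
    membership = np.zeros((c.n_genes, n_groups), dtype=bool)
    for j in range(n_groups):
        membership[perm[j * size : (j + 1) * size], j] = True
    return AnnotationMatrix(
        GeneUniverse(_gene_ids(c.n_genes)), _group_ids(n_groups), membership
    )


def _copula_blend(
    mf_score: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent normal scores rank-coupled to MF at target correlation rho."""
    n = mf_score.size
    # random tie-break so unannotated (MF = 0) genes don't form one block
    order = np.lexsort((rng.permutation(n), mf_score))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    z_mf = scipy.stats.norm.ppf((ranks - 0.5) / n)
    z_noise = rng.standard_normal(n)
    return rho * z_mf + np.sqrt(1.0 - rho**2) * z_noise


def generate_network(
    c: SynthConfig,
    mf: MultifunctionalityScores | None = None,
    annotations: AnnotationMatrix | None = None,
    exact_count: bool = False,
) -> Network:
    """Binary network from the propensity product (p_i * p_j) model.

    Pair (i, j) is linked with probability min(1, s * p_i * p_j), with the
    scale s solved numerically so the expected edge count matches the
    target sparsity.  With ``exact_count`` the target number of edges is
    sampled without replacement with those probabilities as weights
    (tests needing a fixed |E|).  Planted modules then overwrite
    within-group pairs with independent links at the stated density.
    """
    if c.rho > 0 and mf is None:
        raise ValueError("rho > 0 requires multifunctionality scores")
    rng = c.rng(2)
    if c.rho > 0:
        assert mf is not None
        if len(mf.universe) != c.n_genes:
            raise ValueError("mf scores do not match n_genes")
        u = _copula_blend(mf.score, c.rho, rng)
    else:
        u = rng.standard_normal(c.n_genes)
    p = np.exp(c.propensity_sigma * u)
    rows, cols = np.triu_indices(c.n_genes, 1)
    raw = p[rows] * p[cols]
    n_pairs = raw.size
    target = int(round(c.sparsity * n_pairs))
    if target < 1:
        raise ValueError("target sparsity yields zero edges")
    if np.count_nonzero(raw) < target:
        raise ValueError(
            "unreachable sparsity: propensities too concentrated "
            f"({np.count_nonzero(raw)} positive pair scores < {target} target edges)"
        )

    def expected(scale: float) -> float:
        return float(np.minimum(1.0, scale * raw).sum())

    lo, hi = 0.0, 1.0 / raw.max()
    while expected(hi) < target:
        hi *= 2.0
    scale = scipy.optimize.brentq(lambda s: expected(s) - target, lo, hi, xtol=1e-15)
    prob = np.minimum(1.0, scale * raw)
    if exact_count:
        chosen = rng.choice(n_pairs, size=target, replace=False, p=prob / prob.sum())
        mask = np.zeros(n_pairs, dtype=bool)
        mask[chosen] = True
    else:
        mask = rng.random(n_pairs) < prob
    w = np.zeros((c.n_genes, c.n_genes))
    w[rows[mask], cols[mask]] = 1.0
    w += w.T
    net = Network(GeneUniverse(_gene_ids(c.n_genes)), w, binary=True)
    if c.planted_modules:
        if annotations is None:
            raise ValueError("planted modules name annotation groups; pass annotations")
        net = plant_modules(net, annotations, c.planted_modules, seed=c.seed)
    return net


def plant_modules(
    net: Network,
    a: AnnotationMatrix,
    modules: dict[str, float],
    seed: int,
) -> Network:
    """Overwrite within-group pairs to the stated density (1.0 = clique)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    w = net.weights.copy()
    for gid, density in modules.items():
        j = a.group_ids.index(gid)
        idx = np.flatnonzero(a.membership[:, j])
        ri, ci = np.triu_indices(idx.size, 1)
        links = (rng.random(ri.size) < density).astype(float)
        w[idx[ri], idx[ci]] = links
        w[idx[ci], idx[ri]] = links
    return Network(net.universe, w, binary=True)


def generate_expression(
    c: SynthConfig,
    modules: Sequence[Sequence[int]] | Sequence[Sequence[str]] = (),
    n_samples: int = 50,
    loading: float = 0.8,
) -> ExpressionMatrix:
    """Latent-factor expression: module genes share a factor, rest is noise.

    Module genes g get x_g = loading * f + sqrt(1 - loading^2) * noise with
    a per-module factor f; other genes are unit noise.  Overlapping modules
    are allowed (later modules overwrite earlier loadings).
    """
    if not (0.0 <= loading <= 1.0):
        raise ValueError("loading must be in [0, 1]")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = c.rng(4)
    universe = GeneUniverse(_gene_ids(c.n_genes))
    values = rng.standard_normal((c.n_genes, n_samples))
    for module in modules:
        idx = np.array(
            [universe.index(g) if isinstance(g, str) else int(g) for g in module],
            dtype=np.intp,
        )
        factor = rng.standard_normal(n_samples)
        noise = rng.standard_normal((idx.size, n_samples))
        values[idx] = loading * factor + np.sqrt(1.0 - loading**2) * noise
    samples = tuple(f"s{k:03d}" for k in range(n_samples))
    return ExpressionMatrix(universe, samples, values)
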