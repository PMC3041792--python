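"""Gene association networks: construction, sparsification, IPNs.

Networks are stored as dense symmetric non-negative matrices with a zero
diagonal over an ordered gene universe (desk-scale universes make dense
storage simple and fast; edge-list and MatrixMarket I/O are provided for
interchange).  Sparsification keeps a stated fraction of unordered
off-diagonal pairs; all thresholds break ties deterministically by
descending value then lexicographic (i, j) pair order, so outputs are
bit-identical across runs.

The individual property network (IPN) is the central control construct:
the network built by thresholding the self-outer product of the degree
vector to the original's sparsity.  Under a model where gene i takes part
in an interaction with inherent propensity p_i (edge probability
proportional to p_i * p_j), the rank-one matrix built from row sums is the
best least-squares approximation of the original association matrix, and
contains no pair-specific information: any prediction performance it
supports is attributable to node degree (hence multifunctionality) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import scipy.stats

from .annotations import AnnotationMatrix, GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "DegreeVector",
    "ExpressionMatrix",
    "node_degree",
    "build_coexpression",
    "threshold_sparsify",
    "top_overlap_sparsify",
    "aggregate",
    "build_ipn",
    "build_shared_function_network",
    "read_edge_list",
    "write_edge_list",
    "read_dense_tsv",
    "read_mtx",
    "read_expression",
]


@dataclass
class Network:
    """Symmetric non-negative gene association matrix with zero diagonal."""

    universe: GeneUniverse
    weights: np.ndarray
    binary: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.universe)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.binary and not set(np.unique(w)) <= {0.0, 1.0}:
            raise ValueError("binary network has non-0/1 weights")

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def n_edges(self) -> int:
        """Number of unordered pairs with nonzero weight."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def sparsity(self) -> float:
        n = self.n_genes
        return self.n_edges / (n * (n - 1) / 2)

    def edge_array(self) -> np.ndarray:
        """(E, 2) array of gene index pairs with i < j, lexicographic."""
        i, j = np.nonzero(np.triu(self.weights, 1))
        return np.column_stack([i, j])

    def edge_list(self) -> list[tuple[str, str, float]]:
        ids = self.universe.gene_ids
        return [
            (ids[i], ids[j], float(self.weights[i, j])) for i, j in self.edge_array()
        ]

    def binarize(self) -> "Network":
        return Network(self.universe, (self.weights > 0).astype(float), binary=True)


@dataclass
class DegreeVector:
    """Weighted node degree: per-gene row sum of the association matrix."""

    universe: GeneUniverse
    degree: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.universe.gene_ids, "degree": self.degree})


@dataclass
class ExpressionMatrix:
    """Real gene x sample values; NaN marks missing measurements."""

    universe: GeneUniverse
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.universe), len(self.samples)):
            raise ValueError("values must be genes x samples")
        self.values = v


def node_degree(n: Network) -> DegreeVector:
    """Per-gene weighted degree (connection count for binary networks)."""
    return DegreeVector(n.universe, n.weights.sum(axis=1))


def _triu_pairs(n: int, *, include_diagonal: bool = False) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, 0 if include_diagonal else 1)


def _top_pairs(
    values: np.ndarray, rows: np.ndarray, cols: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-m pairs by value desc, ties by (row, col) lexicographic.

    NaN and exactly-zero pairs are never selected: sparsification must not
    create edges where the input has none, and a fixed positive threshold
    cannot admit a zero score.
    """
    vals = np.where(np.isnan(values) | (values == 0), -np.inf, values)
    order = np.lexsort((cols, rows, -vals))
    keep = order[:m]
    keep = keep[np.isfinite(vals[keep])]
    return rows[keep], cols[keep]


def threshold_sparsify(
    m: np.ndarray | Network,
    sparsity: float = 0.005,
    universe: GeneUniverse | None = None,
) -> Network:
    """Keep the top `sparsity` fraction of off-diagonal pairs globally.

    The kept count is floor(sparsity * C(N, 2)); output is binary.
    """
    if isinstance(m, Network):
        universe = m.universe
        w = m.weights
    else:
        w = np.asarray(m, dtype=float)
        if universe is None:
            universe = GeneUniverse(tuple(f"g{i}" for i in range(w.shape[0])))
    if not np.allclose(w, w.T, equal_nan=True):
        raise ValueError("input matrix must be symmetric")
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must be in (0, 1)")
    n = w.shape[0]
    rows, cols = _triu_pairs(n)
    n_keep = int(np.floor(sparsity * len(rows)))
    ri, ci = _top_pairs(w[rows, cols], rows, cols, n_keep)
    out = np.zeros_like(w)
    out[ri, ci] = 1.0
    out[ci, ri] = 1.0
    np.fill_diagonal(out, 0.0)
    return Network(universe, out, binary=True)


def top_overlap_sparsify(
    m: np.ndarray | Network,
    per_gene_sparsity: float = 0.005,
    universe: GeneUniverse | None = None,
) -> Network:
    """Mutual top-partner sparsification (the "top overlap" method).

    Each gene nominates its top floor(per_gene_sparsity * (N-1)) partners by
    value; an edge is kept iff both endpoints nominate each other.  Genes
    whose per-gene list is shorter than 1 contribute no edges.  The method
    constrains node degree to a narrow range compared with global
    thresholding, but tends to preserve node-degree *ranks*.
    """
    if isinstance(m, Network):
        universe = m.universe
        w = m.weights
    else:
        w = np.asarray(m, dtype=float)
        if universe is None:
            universe = GeneUniverse(tuple(f"g{i}" for i in range(w.shape[0])))
    if not np.allclose(w, w.T, equal_nan=True):
        raise ValueError("input matrix must be symmetric")
    n = w.shape[0]
    k = int(np.floor(per_gene_sparsity * (n - 1)))
    out = np.zeros_like(w)
    if k >= 1:
        vals = np.where(np.isnan(w), -np.inf, w).copy()
        np.fill_diagonal(vals, -np.inf)
        nominates = np.zeros((n, n), dtype=bool)
        idx = np.arange(n)
        for i in range(n):
            order = np.lexsort((idx, -vals[i]))[:k]
            order = order[np.isfinite(vals[i, order])]
            nominates[i, order] = True
        mutual = nominates & nominates.T
        out[mutual] = 1.0
    np.fill_diagonal(out, 0.0)
    return Network(universe, out, binary=True)


def build_coexpression(
    e: ExpressionMatrix,
    sparsity: float = 0.005,
    max_fisher_p: float | None = None,
    *,
    absolute: bool = False,
    min_overlap: int = 3,
) -> Network:
    """Binary coexpression network from an expression matrix.

    Pearson correlations are computed over pairwise-complete samples (at
    least ``min_overlap`` shared samples, else the pair is missing).  An
    edge is kept iff its correlation is in the top ``sparsity`` fraction of
    all unordered pairs AND, when ``max_fisher_p`` is given, its one-sided
    Fisher-transform p-value is at most that bound -- whichever criterion
    is more stringent wins.  Positive-tail selection by default;
    ``absolute=True`` ranks by |r|.  Constant-expression genes have no
    defined correlations and contribute no edges.
    """
    if e.values.shape[1] < 3:
        raise ValueError("at least 3 samples required for correlation")
    if not (0 < sparsity < 1):
        raise ValueError("sparsity must be in (0, 1)")
    df = pd.DataFrame(e.values.T)  # samples x genes
    corr = df.corr(min_periods=min_overlap).to_numpy()
    n = len(e.universe)
    const = np.nanstd(e.values, axis=1) == 0
    if const.any():
        logger.info("%d constant-expression genes have no correlations", int(const.sum()))
        corr[const, :] = np.nan
        corr[:, const] = np.nan
    # pairwise-complete sample counts for the Fisher transform
    obs = (~np.isnan(e.values)).astype(float)
    counts = obs @ obs.T
    ranked = np.abs(corr) if absolute else corr
    if max_fisher_p is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.arctanh(np.clip(corr, -1 + 1e-15, 1 - 1e-15))
            se_df = counts - 3
            stat = np.where(se_df > 0, z * np.sqrt(np.maximum(se_df, 0)), np.nan)
            pvals = scipy.stats.norm.sf(np.abs(stat) if absolute else stat)
        ranked = np.where(pvals <= max_fisher_p, ranked, np.nan)
    rows, cols = _triu_pairs(n)
    n_keep = int(np.floor(sparsity * len(rows)))
    ri, ci = _top_pairs(ranked[rows, cols], rows, cols, n_keep)
    out = np.zeros((n, n))
    out[ri, ci] = 1.0
    out[ci, ri] = 1.0
    return Network(e.universe, out, binary=True)


def aggregate(nets: Sequence[Network], mode: Literal["sum", "union"] = "sum") -> Network:
    """Combine networks over a shared universe.

    "sum": weight(i, j) = sum of the input weights (the count of supporting
    networks when inputs are binary).  "union": binary OR of the links
    present in any input.
    """
    if not nets:
        raise ValueError("aggregate requires at least one network")
    universe = nets[0].universe
    if any(net.universe != universe for net in nets[1:]):
        logger.info("aggregating networks over different universes: zero-filled union")
        universe = GeneUniverse.from_iterable(
            g for net in nets for g in net.universe.gene_ids
        )
    total = np.zeros((len(universe), len(universe)))
    for net in nets:
        idx = universe.indices(net.universe.gene_ids)
        total[np.ix_(idx, idx)] += net.weights
    if mode == "union":
        return Network(universe, (total > 0).astype(float), binary=True)
    if mode != "sum":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return Network(universe, total, binary=False)


def build_ipn(n: Network, *, count_self_pairs: bool = True) -> Network:
    """Individual property network: thresholded degree-vector outer product.

    Every pair (i, j), i <= j, is scored by degree(i) * degree(j),
    *including* self-pairs; the top pairs are kept so that the kept count
    equals the original's edge count plus one self-pair per gene (the
    original's sparsity after the addition of identity relationships), and
    self-pairs are then discarded from the returned binary network.
    ``count_self_pairs=False`` drops self-pairs from the budget instead
    (sensitivity analysis).  The IPN depends on the input only through its
    degree vector.
    """
    d = n.weights.sum(axis=1)
    if not d.any():
        raise ValueError("all-zero degrees: no IPN definable")
    ngene = n.n_genes
    budget = n.n_edges + (ngene if count_self_pairs else 0)
    rows, cols = _triu_pairs(ngene, include_diagonal=count_self_pairs)
    scores = d[rows] * d[cols]
    ri, ci = _top_pairs(scores, rows, cols, budget)
    out = np.zeros_like(n.weights)
    out[ri, ci] = 1.0
    out[ci, ri] = 1.0
    np.fill_diagonal(out, 0.0)
    return Network(n.universe, out, binary=True)


def build_shared_function_network(
    a: AnnotationMatrix, n_edges: int = 100
) -> Network:
    """Greedy network of pairs sharing many annotation groups.

    Edges are added one at a time, each time joining the unconnected pair
    with the largest sum over shared groups of 1 / (1 + times the group was
    already used in the network); usage counts update after every addition.
    The reweighting spreads edges across groups instead of exhausting one
    large group.  This is the stress-test construction showing that a tiny,
    function-packed network can post a respectable mean precision-recall
    area from a handful of multifunctional genes.
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    m = a.membership.astype(float)
    ngene, ngroups = m.shape
    used = np.zeros(ngroups)
    out = np.zeros((ngene, ngene))
    rows, cols = _triu_pairs(ngene)
    added = 0
    for _ in range(n_edges):
        group_w = 1.0 / (1.0 + used)
        scores = (m * group_w) @ m.T
        pair_scores = scores[rows, cols]
        pair_scores[out[rows, cols] > 0] = -np.inf
        best = np.lexsort((cols, rows, -pair_scores))[0]
        if not np.isfinite(pair_scores[best]) or pair_scores[best] <= 0:
            logger.warning(
                "only %d scoring pairs available; requested %d edges", added, n_edges
            )
            break
        i, j = rows[best], cols[best]
        out[i, j] = out[j, i] = 1.0
        used += a.membership[i] & a.membership[j]
        added += 1
    return Network(a.universe, out, binary=True)


# ---------------------------------------------------------------------------
# I/O


def read_edge_list(
    path: str | Path, universe: GeneUniverse | None = None
) -> Network:
    """TSV edge list: gene_i <TAB> gene_j [<TAB> weight]; symmetrized."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    w = df[2].astype(float).to_numpy() if df.shape[1] >= 3 else np.ones(len(df))
    if universe is None:
        universe = GeneUniverse.from_iterable(
            pd.concat([df[0], df[1]]).tolist()
        )
    out = np.zeros((len(universe), len(universe)))
    known = set(universe.gene_ids)
    dropped = 0
    for gi, gj, wij in zip(df[0], df[1], w):
        if gi == gj:
            continue
        if gi not in known or gj not in known:
            dropped += 1
            continue
        i, j = universe.index(gi), universe.index(gj)
        out[i, j] = out[j, i] = wij
    if dropped:
        logger.info("dropped %d edges outside the universe", dropped)
    binary = bool(set(np.unique(out)) <= {0.0, 1.0})
    return Network(universe, out, binary=binary)


def write_edge_list(n: Network, path: str | Path) -> None:
    """Emit edges as TSV with gene_i < gene_j in universe order."""
    with open(path, "w") as fh:
        for gi, gj, wij in n.edge_list():
            fh.write(f"{gi}\t{gj}\t{wij:g}\n")


def read_dense_tsv(path: str | Path) -> Network:
    """Dense symmetric matrix TSV with gene ids as header and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column gene ids differ")
    universe = GeneUniverse(tuple(str(g) for g in df.index))
    w = df.to_numpy(dtype=float)
    binary = bool(set(np.unique(w)) <= {0.0, 1.0})
    return Network(universe, w, binary=binary)


def read_mtx(path: str | Path, genes: Iterable[str] | None = None) -> Network:
    """MatrixMarket symmetric sparse matrix; gene ids optional (g0, g1, ...)."""
    mat = scipy.io.mmread(str(path))
    w = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
    w = np.maximum(w, w.T)  # tolerate one-triangle storage
    if genes is None:
        universe = GeneUniverse(tuple(f"g{i}" for i in range(w.shape[0])))
    else:
        universe = GeneUniverse(tuple(genes))
    binary = bool(set(np.unique(w)) <= {0.0, 1.0})
    return Network(universe, w, binary=binary)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Expression TSV: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    universe = GeneUniverse(tuple(str(g) for g in df.index))
    return ExpressionMatrix(
        universe, tuple(str(s) for s in df.columns), df.to_numpy(dtype=float)
    )


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(e.values, index=list(e.universe.gene_ids), columns=list(e.samples))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")
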