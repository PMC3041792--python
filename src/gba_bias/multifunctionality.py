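"""Per-gene multifunctionality scores and optimal fixed gene rankings.

The multifunctionality (MF) score of a gene is the sum, over the annotation
groups it belongs to, of 1 / (Num_in * Num_out), where Num_in is the number
of genes inside the group and Num_out the number outside.  Ignoring the
weights this is simply the number of annotations a gene has; the weighting
counts each membership by how much the gene contributes to that group.

Ranking genes by decreasing MF score is the single fixed gene ordering that
maximizes the mean ROC area over all annotation groups: exchanging two
adjacent genes g, h in any ordering changes the group-averaged AUC by a
quantity proportional to MF(g) - MF(h), so a descending-MF order cannot be
improved by any transposition.  An analogous greedy construction is
provided when the optimization criterion is precision in the top k (PPV@k)
instead of AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats

from .annotations import AnnotationMatrix, GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "MultifunctionalityScores",
    "GeneRanking",
    "multifunctionality_scores",
    "optimal_ranking_auc",
    "optimal_ranking_ppv",
    "group_multifunctionality",
]

TiePolicy = Literal["average", "stable"]


@dataclass
class MultifunctionalityScores:
    universe: GeneUniverse
    score: np.ndarray  # MF score per gene, non-negative
    n_groups_per_gene: np.ndarray  # raw annotation count per gene

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.universe.gene_ids,
                "mf_score": self.score,
                "n_groups": self.n_groups_per_gene,
            }
        )


@dataclass
class GeneRanking:
    """A total order over a gene universe, defined by a score per gene.

    ``order`` lists gene indices by decreasing score.  Under the "average"
    tie policy, tied genes share the mean of their positions in all
    downstream metric computations; under "stable", ties are broken by
    universe order (exact reproducibility of emitted lists).
    """

    universe: GeneUniverse
    score: np.ndarray
    tie_policy: TiePolicy = "average"

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.universe),):
            raise ValueError("one score per universe gene required")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("ranking scores must be finite")

    @property
    def order(self) -> np.ndarray:
        """Gene indices by decreasing score (stable within ties)."""
        return np.argsort(-self.score, kind="stable")

    def effective_scores(self) -> np.ndarray:
        """Score vector for metric evaluation under the declared tie policy.

        "average" keeps raw scores (metrics handle ties by averaging);
        "stable" perturbs ties into the strict universe-order ranking.
        """
        if self.tie_policy == "average":
            return self.score
        n = len(self.score)
        out = np.empty(n)
        out[self.order] = np.arange(n, 0, -1, dtype=float)
        return out

    def to_frame(self) -> pd.DataFrame:
        order = self.order
        return pd.DataFrame(
            {
                "gene": [self.universe.gene_ids[i] for i in order],
                "score": self.score[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def _valid_groups(a: AnnotationMatrix) -> np.ndarray:
    """Mask of groups with 1 <= Num_in < |universe| (Num_out > 0)."""
    sizes = a.group_sizes
    valid = (sizes >= 1) & (sizes < a.n_genes)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "%d groups empty or spanning the whole universe excluded from MF scores",
            n_bad,
        )
    return valid


def multifunctionality_scores(a: AnnotationMatrix) -> MultifunctionalityScores:
    """MF(g) = sum over groups containing g of 1 / (Num_in * Num_out).

    Groups that are empty or span the whole universe (Num_out = 0 makes the
    term undefined) are excluded with a warning.
    """
    valid = _valid_groups(a)
    m = a.membership[:, valid]
    nin = a.group_sizes[valid].astype(float)
    nout = a.complement_sizes[valid].astype(float)
    weights = 1.0 / (nin * nout)
    score = m @ weights
    return MultifunctionalityScores(
        universe=a.universe,
        score=score,
        n_groups_per_gene=a.membership.sum(axis=1),
    )


def optimal_ranking_auc(
    a: AnnotationMatrix, tie_policy: TiePolicy = "average"
) -> GeneRanking:
    """The fixed gene ranking maximizing mean AUC across all groups.

    This is exactly the descending multifunctionality-score order; genes
    with no annotations score 0 and rank last (tied).
    """
    mf = multifunctionality_scores(a)
    return GeneRanking(a.universe, mf.score, tie_policy=tie_policy)


def optimal_ranking_ppv(a: AnnotationMatrix, k: int = 50) -> GeneRanking:
    """Greedy fixed ranking optimizing mean PPV@k across groups.

    Positions are filled front-to-back, each time choosing the gene whose
    placement adds the most to the group-averaged precision in the top k.
    A gene's marginal gain at any position within the top k is proportional
    to its raw annotation count, so the greedy order is: annotation count
    descending, ties broken by MF score then gene id; positions beyond k
    contribute nothing and are ordered by MF score then gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > a.n_genes:
        raise ValueError(f"k={k} exceeds universe size {a.n_genes}")
    mf = multifunctionality_scores(a)
    counts = a.membership.sum(axis=1)
    ids = np.array(a.universe.gene_ids)
    # lexsort: last key is primary
    head_order = np.lexsort((ids, -mf.score, -counts))[:k]
    tail_mask = np.ones(a.n_genes, dtype=bool)
    tail_mask[head_order] = False
    tail_idx = np.flatnonzero(tail_mask)
    tail_order = tail_idx[np.lexsort((ids[tail_idx], -mf.score[tail_idx]))]
    order = np.concatenate([head_order, tail_order])
    score = np.empty(a.n_genes)
    score[order] = np.arange(a.n_genes, 0, -1, dtype=float)
    return GeneRanking(a.universe, score, tie_policy="stable")


def group_multifunctionality(a: AnnotationMatrix, r: GeneRanking) -> pd.DataFrame:
    """Rank groups by how well the fixed ranking predicts their membership.

    Returns one AUC per group (the ranking used as a predictor of group
    membership), sorted descending; highly ranked groups are the "most
    multifunctional" -- their members tend to be highly multifunctional.
    """
    from .prediction import auc

    if r.universe != a.universe:
        raise ValueError("ranking universe does not match annotation universe")
    scores = r.effective_scores()
    rows = []
    for j, gid in enumerate(a.group_ids):
        labels = a.membership[:, j]
        if labels.all() or not labels.any():
            continue
        rows.append((gid, int(labels.sum()), auc(labels, scores)))
    df = pd.DataFrame(rows, columns=["group", "size", "auc"])
    return df.sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)


def spearman_to_ranking(r1: GeneRanking, r2: GeneRanking) -> float:
    """Spearman correlation between two rankings of the same universe.

    The recommended single-function audit: compare the ranking an algorithm
    produced to the optimal (multifunctionality) ranking; high similarity
    means the algorithm's output cannot be assumed function-specific.
    """
    if r1.universe != r2.universe:
        raise ValueError("rankings are over different universes")
    rho = scipy.stats.spearmanr(r1.score, r2.score).statistic
    return float(rho)
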