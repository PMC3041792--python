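"""Guilt-by-association prediction and its evaluation metrics.

Neighbor voting scores a candidate gene for a target group by the sum of
its association ranks to the group's training genes, divided by the sum of
its association ranks to all genes outside the training set.  Association
ranks are per-candidate ranks of the association weights across the
universe (self-association excluded, ties averaged, higher weight = higher
rank); for binary networks the ranks have a closed form in the candidate's
degree, which is used as a fast path.  Prediction quality is summarized
per group over k-fold cross-validation with any of: ROC area (AUC, the
main measure; 0.5 is chance), ROC50 (truncated at the 50th false
positive), PPV@k (precision in the top k), AUP (area under the
precision-recall curve), and CCR (correct classification rate on balanced
pools).

Fixed-ranking evaluation applies one gene ordering -- e.g. node degree or
the optimal multifunctionality ranking -- as the score vector for every
group, with no training; comparing it to cross-validated performance is
the core bias diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .annotations import AnnotationMatrix
from .multifunctionality import GeneRanking
from .networks import Network

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "auc",
    "roc50",
    "ppv_at_k",
    "aup",
    "ccr",
    "balanced_ccr_protocol",
    "assign_folds",
    "neighbor_voting",
    "neighbor_voting_scores",
    "evaluate_fixed_ranking",
    "learnable_filter",
    "get_metric",
]


# ---------------------------------------------------------------------------
# Metrics


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    labels = np.asarray(labels, dtype=bool)
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("metric undefined without both positives and negatives")
    return labels, pos, neg


def auc(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """ROC area in Mann-Whitney form.

    The fraction of (positive, negative) pairs in which the positive scores
    higher, ties counting 1/2.
    """
    labels, pos, neg = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels].sum() - pos * (pos + 1) / 2) / (pos * neg))


def roc50(labels: Sequence[bool], scores: Sequence[float], n_fp: int = 50) -> float:
    """ROC area truncated at the n_fp-th false positive.

    Pairwise wins are counted against only the n_fp highest-scoring
    negatives (ties among negatives at the boundary broken by input
    position) and normalized by n_fp * P, so a ranking placing every
    positive above the first n_fp negatives scores 1.0.  When there are at
    most n_fp negatives this equals the plain AUC.
    """
    if n_fp < 1:
        raise ValueError("n_fp must be >= 1")
    labels, pos, neg = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    if neg <= n_fp:
        return auc(labels, scores)
    neg_idx = np.flatnonzero(~labels)
    order = np.lexsort((neg_idx, -scores[neg_idx]))
    top_neg = scores[neg_idx[order[:n_fp]]]
    pos_scores = scores[labels]
    wins = (pos_scores[:, None] > top_neg[None, :]).sum()
    ties = (pos_scores[:, None] == top_neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (n_fp * pos))


def _expected_tp_top_k(labels: np.ndarray, scores: np.ndarray, k: int) -> float:
    """Expected positives among the top k under random tie resolution.

    Genes strictly above the k-th score value all count; the tie block
    straddling rank k contributes its positive fraction times the number of
    remaining slots.
    """
    order = np.argsort(-scores, kind="stable")
    kth = scores[order[k - 1]]
    above = scores > kth
    block = scores == kth
    slots = k - int(above.sum())
    tp = float(labels[above].sum())
    if slots > 0:
        tp += slots * labels[block].sum() / block.sum()
    return tp


def ppv_at_k(labels: Sequence[bool], scores: Sequence[float], k: int = 50) -> float:
    """Positive predictive value in the top k: expected TP among top k / k."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > labels.size:
        raise ValueError(f"k={k} exceeds number of genes {labels.size}")
    return _expected_tp_top_k(labels, scores, k) / k


def aup(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (average precision).

    Mean, over positives taken in rank order, of the precision at each
    positive's rank; ties are resolved into a strict order by input
    position before evaluation.
    """
    labels, pos, _ = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(labels.size), -scores))
    hits = labels[order]
    cum = np.cumsum(hits)
    prec_at_pos = cum[hits] / (np.flatnonzero(hits) + 1)
    return float(prec_at_pos.mean())


def ccr(labels: Sequence[bool], scores: Sequence[float], threshold_rank: int) -> float:
    """Correct classification rate on a balanced pool.

    The top ``threshold_rank`` genes are called positive; CCR is
    (TP + TN) / total, with the tie block at the boundary contributing its
    expected count.  Requires as many positives as negatives -- build such
    pools with :func:`balanced_ccr_protocol`.
    """
    labels, pos, neg = _check_labels(np.asarray(labels))
    if pos != neg:
        raise ValueError(
            "CCR requires a balanced pool; use balanced_ccr_protocol to build one"
        )
    scores = np.asarray(scores, dtype=float)
    tp = _expected_tp_top_k(labels, scores, threshold_rank)
    fp = threshold_rank - tp
    tn = neg - fp
    return float((tp + tn) / labels.size)


def balanced_ccr_protocol(
    scores: np.ndarray | Callable[[np.ndarray], np.ndarray],
    a: AnnotationMatrix,
    group: str,
    seed: int,
) -> float:
    """Average CCR over balanced member/non-member pools.

    Non-members are partitioned into random blocks of the group's size (the
    last block padded by resampling from other non-members so every gene is
    tested); each block plus the members forms a balanced pool that is
    scored and classified at the top half, and the CCR is averaged across
    blocks.  ``scores`` is a per-gene score vector, or a callable mapping
    pool indices to pool scores.
    """
    j = a.group_ids.index(group)
    labels = a.membership[:, j]
    members = np.flatnonzero(labels)
    nonmembers = np.flatnonzero(~labels)
    s = members.size
    if s > nonmembers.size:
        raise ValueError("group larger than half the universe")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(nonmembers)
    values = []
    n_blocks = int(np.ceil(nonmembers.size / s))
    for b in range(n_blocks):
        block = shuffled[b * s : (b + 1) * s]
        if block.size < s:
            pool_rest = np.setdiff1d(nonmembers, block)
            pad = rng.choice(pool_rest, size=s - block.size, replace=False)
            block = np.concatenate([block, pad])
        pool = np.concatenate([members, block])
        pool_scores = scores(pool) if callable(scores) else np.asarray(scores)[pool]
        pool_labels = np.concatenate([np.ones(s, bool), np.zeros(s, bool)])
        values.append(ccr(pool_labels, pool_scores, threshold_rank=s))
    return float(np.mean(values))


_METRICS: dict[str, Callable[..., float]] = {
    "auc": auc,
    "roc50": roc50,
    "ppv50": lambda labels, scores: ppv_at_k(labels, scores, k=min(50, len(labels))),
    "aup": aup,
}


def get_metric(name: str) -> Callable[..., float]:
    try:
        return _METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; choose from {sorted(_METRICS)}")


# ---------------------------------------------------------------------------
# Neighbor voting


@dataclass
class EvaluationResult:
    """Per-group metric values with fold/seed provenance."""

    values: pd.Series  # indexed by group id
    metric: str
    folds: int
    seed: int | None
    predictor: str
    group_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def summary(self) -> float:
        """Unweighted mean over evaluated groups."""
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"group": self.values.index, self.metric: self.values.values})
        if self.group_sizes is not None:
            df.insert(1, "size", self.group_sizes.reindex(self.values.index).values)
        df["n_folds"] = self.folds
        return df


def assign_folds(n_pos: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded round-robin fold labels over shuffled positives.

    Fold sizes differ by at most one and every positive is assigned once.
    """
    order = rng.permutation(n_pos)
    labels = np.empty(n_pos, dtype=int)
    labels[order] = np.arange(n_pos) % folds
    return labels


def _rank_matrix(n: Network) -> np.ndarray:
    """R[c, g]: rank of w(c, g) among {w(c, h) : h != c}, ties averaged.

    Higher weight = higher rank value.  R[c, c] is set to 0 and must never
    be consumed.  For binary networks the ranks are affine in the adjacency
    row: with k = degree(c) and N' = N - 1, absent partners share rank
    (N' - k + 1) / 2 and present partners share rank N' - k + (k + 1) / 2.
    """
    w = n.weights
    ngene = n.n_genes
    if n.binary:
        k = w.sum(axis=1)
        nprime = ngene - 1
        lo = (nprime - k + 1) / 2.0
        hi = (nprime - k) + (k + 1) / 2.0
        r = lo[:, None] + (hi - lo)[:, None] * w
    else:
        masked = w.copy()
        np.fill_diagonal(masked, -np.inf)
        r = scipy.stats.rankdata(masked, axis=1) - 1.0
    np.fill_diagonal(r, 0.0)
    return r


def neighbor_voting_scores(
    rank_matrix: np.ndarray, train_idx: np.ndarray
) -> np.ndarray:
    """Candidate scores: sum of ranks to training genes / sum to non-training.

    Valid for candidates outside the training set; training genes' own
    entries are meaningless and should be masked by the caller.
    """
    ngene = rank_matrix.shape[0]
    total = (ngene - 1) * ngene / 2.0  # sum of ranks 1..N-1 per candidate
    num = rank_matrix[:, train_idx].sum(axis=1)
    denom = total - num
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, num / denom, np.inf)
    return out


def neighbor_voting(
    n: Network,
    a: AnnotationMatrix,
    folds: int = 3,
    seed: int = 0,
    metric: str = "auc",
    groups: Sequence[str] | None = None,
    rank_matrix: np.ndarray | None = None,
) -> EvaluationResult:
    """Cross-validated neighbor-voting performance per annotation group.

    For each group and fold, the fold's positives are hidden, every
    non-training gene is scored by its summed association ranks to the
    training positives over its summed ranks to non-training genes, and the
    hidden positives are evaluated against all non-member genes with the
    requested metric; the per-group value is the unweighted mean over
    folds.  Groups with fewer positives than folds are skipped (logged).
    A precomputed ``rank_matrix`` may be supplied when evaluating many
    annotation sets against one network.
    """
    if n.universe != a.universe:
        raise ValueError("network and annotations must share a universe")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    metric_fn = get_metric(metric)
    if rank_matrix is None:
        rank_matrix = _rank_matrix(n)
    rng = np.random.default_rng(seed)
    group_ids = list(groups) if groups is not None else list(a.group_ids)
    pos_by_group = {g: np.flatnonzero(a.membership[:, a.group_ids.index(g)]) for g in group_ids}
    values = {}
    sizes = {}
    skipped = 0
    for gid in group_ids:
        pos = pos_by_group[gid]
        if pos.size < folds or pos.size > a.n_genes - 1:
            skipped += 1
            continue
        fold_of = assign_folds(pos.size, folds, rng)
        member = np.zeros(a.n_genes, dtype=bool)
        member[pos] = True
        fold_vals = []
        for f in range(folds):
            hidden = pos[fold_of == f]
            train = pos[fold_of != f]
            scores = neighbor_voting_scores(rank_matrix, train)
            eval_mask = ~member
            eval_idx = np.concatenate([hidden, np.flatnonzero(eval_mask)])
            labels = np.concatenate(
                [np.ones(hidden.size, bool), np.zeros(int(eval_mask.sum()), bool)]
            )
            fold_vals.append(metric_fn(labels, scores[eval_idx]))
        values[gid] = float(np.mean(fold_vals))
        sizes[gid] = int(pos.size)
    if skipped:
        logger.info("skipped %d groups with fewer positives than folds", skipped)
    return EvaluationResult(
        values=pd.Series(values, dtype=float),
        metric=metric,
        folds=folds,
        seed=seed,
        predictor="neighbor-voting",
        group_sizes=pd.Series(sizes, dtype="Int64"),
    )


def evaluate_fixed_ranking(
    r: GeneRanking,
    a: AnnotationMatrix,
    metric: str = "auc",
    groups: Sequence[str] | None = None,
    predictor: str = "fixed-ranking",
) -> EvaluationResult:
    """Evaluate one gene ordering as the score vector for every group.

    No cross-validation is performed: the ranking uses no group-specific
    training, so the full membership of each group serves as positives and
    everything else as negatives.
    """
    if r.universe != a.universe:
        raise ValueError("ranking universe does not match annotation universe")
    metric_fn = get_metric(metric)
    scores = r.effective_scores()
    group_ids = list(groups) if groups is not None else list(a.group_ids)
    values = {}
    sizes = {}
    for gid in group_ids:
        labels = a.membership[:, a.group_ids.index(gid)]
        if not labels.any() or labels.all():
            continue
        values[gid] = metric_fn(labels, scores)
        sizes[gid] = int(labels.sum())
    return EvaluationResult(
        values=pd.Series(values, dtype=float),
        metric=metric,
        folds=0,
        seed=None,
        predictor=predictor,
        group_sizes=pd.Series(sizes, dtype="Int64"),
    )


def learnable_filter(n: Network, a: AnnotationMatrix) -> list[str]:
    """Group ids with at least one association within the group.

    Groups whose members are mutually unconnected cannot be learned from
    the network at all and only add chance-level noise to summaries.
    """
    if n.universe != a.universe:
        raise ValueError("network and annotations must share a universe")
    kept = []
    for j, gid in enumerate(a.group_ids):
        idx = np.flatnonzero(a.membership[:, j])
        if idx.size >= 2 and np.any(n.weights[np.ix_(idx, idx)] > 0):
            kept.append(gid)
    return kept
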