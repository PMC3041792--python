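"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use naive enumeration (explicit
pair loops, itertools permutations) so they stay independent of the
vectorized implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gba_bias.annotations import AnnotationMatrix, GeneUniverse


# ---------------------------------------------------------------------------
# oracles


def brute_auc(labels, scores) -> float:
    """Pairwise enumeration: wins + half-ties over all (pos, neg) pairs."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_roc50(labels, scores, n_fp=50) -> float:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    neg_idx = [i for i in range(len(labels)) if not labels[i]]
    if len(neg_idx) <= n_fp:
        return brute_auc(labels, scores)
    neg_sorted = sorted(neg_idx, key=lambda i: (-scores[i], i))[:n_fp]
    pos = scores[labels]
    total = 0.0
    for p in pos:
        for i in neg_sorted:
            if p > scores[i]:
                total += 1.0
            elif p == scores[i]:
                total += 0.5
    return total / (n_fp * len(pos))


def brute_average_precision(labels, scores) -> float:
    """Cumulative precision sum over positives in stable rank order."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], i))
    hits = 0
    precisions = []
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            hits += 1
            precisions.append(hits / rank)
    return float(np.mean(precisions))


def brute_ppv_at_k(labels, scores, k) -> float:
    """Mean PPV@k over every tie-resolving strict order (exhaustive)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    idx = list(range(len(labels)))
    vals = []
    # enumerate all distinct stable orders induced by permuting within ties
    for perm in itertools.permutations(idx):
        if any(scores[perm[i]] < scores[perm[i + 1]] for i in range(len(idx) - 1)):
            continue
        vals.append(sum(labels[list(perm[:k])]) / k)
    return float(np.mean(vals))


def mean_auc_of_order(membership: np.ndarray, order: tuple[int, ...]) -> float:
    """Mean (over groups) AUC of a strict gene order, by pair counting."""
    n, g = membership.shape
    position = {gene: r for r, gene in enumerate(order)}  # 0 = best
    total = 0.0
    used = 0
    for j in range(g):
        labels = membership[:, j]
        pos = [i for i in range(n) if labels[i]]
        neg = [i for i in range(n) if not labels[i]]
        if not pos or not neg:
            continue
        wins = sum(1 for p in pos for q in neg if position[p] < position[q])
        total += wins / (len(pos) * len(neg))
        used += 1
    return total / used


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_annotation(rng, n_genes, n_groups, p=0.4) -> AnnotationMatrix:
    """Random membership matrix ensuring no empty/full groups."""
    while True:
        m = rng.random((n_genes, n_groups)) < p
        sizes = m.sum(axis=0)
        if ((sizes >= 1) & (sizes < n_genes)).all():
            return AnnotationMatrix(
                GeneUniverse(tuple(f"g{i}" for i in range(n_genes))),
                tuple(f"G{j}" for j in range(n_groups)),
                m,
            )


@pytest.fixture
def annotation_factory():
    return random_annotation


@pytest.fixture
def gmt_file(tmp_path):
    """Write GMT lines to a temp file and return its path."""

    def write(lines, name="sets.gmt"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return write
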