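"""One-shot multifunctionality-bias audit of a network + annotation pair.

The recommended workflow for a user who has run (or is about to trust) a
guilt-by-association analysis: compute the optimal multifunctionality
ranking, compare per-group performance of the real network against the
node-degree ranking and against the network's IPN, optionally attach
degree-preserving empirical p-values per group, and report how similar a
user-supplied ranking is to the optimal ranking.  High similarity between
an algorithm's output and the optimal ranking means its predictions cannot
be assumed to be function-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationMatrix
from .multifunctionality import (
    GeneRanking,
    MultifunctionalityScores,
    multifunctionality_scores,
    optimal_ranking_auc,
    spearman_to_ranking,
)
from .networks import Network, build_ipn, node_degree
from .nulls import BiasReport, bias_report, group_nulls, nv_auc_predictor
from .prediction import learnable_filter, neighbor_voting

__all__ = ["AuditResult", "audit"]


@dataclass
class AuditResult:
    mf: MultifunctionalityScores
    optimal_ranking: GeneRanking
    bias: BiasReport
    ipn_values: pd.Series  # per-group neighbor-voting values on the IPN
    mean_real: float
    mean_ipn: float
    null_table: pd.DataFrame | None
    user_ranking_similarity: float | None
    learnable_groups: list[str]

    def group_table(self) -> pd.DataFrame:
        """Per-group audit table: degree AUC, real AUC, IPN AUC, p-values."""
        df = self.bias.table.copy()
        df["ipn_auc"] = self.ipn_values.reindex(df["group"]).to_numpy()
        if self.null_table is not None:
            nt = self.null_table.set_index("group")
            df["empirical_p"] = nt["empirical_p"].reindex(df["group"]).to_numpy()
            df["bh_q"] = nt["bh_q"].reindex(df["group"]).to_numpy()
        return df

    def summary(self) -> dict[str, float]:
        return {
            "mean_degree_auc": self.bias.mean_degree_auc,
            "mean_real_auc": self.mean_real,
            "mean_ipn_auc": self.mean_ipn,
            "spearman_degree_mf": self.bias.spearman_degree_mf,
            "spearman_degree_auc_vs_real_auc": self.bias.spearman_auc,
            "n_learnable_groups": float(len(self.learnable_groups)),
        }


def audit(
    n: Network,
    a: AnnotationMatrix,
    seed: int = 0,
    folds: int = 3,
    metric: str = "auc",
    replicates: int = 0,
    user_ranking: GeneRanking | None = None,
    learnable_only: bool = True,
) -> AuditResult:
    """Run the full bias audit.

    ``replicates`` > 0 adds degree-preserving null p-values per group
    (costly; shared replicates across groups).  ``learnable_only``
    restricts to groups with at least one within-group association,
    matching how results are usually displayed.
    """
    mf = multifunctionality_scores(a)
    opt = optimal_ranking_auc(a)
    groups = learnable_filter(n, a) if learnable_only else list(a.group_ids)
    predictor = nv_auc_predictor(folds=folds, cv_seed=seed, metric=metric)
    bias = bias_report(n, a, mf, predictor=predictor, seed=seed, groups=groups)
    net_binary = n if n.binary else n.binarize()
    ipn = build_ipn(net_binary)
    ipn_res = neighbor_voting(
        ipn, a, folds=folds, seed=seed, metric=metric, groups=groups
    )
    null_table = None
    if replicates > 0:
        null_table = group_nulls(
            net_binary, a, predictor, replicates=replicates, seed=seed, groups=groups
        )
    similarity = None
    if user_ranking is not None:
        similarity = spearman_to_ranking(user_ranking, opt)
    return AuditResult(
        mf=mf,
        optimal_ranking=opt,
        bias=bias,
        ipn_values=ipn_res.values,
        mean_real=bias.mean_predictor_auc,
        mean_ipn=float(ipn_res.values.mean()),
        null_table=null_table,
        user_ranking_similarity=similarity,
        learnable_groups=groups,
    )
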