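"""Single-sample gene-set enrichment scoring and subtype association tests.

Per sample, genes are ranked by descending expression (ties get average
rank); the enrichment score of a set is the running-sum difference between a
rank-weighted ECDF over in-set genes (weight = rank^alpha, alpha = 0.25) and
the uniform ECDF over out-of-set genes.  Optional range normalization divides
the whole score matrix by its global max - min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, SignatureSet
from .survival_stats import bh_fdr


@dataclass
class ScoreMatrix:
    scores: pd.DataFrame            # samples x signatures
    normalization_tag: str = "raw"  # "raw" | "range_normalized"
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("non-finite enrichment scores")


def _sample_es(order_weights: np.ndarray, in_set: np.ndarray) -> float:
    """Running-sum ES for one sample given genes already in walk order.

    ``order_weights``: rank value ^ alpha per gene in descending-expression
    order; ``in_set``: boolean mask in the same order.
    """
    n = order_weights.size
    n_in = int(in_set.sum())
    w_in = np.where(in_set, order_weights, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: SignatureSet,
    alpha: float = 0.25,
    range_normalize: bool = True,
) -> ScoreMatrix:
    """ssGSEA enrichment scores for every (sample, signature) pair.

    Sets with fewer than 2 genes present in the expression matrix are skipped
    with a warning; a set covering the whole gene universe is an error.
    """
    vals = expr.values
    genes = vals.index
    n = len(genes)
    # descending-expression walk order per sample; average ranks for ties
    ranks = vals.rank(axis=0, method="average").to_numpy()  # 1 = lowest
    weights = ranks ** alpha
    order = np.argsort(-vals.to_numpy(), axis=0, kind="stable")

    masks: dict[str, np.ndarray] = {}
    for name, members in sets:
        present = np.asarray(genes.isin(members))
        n_in = int(present.sum())
        if n_in < 2:
            warnings.warn(f"signature {name!r}: < 2 genes matched; skipped",
                          stacklevel=2)
            continue
        if n_in == n:
            raise ValueError(f"signature {name!r} covers the entire gene universe")
        masks[name] = present
    if not masks:
        raise ValueError("no usable signatures after matching")

    out = np.zeros((vals.shape[1], len(masks)))
    names = list(masks)
    for j in range(vals.shape[1]):
        oj = order[:, j]
        wj = weights[oj, j]
        for s, name in enumerate(names):
            out[j, s] = _sample_es(wj, masks[name][oj])
    scores = pd.DataFrame(out, index=vals.columns, columns=names)
    scores.index.name = "sample_id"
    tag = "raw"
    if range_normalize:
        span = float(out.max() - out.min())
        if span > 0:
            scores = scores / span
        tag = "range_normalized"
    return ScoreMatrix(scores=scores, normalization_tag=tag, alpha=alpha)


def group_differential(
    values: pd.DataFrame,
    labels: pd.Series,
    test: str = "anova",
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-column ANOVA or Kruskal-Wallis across subtype labels.

    Returns a table (column, statistic, p, q, differential) with BH q-values
    and a flag at ``q_threshold``.  Constant columns get p = 1 with a warning.
    """
    labels = labels.loc[values.index]
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 samples")
    if test not in ("anova", "kruskal"):
        raise ValueError(f"unknown test {test!r}")
    rows = []
    for col in values.columns:
        arrs = [values.loc[labels == g, col].to_numpy(dtype=float) for g in groups]
        pooled = np.concatenate(arrs)
        if np.ptp(pooled) == 0:
            warnings.warn(f"column {col!r} is constant; p set to 1", stacklevel=2)
            rows.append((col, 0.0, 1.0))
            continue
        if test == "anova":
            stat, p = stats.f_oneway(*arrs)
        else:
            stat, p = stats.kruskal(*arrs)
        if not np.isfinite(p):
            p = 1.0
        rows.append((col, float(stat), float(p)))
    table = pd.DataFrame(rows, columns=["column", "statistic", "p"]).set_index("column")
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["differential"] = table["q"] < q_threshold
    return table
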