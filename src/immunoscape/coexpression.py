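"""Weighted co-expression network analysis of immune genes.

An unsigned adjacency |cor|^beta (soft threshold beta, default 4) is
converted to the topological overlap matrix (TOM); genes are clustered by
average linkage on 1 - TOM and cut into modules (minimum 30 genes, unassigned
genes labeled "grey"); module eigengenes (first principal component of the
standardized module submatrix) are merged below a dissimilarity height of
0.25; module membership kME is the correlation of each gene with each
eigengene, and hub genes are members with kME > 0.9.

The published dynamic-hybrid branch cut is approximated by a static cut at a
merge-height quantile mapped from the deep-split setting (0..4 ->
0.95..0.75); the full hybrid algorithm is deliberately out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io_core import ExpressionMatrix
from .ssgsea import group_differential
from .survival_stats import cox_ph, logrank_test, median_split

logger = logging.getLogger(__name__)

DEEP_SPLIT_QUANTILE = {0: 0.95, 1: 0.90, 2: 0.85, 3: 0.80, 4: 0.75}

GREY = "grey"


@dataclass
class CoexpressionParams:
    beta: int = 4
    min_module_size: int = 30
    deep_split: int = 4
    merge_height: float = 0.25
    network_type: str = "unsigned"

    def __post_init__(self) -> None:
        if self.beta < 1 or int(self.beta) != self.beta:
            raise ValueError("beta must be a positive integer")
        if not 0 < self.merge_height < 1:
            raise ValueError("merge_height must be in (0, 1)")
        if self.deep_split not in DEEP_SPLIT_QUANTILE:
            raise ValueError("deep_split must be one of 0..4")
        if self.network_type != "unsigned":
            raise ValueError("only unsigned networks are supported")


@dataclass
class GeneModuleSet:
    assignment: pd.Series             # gene -> module label ("grey" unassigned)
    eigengenes: pd.DataFrame          # samples x modules, unit-norm columns
    kme: pd.DataFrame                 # genes x modules
    hub_genes: dict[str, list[str]]   # module -> members with kME > threshold
    variance_explained: dict[str, float] = field(default_factory=dict)
    merge_history: list[tuple[str, str, float]] = field(default_factory=list)


def adjacency_matrix(expr: ExpressionMatrix, beta: int = 4) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor(i, j)|^beta over genes."""
    vals = expr.values
    sds = vals.std(axis=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"constant gene {bad!r}")
    a = np.abs(np.corrcoef(vals.to_numpy())) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=vals.index, columns=vals.index)


def scale_free_fit_index(connectivity: np.ndarray, n_bins: int = 10
                         ) -> tuple[float, float]:
    """Scale-free topology fit: R^2 of log10 p(k) vs log10 k over k-bins.

    Connectivities are split into ``n_bins`` equal-width bins; empty bins are
    dropped; the per-bin proportion is regressed on the log mean connectivity.
    Returns (signed fit index, slope): the index is R^2 when the slope is
    negative and -R^2 otherwise.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("too few positive connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, prop = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k.append(k[mask].mean())
        prop.append(mask.mean())
    if len(mean_k) < 3:
        return 0.0, 0.0
    lx = np.log10(np.asarray(mean_k))
    ly = np.log10(np.asarray(prop))
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    fit = r2 if slope < 0 else -r2
    return float(fit), float(slope)


def soft_threshold_scan(expr: ExpressionMatrix, powers=range(1, 21)) -> pd.DataFrame:
    """Scale-free fit index, slope and mean connectivity per candidate power."""
    if expr.shape[0] < 30 or expr.shape[1] < 10:
        raise ValueError("need >= 30 genes and >= 10 samples")
    vals = expr.values
    sds = vals.std(axis=1)
    if (sds == 0).any():
        raise ValueError(f"constant gene {sds.index[sds == 0][0]!r}")
    cor = np.abs(np.corrcoef(vals.to_numpy()))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in powers:
        a = cor ** beta
        k = a.sum(axis=1)
        fit, slope = scale_free_fit_index(k)
        rows.append({"power": int(beta), "scale_free_fit_r2": fit,
                     "slope": slope, "mean_connectivity": float(k.mean())})
    return pd.DataFrame(rows).set_index("power")


def tom_matrix(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency (unit diagonal).

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the connectivity of i.
    """
    a = adjacency.to_numpy() if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    m = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a                      # (i,j): sum_u a_iu a_uj, u != i,j after diag=0
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    params: CoexpressionParams | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    The cut height sits at the ``deep_split``-mapped fraction of the
    dendrogram's merge-height range (between its 5th percentile and maximum,
    the dynamic-tree-cut cutHeight convention); branches smaller than
    ``min_module_size`` become grey.  Modules are named M1, M2, ... by
    descending size (ties by smallest member gene id).
    """
    params = params or CoexpressionParams()
    n = len(gene_ids)
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size: all grey", stacklevel=2)
        return pd.Series(GREY, index=pd.Index(gene_ids, name="gene_id"), name="module")
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    z = average(squareform(np.clip(d, 0, None), checks=False))
    heights = z[:, 2]
    h_lo, h_hi = float(np.quantile(heights, 0.05)), float(heights.max())
    cut = h_lo + DEEP_SPLIT_QUANTILE[params.deep_split] * (h_hi - h_lo)
    raw = fcluster(z, t=cut, criterion="distance")
    labels = np.full(n, GREY, dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= params.min_module_size]
    ordered = sorted(
        kept,
        key=lambda c: (-sizes[c], min(np.asarray(gene_ids)[raw == c])),
    )
    for rank, c in enumerate(ordered, start=1):
        labels[raw == c] = f"M{rank}"
    out = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"), name="module")
    logger.info("detected %d module(s); %d grey gene(s)",
                len(ordered), int((out == GREY).sum()))
    return out


def _eigengene(submatrix: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of the gene-standardized submatrix.

    Returns (unit-norm eigengene over samples, variance explained).  The sign
    is oriented so the eigengene correlates positively with the module's mean
    expression profile.
    """
    sds = submatrix.std(axis=1, ddof=0)
    if (sds == 0).all():
        raise ValueError("module submatrix has rank 0")
    keep = sds > 0
    z = (submatrix[keep] - submatrix[keep].mean(axis=1, keepdims=True)) / sds[keep, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    mean_profile = submatrix.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return e, var_explained


def module_eigengenes(
    expr: ExpressionMatrix,
    labels: pd.Series,
    merge_height: float = 0.25,
    hub_kme_threshold: float = 0.9,
) -> GeneModuleSet:
    """Eigengenes, module merging, kME and hub genes.

    Modules whose eigengene dissimilarity 1 - cor falls below
    ``merge_height`` are merged iteratively (closest pair first, ties by
    alphabetical module name), eigengenes recomputed, then kME = cor(gene,
    eigengene) and hub genes (same-module kME > ``hub_kme_threshold``) are
    derived.
    """
    vals = expr.values
    labels = labels.loc[vals.index]
    modules = sorted(set(labels) - {GREY})
    if not modules:
        raise ValueError("no non-grey modules")
    members: dict[str, list[str]] = {
        m: list(labels.index[labels == m]) for m in modules
    }
    history: list[tuple[str, str, float]] = []

    def eigengene_table() -> tuple[pd.DataFrame, dict[str, float]]:
        cols, var = {}, {}
        for m in sorted(members):
            e, ve = _eigengene(vals.loc[members[m]].to_numpy(dtype=float))
            cols[m] = e
            var[m] = ve
        return pd.DataFrame(cols, index=vals.columns), var

    eig, var = eigengene_table()
    while len(members) > 1:
        cor = np.corrcoef(eig.to_numpy().T)
        names = list(eig.columns)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        best = np.inf
        pair = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if diss[i, j] < best - 1e-15:
                    best, pair = diss[i, j], (names[i], names[j])
        if pair is None or best >= merge_height:
            break
        a, b = sorted(pair)
        history.append((a, b, float(best)))
        members[a] = members[a] + members[b]
        del members[b]
        eig, var = eigengene_table()
        logger.info("merged module %s into %s (dissimilarity %.3f)", b, a, best)

    new_labels = pd.Series(GREY, index=labels.index, name="module", dtype=object)
    for m, genes in members.items():
        new_labels.loc[genes] = m

    gene_z = vals.to_numpy(dtype=float)
    kme = pd.DataFrame(index=vals.index, columns=sorted(members), dtype=float)
    for m in kme.columns:
        e = eig[m].to_numpy()
        ec = e - e.mean()
        gc = gene_z - gene_z.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(gc, axis=1) * np.linalg.norm(ec)
        with np.errstate(invalid="ignore", divide="ignore"):
            kme[m] = np.where(denom > 0, gc @ ec / denom, np.nan)
    hubs = {
        m: sorted(
            g for g in members[m]
            if np.isfinite(kme.loc[g, m]) and kme.loc[g, m] > hub_kme_threshold
        )
        for m in members
    }
    return GeneModuleSet(assignment=new_labels, eigengenes=eig, kme=kme,
                         hub_genes=hubs, variance_explained=var,
                         merge_history=history)


def module_prognosis(
    module_set: GeneModuleSet,
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    subtype_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-module survival and subtype association.

    For each module: univariate Cox on the (standardized) eigengene, log-rank
    comparison of high vs low mean module expression (median split), and, when
    subtype labels are given, ANOVA of the eigengene across subtypes.
    """
    samples = [s for s in expr.sample_ids if s in clinical.index]
    times = clinical.loc[samples, "os_time"].to_numpy(dtype=float)
    events = clinical.loc[samples, "os_event"].to_numpy(dtype=float)
    eig = module_set.eigengenes.loc[samples]
    assoc = None
    if subtype_labels is not None:
        assoc = group_differential(eig, subtype_labels.loc[samples], test="anova")
    rows = []
    for m in eig.columns:
        e = eig[m].to_numpy(dtype=float)
        fit = cox_ph(((e - e.mean()) / e.std()).reshape(-1, 1), times, events)
        f = fit.fits[0]
        member_genes = list(module_set.assignment.index[module_set.assignment == m])
        mean_score = expr.values.loc[member_genes, samples].mean(axis=0).to_numpy()
        grp = median_split(mean_score)
        chi2, logrank_p = logrank_test(times, events, grp)
        row = {
            "module": m, "cox_hr": f.hr, "cox_ci_low": f.ci95[0],
            "cox_ci_high": f.ci95[1], "cox_p": f.p,
            "logrank_chi2": chi2, "logrank_p": logrank_p,
        }
        if assoc is not None:
            row["subtype_anova_p"] = float(assoc.loc[m, "p"])
            row["subtype_anova_q"] = float(assoc.loc[m, "q"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")
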