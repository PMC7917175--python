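"""Graph-learned immune landscape via a discriminative principal tree.

Samples' immune profiles are jointly projected to a low-dimensional latent
space (orthonormal projection W, latent coordinates Z) and summarized by K
centers Y connected by a spanning tree, in the spirit of DDRTree.  The
objective

    sum_i ||x_i - W z_i||^2  +  lambda * sum_(k,k') in tree ||y_k - y_k'||^2
    + gamma * ( sum_ik r_ik ||z_i - y_k||^2 + sigma * sum_ik r_ik log r_ik )

is minimized by exact block-coordinate updates — soft assignments R
(row-normalized Gaussian kernel), minimum spanning tree over centers, a
Laplacian-penalized linear solve for Y, a Procrustes step for W and a closed
form for Z — so the objective trace is non-increasing by construction.

Downstream utilities correlate latent components with signature scores,
partition the tree into branches (maximal paths between nodes of degree != 2)
to split subtypes into lettered subsets, and compare survival between sample
groups at the most separated terminal (leaf) positions of the tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .survival_stats import bh_fdr, multigroup_logrank, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class LandscapeEmbedding:
    sample_ids: list[str]
    Z: np.ndarray                  # q x n latent coordinates
    W: np.ndarray                  # features x q, orthonormal columns
    Y: np.ndarray                  # q x K center positions
    tree_edges: list[tuple[int, int]]
    R: np.ndarray                  # n x K soft assignments, rows sum to 1
    branch_id: np.ndarray          # per-sample branch index
    center_branch: np.ndarray      # per-center branch index
    objective_trace: list[float]
    params: dict = field(default_factory=dict)

    @property
    def n_centers(self) -> int:
        return self.Y.shape[1]

    def hard_centers(self) -> np.ndarray:
        return np.argmax(self.R, axis=1)

    def coordinates(self, n_components: int = 2) -> pd.DataFrame:
        comp = self.Z[:n_components].T
        return pd.DataFrame(
            comp, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"component_{i + 1}" for i in range(comp.shape[1])],
        )


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between columns of a (q x n) and b (q x m)."""
    aa = (a**2).sum(axis=0)[:, None]
    bb = (b**2).sum(axis=0)[None, :]
    return np.maximum(aa + bb - 2.0 * (a.T @ b), 0.0)


def _mst_edges(y: np.ndarray) -> list[tuple[int, int]]:
    d = _sqdist(y, y)
    # strictly positive weights so the sparse MST keeps every edge
    mst = minimum_spanning_tree(d + 1e-12)
    rows, cols = mst.nonzero()
    return sorted((int(min(i, j)), int(max(i, j))) for i, j in zip(rows, cols))


def _tree_laplacian(edges, k: int) -> np.ndarray:
    lap = np.zeros((k, k))
    for i, j in edges:
        lap[i, i] += 1
        lap[j, j] += 1
        lap[i, j] -= 1
        lap[j, i] -= 1
    return lap


def _branches(edges, k: int) -> np.ndarray:
    """Partition tree edges into maximal paths between nodes of degree != 2.

    Returns a per-center branch id; junction nodes (degree > 2) adopt the id
    of the first incident branch.
    """
    adj: dict[int, list[int]] = {i: [] for i in range(k)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    degree = {i: len(adj[i]) for i in adj}
    endpoints = [i for i in range(k) if degree[i] != 2]
    if not endpoints:  # degenerate: cycle-free implies k <= 2 handled above
        endpoints = [0]
    branch = np.full(k, -1, dtype=int)
    next_id = 0
    visited_edges = set()
    for start in sorted(endpoints):
        for nb in sorted(adj[start]):
            if (min(start, nb), max(start, nb)) in visited_edges:
                continue
            # walk the path until the next node of degree != 2
            path = [start, nb]
            visited_edges.add((min(start, nb), max(start, nb)))
            while degree[path[-1]] == 2:
                nxt = [x for x in adj[path[-1]] if x != path[-2]][0]
                visited_edges.add((min(path[-1], nxt), max(path[-1], nxt)))
                path.append(nxt)
            for node in path:
                if branch[node] < 0:
                    branch[node] = next_id
            next_id += 1
    branch[branch < 0] = 0  # isolated centers (k == 1)
    return branch


def ddrtree_embed(
    features: pd.DataFrame,
    q: int = 2,
    K: int | None = None,
    lam: float = 1.0,
    gamma: float = 10.0,
    sigma: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-5,
    seed: int = 0,
) -> LandscapeEmbedding:
    """Fit the principal tree to a samples-by-features matrix.

    ``q`` latent components (at most 4), ``K`` centers (default min(n, 50)),
    tree rigidity ``lam``, assignment weight ``gamma``, kernel bandwidth
    ``sigma`` (default 0.01 x median pairwise latent distance at
    initialization).  Deterministic for fixed inputs and seed.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if sigma is not None and sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = features.to_numpy(dtype=float).T  # d x n
    d, n = x.shape
    if not 1 <= q <= min(4, d):
        raise ValueError(f"q={q} outside [1, min(4, {d})]")
    if K is None:
        K = min(n, 50)
    if not 2 <= K <= n:
        raise ValueError(f"K={K} outside [2, n={n}]")
    x = x - x.mean(axis=1, keepdims=True)

    # init: leading principal components; centers by k-means++ on Z
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    w = u[:, :q]
    z = w.T @ x
    km = KMeans(n_clusters=K, n_init=1, init="k-means++", random_state=seed)
    km.fit(z.T)
    y = km.cluster_centers_.T
    if sigma is None:
        pd2 = _sqdist(z, z)
        med = float(np.median(np.sqrt(pd2[np.triu_indices(n, k=1)])))
        sigma = max(0.01 * med, 1e-8)

    edges = _mst_edges(y)
    trace: list[float] = []
    r = np.full((n, K), 1.0 / K)
    prev_obj = np.inf
    converged = False
    for _ in range(max_iter):
        # (1) soft assignments
        d2 = _sqdist(z, y)
        logr = -d2 / sigma
        logr -= logsumexp(logr, axis=1, keepdims=True)
        r = np.exp(logr)
        # (2) tree update (MST minimizes the lambda term given Y)
        edges = _mst_edges(y)
        lap = _tree_laplacian(edges, K)
        # (3) centers: (lam L + gamma D) linear solve
        dcol = r.sum(axis=0)
        a = lam * lap + gamma * np.diag(dcol)
        y = np.linalg.solve(a.T, (gamma * z @ r).T).T
        # (4) projection (Procrustes) and latent coordinates
        m = x @ z.T
        uu, _, vv = np.linalg.svd(m, full_matrices=False)
        w = uu @ vv
        z = (w.T @ x + gamma * y @ r.T) / (1.0 + gamma)

        d2 = _sqdist(z, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(np.sum(np.where(r > 0, r * np.log(r), 0.0)))
        obj = (
            float(((x - w @ z) ** 2).sum())
            + lam * sum(float(((y[:, i] - y[:, j]) ** 2).sum()) for i, j in edges)
            + gamma * (float((r * d2).sum()) + sigma * ent)
        )
        trace.append(obj)
        if np.isfinite(prev_obj) and abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn(f"principal tree did not converge in {max_iter} iterations",
                      stacklevel=2)
    edges = _mst_edges(y)
    center_branch = _branches(edges, K)
    branch_id = center_branch[np.argmax(r, axis=1)]
    return LandscapeEmbedding(
        sample_ids=list(features.index), Z=z, W=w, Y=y, tree_edges=edges,
        R=r, branch_id=branch_id, center_branch=center_branch,
        objective_trace=trace,
        params={"q": q, "K": K, "lambda": lam, "gamma": gamma,
                "sigma": sigma, "seed": seed, "converged": converged},
    )


def component_correlations(
    embedding: LandscapeEmbedding, scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each latent component with each signature score.

    Returns a long table (component, signature, r, p, q); constant components
    are reported with missing correlations.
    """
    scores = scores.loc[embedding.sample_ids]
    rows = []
    for ci in range(embedding.Z.shape[0]):
        comp = embedding.Z[ci]
        const = np.ptp(comp) == 0
        for sig in scores.columns:
            v = scores[sig].to_numpy(dtype=float)
            if const or np.ptp(v) == 0:
                rows.append((f"component_{ci + 1}", sig, np.nan, np.nan))
            else:
                r, p = stats.pearsonr(comp, v)
                rows.append((f"component_{ci + 1}", sig, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["component", "signature", "r", "p"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


def branch_subsets(
    embedding: LandscapeEmbedding,
    subtype_labels: pd.Series,
    min_samples_per_branch: int = 10,
) -> pd.Series:
    """Split subtypes that straddle several tree branches into lettered subsets.

    A subtype occupying >= 2 branches, each with >= ``min_samples_per_branch``
    of its samples, becomes IS?A, IS?B, ... by descending branch occupancy;
    otherwise the subtype label is kept unchanged.
    """
    if not embedding.tree_edges:
        raise ValueError("embedding has no tree")
    labels = subtype_labels.loc[embedding.sample_ids]
    branch = pd.Series(embedding.branch_id, index=labels.index)
    out = labels.astype(object).copy()
    for st in sorted(labels.unique()):
        members = labels == st
        counts = branch[members].value_counts()
        big = counts[counts >= min_samples_per_branch]
        if len(big) >= 2:
            for letter_i, b in enumerate(big.index):
                mask = members & (branch == b)
                out.loc[mask] = f"{st}{chr(ord('A') + letter_i)}"
            # residual samples on minor branches keep the largest subset label
            residual = members & ~branch.isin(big.index)
            out.loc[residual] = f"{st}A"
    out.name = "subset"
    return out


def extreme_location_groups(
    embedding: LandscapeEmbedding,
    clinical: pd.DataFrame,
    n_groups: int = 3,
) -> dict:
    """Survival comparison between samples at the most separated tree leaves.

    The ``n_groups`` leaf centers with the largest pairwise separation are
    selected greedily (farthest pair first, then farthest-from-chosen); each
    group collects samples whose highest-probability center lies on the
    leaf's terminal segment (the leaf and its incident edge), with centers
    claimed by at most one group.  Returns the groups, the overall
    multi-group log-rank test and pairwise log-rank p-values.
    """
    adj: dict[int, list[int]] = {i: [] for i in range(embedding.n_centers)}
    for i, j in embedding.tree_edges:
        adj[i].append(j)
        adj[j].append(i)
    leaves = [i for i in adj if len(adj[i]) == 1]
    if len(leaves) < n_groups:
        raise ValueError(f"tree has {len(leaves)} leaves < n_groups={n_groups}")
    ypos = embedding.Y
    d = _sqdist(ypos[:, leaves], ypos[:, leaves])
    chosen = list(np.unravel_index(np.argmax(d), d.shape))
    while len(chosen) < n_groups:
        rest = [i for i in range(len(leaves)) if i not in chosen]
        nxt = max(rest, key=lambda i: min(d[i, c] for c in chosen))
        chosen.append(nxt)
    chosen_leaves = [leaves[i] for i in chosen]

    hard = embedding.hard_centers()
    samples = np.asarray(embedding.sample_ids)
    claimed: set[int] = set()
    groups: dict[str, list[str]] = {}
    for gi, leaf in enumerate(chosen_leaves):
        segment = [c for c in [leaf, adj[leaf][0]] if c not in claimed]
        claimed.update(segment)
        mask = np.isin(hard, segment)
        groups[f"group_{gi + 1}"] = sorted(samples[mask])

    times_all, events_all, labels_all = [], [], []
    for name, members in groups.items():
        members_in = [s for s in members if s in clinical.index]
        times_all.extend(clinical.loc[members_in, "os_time"])
        events_all.extend(clinical.loc[members_in, "os_event"])
        labels_all.extend([name] * len(members_in))
    result = {"groups": groups, "leaf_centers": chosen_leaves}
    labels_arr = np.asarray(labels_all)
    if len(set(labels_all)) >= 2 and np.sum(events_all) > 0:
        chi2, df, p = multigroup_logrank(times_all, events_all, labels_arr)
        result["logrank_chi2"], result["logrank_df"], result["logrank_p"] = chi2, df, p
        pairwise = {}
        names = sorted(groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                mask = np.isin(labels_arr, [names[i], names[j]])
                if mask.sum() and np.asarray(events_all)[mask].sum() > 0 \
                        and len(set(labels_arr[mask])) == 2:
                    _, pp = logrank_test(np.asarray(times_all)[mask],
                                         np.asarray(events_all)[mask],
                                         labels_arr[mask])
                    pairwise[(names[i], names[j])] = pp
        result["pairwise_logrank_p"] = pairwise
    return result
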