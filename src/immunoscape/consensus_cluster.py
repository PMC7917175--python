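"""Bootstrap consensus clustering with PAM over 1 - Pearson distance.

For each k in a range, samples are repeatedly subsampled (default 80% of
patients, without replacement), partitioned around medoids, and the fraction
of resamples in which each sample pair lands in the same cluster (among those
where both were drawn) forms the consensus matrix.  The area under the CDF of
consensus entries as a function of k, and its relative increase (the "delta
area"), drive the choice of k; final subtype labels come from clustering the
consensus matrix itself and are renamed IS1..ISk by descending size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def pearson_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows, clipped to [0, 2], zero diagonal."""
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.corrcoef(profiles)
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def pam_cluster(dist: np.ndarray, k: int, seed: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Partition around medoids: deterministic BUILD then repeated SWAP.

    SWAP accepts the best cost-reducing (medoid, candidate) exchange until no
    swap lowers the total distance-to-medoid cost; ties break toward the
    lowest index, so the result is deterministic (``seed`` is accepted for
    interface symmetry but unused).  Returns (labels in 0..k-1 ordered by
    medoid index, sorted medoid indices).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(dist).any():
        raise ValueError("NaN in distance matrix")
    if not (2 <= k <= n):
        raise ValueError(f"k={k} outside [2, n={n}]")

    # BUILD: greedy selection maximizing decrease of total nearest-medoid cost
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    d_near = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        d_near = np.minimum(d_near, dist[:, best])

    medoids = np.array(sorted(medoids))
    for _ in range(300):  # SWAP
        dmed = dist[:, medoids]                       # n x k
        nearest = np.argmin(dmed, axis=1)
        d1 = dmed[np.arange(n), nearest]
        part = np.partition(dmed, 1, axis=1)
        d2 = part[:, 1] if k > 1 else np.full(n, np.inf)
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            mine = nearest == mi
            # cost change for every candidate h simultaneously
            others = np.minimum(dist[~mine], d1[~mine, None]).sum(axis=0) \
                - d1[~mine].sum()
            mine_cost = np.minimum(dist[mine], d2[mine, None]).sum(axis=0) \
                - d1[mine].sum()
            delta = others + mine_cost
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = np.sort(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # a medoid belongs to its own cluster
    return labels, medoids


@dataclass
class ConsensusResult:
    sample_ids: list[str]
    k_range: list[int]
    matrices: dict[int, np.ndarray]
    B: int
    frac: float
    seed: int
    cdf_grid: dict[int, np.ndarray] = field(default_factory=dict)
    cdf_values: dict[int, np.ndarray] = field(default_factory=dict)
    area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None
    labels: pd.Series | None = None
    k_rule: str = ""


def consensus_matrices(
    features: pd.DataFrame,
    k_range=range(2, 11),
    B: int = 500,
    frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Build per-k consensus matrices over B subsampled PAM runs.

    ``features`` is samples x genes (each row a sample's expression profile);
    the clustering distance is 1 - Pearson correlation between profiles.
    M_k(i, j) = co-clustered count / co-sampled count; never co-sampled pairs
    are set to 0 with a warning; the diagonal is 1.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    n = features.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples")
    k_range = [int(k) for k in k_range]
    if any(k > n for k in k_range):
        raise ValueError("k_range exceeds sample count")
    x = features.to_numpy(dtype=float)
    dist = pearson_distance(x)
    rng = np.random.default_rng(seed)
    m = int(np.ceil(frac * n))
    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    drawn = np.zeros(n, dtype=bool)
    for _ in range(B):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        drawn[idx] = True
        co_sample[np.ix_(idx, idx)] += 1
        sub = dist[np.ix_(idx, idx)]
        for k in k_range:
            labels, _ = pam_cluster(sub, k)
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same
    if not drawn.all():
        warnings.warn(
            f"{(~drawn).sum()} sample(s) never drawn across {B} resamples",
            stacklevel=2,
        )
    never = co_sample == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{never.sum() // 2} sample pair(s) never co-sampled; consensus set to 0",
            stacklevel=2,
        )
    matrices = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            mk = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
            mk = (mk + mk.T) / 2.0
            np.fill_diagonal(mk, 1.0)
            matrices[k] = mk
    return ConsensusResult(sample_ids=list(features.index), k_range=k_range,
                           matrices=matrices, B=B, frac=frac, seed=seed)


def cdf_delta_area(result: ConsensusResult) -> ConsensusResult:
    """Attach per-k CDF curves, areas A(k) and delta areas.

    A(k) integrates the right-continuous empirical CDF of upper-triangle
    consensus entries over [0, 1]; delta(2) = A(2) and
    delta(k) = (A(k) - A(k-1)) / A(k-1) for k >= 3.
    """
    ks = sorted(result.k_range)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k_range must be consecutive for delta areas")
    for k in ks:
        if k not in result.matrices:
            raise ValueError(f"missing consensus matrix for k={k}")
        mk = result.matrices[k]
        iu = np.triu_indices_from(mk, k=1)
        entries = np.sort(mk[iu])
        grid = np.unique(np.concatenate([[0.0], entries, [1.0]]))
        cdf = np.searchsorted(entries, grid, side="right") / entries.size
        area = float(np.sum(np.diff(grid) * cdf[:-1]))
        result.cdf_grid[k] = grid
        result.cdf_values[k] = cdf
        result.area[k] = area
    for i, k in enumerate(ks):
        if i == 0:
            result.delta_area[k] = result.area[k]
        else:
            prev = result.area[ks[i - 1]]
            result.delta_area[k] = (result.area[k] - prev) / prev if prev > 0 else np.inf
    return result


def _rename_by_size(labels: np.ndarray, sample_ids: list[str]) -> pd.Series:
    """Rename integer clusters IS1..ISk by descending size.

    Equal-sized clusters are ordered by their alphabetically smallest member.
    """
    groups = {}
    for lab in np.unique(labels):
        members = sorted(np.asarray(sample_ids)[labels == lab])
        groups[lab] = (-len(members), members[0])
    order = sorted(groups, key=lambda g: groups[g])
    mapping = {lab: f"IS{i + 1}" for i, lab in enumerate(order)}
    return pd.Series([mapping[l] for l in labels],
                     index=pd.Index(sample_ids, name="sample_id"), name="subtype")


def select_k_and_label(
    result: ConsensusResult,
    rule: str = "delta_area",
    delta_threshold: float = 0.05,
    k_override: int | None = None,
    final_method: str = "pam",
) -> ConsensusResult:
    """Choose k and derive final subtype labels from the consensus matrix.

    Default rule: largest k whose delta area is >= ``delta_threshold``.
    ``k_override`` forces a specific k (recorded in ``k_rule``).  Final labels
    cluster the consensus *distance* 1 - M_k, by PAM (default) or
    average-linkage hierarchical clustering.
    """
    if not result.delta_area:
        cdf_delta_area(result)
    if k_override is not None:
        if k_override not in result.k_range:
            raise ValueError(f"override k={k_override} outside k_range")
        chosen = int(k_override)
        result.k_rule = f"manual override k={chosen}"
    elif rule == "delta_area":
        eligible = [k for k in sorted(result.k_range)
                    if result.delta_area[k] >= delta_threshold]
        if not eligible:
            raise ValueError("no k satisfies the delta-area rule")
        chosen = max(eligible)
        result.k_rule = f"delta_area>={delta_threshold}"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    result.chosen_k = chosen
    d = 1.0 - result.matrices[chosen]
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    if final_method == "pam":
        labels, _ = pam_cluster(d, chosen)
    elif final_method == "hierarchical":
        z = average(squareform(d, checks=False))
        labels = fcluster(z, t=chosen, criterion="maxclust") - 1
    else:
        raise ValueError(f"unknown final_method {final_method!r}")
    result.labels = _rename_by_size(labels, result.sample_ids)
    logger.info("chose k=%d (%s); subtype sizes %s", chosen, result.k_rule,
                result.labels.value_counts().to_dict())
    return result


def run_consensus(
    features: pd.DataFrame,
    k_range=range(2, 11),
    B: int = 500,
    frac: float = 0.8,
    seed: int = 0,
    delta_threshold: float = 0.05,
    k_override: int | None = None,
    final_method: str = "pam",
) -> ConsensusResult:
    """Convenience wrapper: matrices -> CDF/delta areas -> k + labels."""
    res = consensus_matrices(features, k_range=k_range, B=B, frac=frac, seed=seed)
    cdf_delta_area(res)
    return select_k_and_label(res, delta_threshold=delta_threshold,
                              k_override=k_override, final_method=final_method)
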