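"""Cross-cohort subtype reproducibility.

Discovery subtypes are summarized by centroids, projected onto an independent
cohort by correlation nearest-centroid assignment, and scored by in-group
proportion (IGP: fraction of a subtype's samples whose nearest other sample
shares the subtype) and by Pearson correlation between discovery and
validation centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus_cluster import pearson_distance

logger = logging.getLogger(__name__)


@dataclass
class CentroidSet:
    """Per-subtype mean profile over a feature space (genes or module scores)."""

    centroids: pd.DataFrame  # subtypes x features

    def __post_init__(self) -> None:
        if self.centroids.index.has_duplicates:
            raise ValueError("duplicate subtype names")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.centroids.columns)


def subtype_centroids(features: pd.DataFrame, labels: pd.Series) -> CentroidSet:
    """Per-feature mean over each subtype's members (each needs >= 2 samples)."""
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"subtype(s) with < 2 samples: {list(small.index)}")
    cent = features.groupby(labels).mean()
    cent.index.name = "subtype"
    return CentroidSet(centroids=cent.sort_index())


def nearest_centroid_assign(features: pd.DataFrame, centroids: CentroidSet) -> pd.Series:
    """Assign each sample to the centroid with the highest Pearson correlation.

    Features are aligned by name (unmatched dropped with a warning); exact
    ties go to the lowest-index subtype; zero-variance samples are returned
    unassigned (NaN) and flagged.
    """
    shared = [f for f in centroids.feature_names if f in features.columns]
    if not shared:
        raise ValueError("no shared features between cohort and centroids")
    dropped = len(centroids.feature_names) - len(shared)
    if dropped:
        logger.warning("%d centroid feature(s) missing from cohort; dropped", dropped)
    x = features[shared].to_numpy(dtype=float)
    c = centroids.centroids[shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    cn = np.linalg.norm(cc, axis=1)
    out = []
    names = centroids.subtypes
    for i in range(x.shape[0]):
        if xn[i] == 0:
            out.append(None)
            continue
        r = (xc[i] @ cc.T) / (xn[i] * cn)
        best = float(r.max())
        winners = np.flatnonzero(np.isclose(r, best, rtol=0.0, atol=1e-12))
        if winners.size > 1:
            logger.info("sample %s: centroid tie, assigned lowest-index subtype",
                        features.index[i])
        out.append(names[int(winners[0])])
    assigned = pd.Series(out, index=features.index, name="subtype", dtype=object)
    n_un = assigned.isna().sum()
    if n_un:
        logger.warning("%d zero-variance sample(s) left unassigned", n_un)
    return assigned


def igp_from_labels(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """IGP of given labels: per subtype, the fraction of its samples whose
    nearest other sample (1 - Pearson) carries the same label."""
    labels = labels.loc[features.index]
    d = pearson_distance(features.to_numpy(dtype=float))
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    same = labels.to_numpy() == labels.to_numpy()[nn]
    out = {}
    for st in sorted(labels.unique()):
        members = (labels == st).to_numpy()
        out[st] = float(same[members].mean()) if members.sum() >= 2 else np.nan
    return pd.Series(out, name="igp")


def in_group_proportion(
    features: pd.DataFrame,
    centroids: CentroidSet,
    discovery_features: pd.DataFrame | None = None,
    discovery_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-subtype IGP and (optionally) discovery-validation centroid Pearson.

    Samples are assigned by :func:`nearest_centroid_assign`; IGP(subtype) is
    the fraction of its samples whose nearest *other* validation sample
    (1 - Pearson distance) carries the same assignment.  Subtypes with exactly
    one assigned sample get IGP = NaN.  If the discovery cohort is supplied,
    the Pearson correlation between each subtype's discovery and validation
    centroid (over shared features) is reported alongside.
    """
    assigned = nearest_centroid_assign(features, centroids)
    ok = assigned.notna()
    feats = features.loc[ok]
    labs = assigned.loc[ok]
    igp = igp_from_labels(feats, labs)

    rows = []
    val_cent = feats.groupby(labs).mean() if len(feats) else pd.DataFrame()
    for st in centroids.subtypes:
        members = labs == st
        n = int(members.sum())
        st_igp = float(igp[st]) if st in igp.index and n >= 2 else np.nan
        r = np.nan
        if n >= 1 and discovery_features is not None and discovery_labels is not None:
            disc_cent = subtype_centroids(discovery_features, discovery_labels)
            if st in disc_cent.centroids.index and st in val_cent.index:
                shared = [f for f in disc_cent.feature_names if f in val_cent.columns]
                a = disc_cent.centroids.loc[st, shared].to_numpy(dtype=float)
                b = val_cent.loc[st, shared].to_numpy(dtype=float)
                r = float(np.corrcoef(a, b)[0, 1])
        elif n >= 1 and st in val_cent.index:
            shared = [f for f in centroids.feature_names if f in val_cent.columns]
            a = centroids.centroids.loc[st, shared].to_numpy(dtype=float)
            b = val_cent.loc[st, shared].to_numpy(dtype=float)
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"subtype": st, "n_assigned": n, "igp": st_igp,
                     "centroid_pearson": r})
    return pd.DataFrame(rows).set_index("subtype")
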