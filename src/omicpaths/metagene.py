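"""Metagene summarization of dense pathway nodes.

A pathway node aggregating many measured features (a gene family, a
MapMan BIN, a complex) cannot display every profile on a map, so nodes
with more than four matching features are compressed into metagenes —
one representative profile per "profile type" present in the node. The
realization is deterministic:

1. each feature profile is standardized to zero mean, unit variance
   across conditions (missing values excluded from the moments);
2. features are clustered by correlation distance (1 − Pearson) with
   average-linkage hierarchical clustering; the cluster count k is chosen
   in 2..min(max_k, n − 1) by maximum mean silhouette, collapsing to a
   single cluster when the best silhouette falls below 0.25;
3. each cluster's metagene is the first principal component score vector
   of its standardized profiles, sign-oriented to correlate positively
   with the cluster's mean profile, and reported together with the PC1
   variance share within the cluster.

No step involves randomness, so results are reproducible without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import NotApplicableError, ValidationError
from .model import OmicsDataset, Pathway

TRIGGER = 4  # metagenes only for nodes with strictly more matched features
SILHOUETTE_CUTOFF = 0.25
DEFAULT_MAX_K = 5


@dataclass
class Metagene:
    profile: np.ndarray  # standardized, one value per condition
    members: list[str]
    variance_explained: float


@dataclass
class MetageneSet:
    node_id: str
    layer: str
    metagenes: list[Metagene]
    trigger_count: int
    conditions: list[str] = field(default_factory=list)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rows; missing excluded from the moments,
    then imputed at the (zero) mean. Zero-variance rows become all-zero."""
    out = np.array(x, dtype=float)
    mean = np.nanmean(out, axis=1, keepdims=True)
    std = np.nanstd(out, axis=1, keepdims=True)
    std[std == 0.0] = 1.0
    out = (out - mean) / std
    return np.nan_to_num(out, nan=0.0)


def _correlation_distance(z: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Pearson on standardized (possibly zero) rows."""
    norms = np.linalg.norm(z, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    unit = z / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def _choose_clusters(dist: np.ndarray, max_k: int) -> np.ndarray:
    """Average-linkage labels with k picked by best mean silhouette."""
    n = dist.shape[0]
    if dist.max() < 1e-12:  # all profiles identical up to scale
        return np.ones(n, dtype=int)
    z = linkage(squareform(dist, checks=False), method="average")
    best_labels = np.ones(n, dtype=int)
    best_score = -np.inf
    for k in range(2, min(max_k, n - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if score > best_score:
            best_score = score
            best_labels = labels
    if best_score < SILHOUETTE_CUTOFF:
        return np.ones(n, dtype=int)
    return best_labels


def _cluster_metagene(z: np.ndarray, ids: list[str]) -> Metagene:
    """PC1 condition profile of one cluster of standardized rows."""
    if z.shape[0] == 1:
        profile = z[0].copy()
        ve = 1.0
    else:
        # uncentered PCA on standardized profiles: dominant condition pattern
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        total = float((s**2).sum())
        ve = float(s[0] ** 2 / total) if total > 0 else 1.0
        profile = vt[0].copy()
    mean_profile = z.mean(axis=0)
    if float(profile @ mean_profile) < 0:
        profile = -profile
    sd = profile.std()
    if sd > 0:
        profile = (profile - profile.mean()) / sd
    return Metagene(profile=profile, members=list(ids), variance_explained=ve)


def compute_node_metagenes(
    profiles: pd.DataFrame,
    node_id: str = "",
    layer: str = "",
    max_k: int = DEFAULT_MAX_K,
) -> MetageneSet:
    """Compress a features×conditions profile matrix into metagenes.

    Requires more than :data:`TRIGGER` features (after dropping
    all-missing rows) and at least 3 conditions; otherwise raises
    :class:`NotApplicableError` / :class:`ValidationError` and the caller
    displays the features directly.
    """
    if profiles.shape[1] < 3:
        raise ValidationError(
            f"metagenes need >= 3 conditions, got {profiles.shape[1]}"
        )
    keep = ~profiles.isna().all(axis=1)
    profiles = profiles.loc[keep]
    n = profiles.shape[0]
    if n <= TRIGGER:
        raise NotApplicableError(
            f"node has {n} usable features; metagenes require more than {TRIGGER}"
        )
    if max_k < 1:
        raise ValidationError(f"max_k must be >= 1, got {max_k}")

    ids = [str(i) for i in profiles.index]
    z = _standardize_rows(profiles.to_numpy(dtype=float))
    dist = _correlation_distance(z)
    labels = _choose_clusters(dist, max_k)

    metagenes: list[Metagene] = []
    for lab in sorted(np.unique(labels)):
        idx = np.flatnonzero(labels == lab)
        metagenes.append(
            _cluster_metagene(z[idx], [ids[i] for i in idx])
        )
    metagenes.sort(key=lambda m: (-len(m.members), m.members))
    return MetageneSet(
        node_id=node_id,
        layer=layer,
        metagenes=metagenes,
        trigger_count=n,
        conditions=[str(c) for c in profiles.columns],
    )


def summarize_pathway(
    pathway: Pathway,
    datasets: Sequence[OmicsDataset],
    max_k: int = DEFAULT_MAX_K,
) -> list[MetageneSet]:
    """Metagenes for every (node, layer) with more than four matched features.

    Nodes at or below the trigger pass through untouched (no entry in the
    result); their features are displayed directly.
    """
    out: list[MetageneSet] = []
    for node in pathway.nodes:
        member_ids = set(node.members) | {node.id}
        for ds in datasets:
            matched = sorted(member_ids & ds.ids)
            if len(matched) <= TRIGGER or len(ds.conditions) < 3:
                continue
            frame = pd.DataFrame(
                {fid: ds[fid].profile for fid in matched},
            ).T
            frame.columns = ds.conditions
            usable = (~frame.isna().all(axis=1)).sum()
            if usable <= TRIGGER:
                continue
            out.append(
                compute_node_metagenes(frame, node_id=node.id, layer=ds.name, max_k=max_k)
            )
    return out


def metagene_frame(sets: Sequence[MetageneSet]) -> pd.DataFrame:
    """One row per metagene: node, index, size, variance share, profile."""
    rows = []
    for ms in sets:
        for i, mg in enumerate(ms.metagenes, start=1):
            row: dict[str, object] = {
                "node_id": ms.node_id,
                "layer": ms.layer,
                "metagene_index": i,
                "n_members": len(mg.members),
                "variance_explained": mg.variance_explained,
            }
            for cond, val in zip(ms.conditions, mg.profile):
                row[cond] = val
            rows.append(row)
    return pd.DataFrame(rows)


def membership_frame(sets: Sequence[MetageneSet]) -> pd.DataFrame:
    rows = []
    for ms in sets:
        for i, mg in enumerate(ms.metagenes, start=1):
            for fid in mg.members:
                rows.append(
                    {
                        "node_id": ms.node_id,
                        "layer": ms.layer,
                        "metagene_index": i,
                        "feature_id": fid,
                    }
                )
    return pd.DataFrame(rows, columns=["node_id", "layer", "metagene_index", "feature_id"])
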