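"""Connectivity-fingerprint clustering of labeled subtypes.

Each subtype gets a feature vector of length 2T over an ordered universe of T
connectome cell types: the first T entries count synapses its cells receive
from each type, the last T the synapses they send to each type.  Pairwise L2
distances between (normalized) fingerprints feed average-linkage hierarchical
clustering, cut at a fixed height to define flat connectivity clusters.

An absolute cut height (the study uses 0.3) is only meaningful on normalized
fingerprints — raw synapse-count distances are orders of magnitude larger —
so the default normalization divides each half of the vector by its own sum
(input and output profile each a composition); ``raw`` and ``total``
(whole-row) modes are selectable and the mode is recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "FeatureMatrix",
    "ClusterAssignment",
    "build_features",
    "feature_distances",
    "cluster",
    "NORMALIZATIONS",
]

NORMALIZATIONS = ("raw", "half-sum", "total")


@dataclass
class FeatureMatrix:
    values: pd.DataFrame  # rows: subtypes; columns: in::TYPE then out::TYPE
    normalization: str
    type_universe: list
    zero_rows: list  # subtypes with no qualifying synapses at all


@dataclass
class ClusterAssignment:
    labels: pd.Series  # subtype -> cluster id (1-based)
    linkage_matrix: np.ndarray
    method: str
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def build_features(
    edges: pd.DataFrame,
    subtype_map: Mapping,
    type_map: Mapping,
    type_universe: Sequence | None = None,
    subtypes: Sequence | None = None,
    normalization: str = "half-sum",
) -> FeatureMatrix:
    """Connectivity fingerprints: synapses per (subtype, partner type, direction).

    ``subtype_map`` maps the labeled cells to their subtype; ``type_map`` maps
    any cell to its connectome type (the column universe).  ``type_universe``
    defaults to all types observed in the edge table, in sorted order.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    pre_sub = edges["pre_id"].map(subtype_map)
    post_sub = edges["post_id"].map(subtype_map)
    pre_type = edges["pre_id"].map(type_map)
    post_type = edges["post_id"].map(type_map)
    if type_universe is None:
        type_universe = sorted(
            set(pre_type.dropna().unique()) | set(post_type.dropna().unique())
        )
    else:
        type_universe = list(type_universe)
    if subtypes is None:
        subtypes = sorted(set(subtype_map.values()))
    else:
        subtypes = list(subtypes)

    t_index = pd.Index(type_universe)
    received = (
        pd.DataFrame(
            {"sub": post_sub, "typ": pre_type, "syn": edges["syn_count"]}
        )
        .dropna(subset=["sub", "typ"])
        .groupby(["sub", "typ"], observed=True)["syn"]
        .sum()
        .unstack(fill_value=0)
        .reindex(index=subtypes, columns=t_index, fill_value=0)
    )
    sent = (
        pd.DataFrame({"sub": pre_sub, "typ": post_type, "syn": edges["syn_count"]})
        .dropna(subset=["sub", "typ"])
        .groupby(["sub", "typ"], observed=True)["syn"]
        .sum()
        .unstack(fill_value=0)
        .reindex(index=subtypes, columns=t_index, fill_value=0)
    )
    received.columns = [f"in::{t}" for t in type_universe]
    sent.columns = [f"out::{t}" for t in type_universe]
    feat = pd.concat([received, sent], axis=1).astype(float)
    zero_rows = feat.index[feat.sum(axis=1) == 0].tolist()

    if normalization == "half-sum":
        t = len(type_universe)
        halves = [feat.iloc[:, :t].copy(), feat.iloc[:, t:].copy()]
        for half in halves:
            sums = half.sum(axis=1)
            nz = sums > 0
            half.loc[nz] = half.loc[nz].div(sums[nz], axis=0)
        feat = pd.concat(halves, axis=1)
    elif normalization == "total":
        sums = feat.sum(axis=1)
        nz = sums > 0
        feat.loc[nz] = feat.loc[nz].div(sums[nz], axis=0)
    return FeatureMatrix(
        values=feat,
        normalization=normalization,
        type_universe=list(type_universe),
        zero_rows=zero_rows,
    )


def feature_distances(features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise L2 (Euclidean) distances between fingerprints."""
    vals = features.values if isinstance(features, FeatureMatrix) else features
    arr = vals.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("feature matrix contains non-finite entries")
    from scipy.spatial.distance import pdist

    d = squareform(pdist(arr, metric="euclidean"))
    return pd.DataFrame(d, index=vals.index, columns=vals.index)


def cluster(
    dist: pd.DataFrame,
    method: str = "average",
    cut_height: float = 0.3,
) -> ClusterAssignment:
    """Agglomerative clustering on a precomputed distance matrix with a flat
    cut at ``cut_height`` (items merged at distance <= cut share a cluster).
    """
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if dist.shape[0] == 1:
        labels = pd.Series([1], index=dist.index, name="cluster")
        return ClusterAssignment(labels, np.empty((0, 4)), method, cut_height)
    condensed = squareform(dist.to_numpy(dtype=float), checks=True)
    z = linkage(condensed, method=method)
    flat = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(flat, index=dist.index, name="cluster")
    return ClusterAssignment(labels, z, method, cut_height)
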