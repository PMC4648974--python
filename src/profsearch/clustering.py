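"""Taylor-Butina sphere-exclusion clustering and the structural diversity index.

The Taylor-Butina algorithm partitions a set of fingerprints by repeatedly
taking the compound with the most neighbors (pairwise Tanimoto >= cutoff) as
a cluster centroid and assigning its still-unclaimed neighbors to it.
Neighbor counts are computed once up front and candidates processed in
descending order of that initial count; compounds whose neighbors were all
claimed earlier remain as ("false") singletons.  Ties in the neighbor count
are broken by the lowest input index so results are deterministic.

The diversity index H is Shannon entropy (base 2) applied to the resulting
cluster-size distribution:

    H = - Σᵢ (nᵢ/n) log₂(nᵢ/n)

Higher H means a more scaffold-diverse compound set, i.e. a harder
retrieval problem for a single random query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy


@dataclass
class Cluster:
    centroid: int  # input index of the centroid compound
    members: list[int]  # input indices, centroid included


@dataclass
class Clustering:
    """Disjoint clusters covering every input index exactly once."""

    clusters: list[Cluster]
    cutoff: float

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c.members) for c in self.clusters])

    @property
    def n_items(self) -> int:
        return int(self.sizes.sum())

    def centroid_indices(self) -> list[int]:
        return [c.centroid for c in self.clusters]


def taylor_butina(fps: np.ndarray, cutoff: float) -> Clustering:
    """Sphere-exclusion clustering of a fingerprint matrix.

    Parameters
    ----------
    fps : (n, M) array of 0/1
        One fingerprint per row.
    cutoff : float in (0, 1)
        Two compounds are neighbors when their binary Tanimoto similarity
        is >= cutoff (inclusive).

    Returns
    -------
    Clustering
        Every non-centroid member has similarity >= cutoff to its centroid.
    """
    X = np.asarray(fps, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("taylor_butina needs a nonempty 2-D fingerprint matrix")
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    n = X.shape[0]
    pop = X.sum(axis=1)
    inter = X @ X.T
    denom = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, inter / denom, 0.0)
    adj = sim >= cutoff
    np.fill_diagonal(adj, False)

    counts = adj.sum(axis=1)
    # descending neighbor count, ties by ascending input index
    order = np.lexsort((np.arange(n), -counts))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[Cluster] = []
    for i in order:
        if assigned[i]:
            continue
        members = [int(i)] + [int(j) for j in np.nonzero(adj[i] & ~assigned)[0] if j != i]
        for j in members:
            assigned[j] = True
        clusters.append(Cluster(centroid=int(i), members=members))
    return Clustering(clusters=clusters, cutoff=cutoff)


def diversity_index(clustering) -> float:
    """Shannon entropy (bits) of the cluster-size distribution.

    Accepts a :class:`Clustering` or a bare sequence of cluster sizes.
    """
    if isinstance(clustering, Clustering):
        sizes = clustering.sizes
    else:
        sizes = np.asarray(clustering, dtype=np.float64)
    if sizes.size == 0:
        raise ValueError("cannot compute the diversity index of an empty clustering")
    return float(entropy(sizes / sizes.sum(), base=2))
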