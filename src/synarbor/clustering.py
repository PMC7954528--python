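"""Constrained single-linkage clustering of synapses under the tree metric.

Synapses on the postsynaptic arbor are grouped by agglomerative single-linkage
clustering with two constraints expressed in micrometres of along-neurite
distance:

* ``d_nn`` — the maximum allowed nearest-neighbor distance between the most
  proximal members of two clusters for them to be joined;
* ``d_ext`` — the maximum allowed overall spatial extent (tree-metric diameter)
  of any produced cluster.

Starting from singletons, the pair of clusters at minimal single-linkage
distance among all *admissible* pairs (linkage ≤ d_nn and merged extent ≤
d_ext) is joined; a minimal pair whose merge would exceed d_ext is skipped in
favor of the next admissible pair.  Aggregation stops when no admissible pair
remains.  Ties on the linkage distance are broken deterministically by the
lexicographically smallest pair of smallest member synapse ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from synarbor.morpho import Skeleton, SynapseTable

try:  # compiled merge loop; the pure-numpy path below is the reference
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ClusterParams",
    "PathDistanceMatrix",
    "SynapseCluster",
    "ClusterSet",
    "pairwise_distances",
    "cluster_synapses",
    "filter_for_fratio",
    "filter_multi_synapse",
    "cluster_size_table",
]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering parameters in µm: nearest-neighbor bound and extent bound."""

    d_nn: float
    d_ext: float

    def __post_init__(self) -> None:
        if self.d_nn <= 0 or self.d_ext <= 0:
            raise ValueError("d_nn and d_ext must be positive")


@dataclass(frozen=True)
class PathDistanceMatrix:
    """Pairwise along-neurite distances (µm) between synapse attachment nodes."""

    synapse_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.synapse_ids), len(self.synapse_ids)):
            raise ValueError("distance matrix shape does not match synapse ids")
        if len(self.synapse_ids) and (
            not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0)
        ):
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.synapse_ids)


@dataclass(frozen=True)
class SynapseCluster:
    """One spatial cluster of synapses."""

    member_synapses: frozenset[str]
    member_partners: frozenset[str]
    extent: float  # µm, max pairwise path distance among members

    @property
    def n_synapses(self) -> int:
        return len(self.member_synapses)

    @property
    def n_partners(self) -> int:
        return len(self.member_partners)


@dataclass(frozen=True)
class ClusterSet:
    """A set of synapse clusters produced with particular parameters."""

    clusters: tuple[SynapseCluster, ...]
    params: ClusterParams

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster_id": k, "synapse_id": sid}
            for k, cluster in enumerate(self.clusters)
            for sid in sorted(cluster.member_synapses)
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "synapse_id"])

    def to_summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": k,
                "n_synapses": c.n_synapses,
                "n_partners": c.n_partners,
                "extent_um": c.extent,
            }
            for k, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "n_synapses", "n_partners", "extent_um"]
        )


def pairwise_distances(skeleton: Skeleton, table: SynapseTable) -> PathDistanceMatrix:
    """Along-neurite distance matrix between all synapses of a table."""
    table.validate_against(skeleton)
    ids = tuple(table.synapse_ids)
    nodes = [table[sid].attach_node for sid in ids]
    if not ids:
        return PathDistanceMatrix(synapse_ids=(), matrix=np.zeros((0, 0)))
    matrix = skeleton.pairwise_path_distances(nodes)
    # exact symmetry/zero diagonal despite floating point in Dijkstra
    matrix = 0.5 * (matrix + matrix.T)
    np.fill_diagonal(matrix, 0.0)
    return PathDistanceMatrix(synapse_ids=ids, matrix=matrix)


def cluster_synapses(
    distances: PathDistanceMatrix,
    params: ClusterParams,
    table: SynapseTable | None = None,
) -> ClusterSet:
    """Constrained single-linkage clustering of synapses.

    Maintains between-cluster single-linkage (minimum cross distance) and
    complete-linkage (maximum cross distance) matrices, updated by the
    Lance–Williams rules ``min`` and ``max`` on each merge, so every step is a
    vectorized scan.  The extent of a merged cluster is
    ``max(extent_a, extent_b, complete_linkage(a, b))``.

    Passing the synapse ``table`` fills in each cluster's distinct presynaptic
    partners; without it, partner sets are empty.
    """
    n = len(distances)
    if n == 0:
        return ClusterSet(clusters=(), params=params)

    # deterministic tie-break key: smallest member synapse id (string order)
    ids = distances.synapse_ids
    order = {sid: rank for rank, sid in enumerate(sorted(ids))}
    min_rank = np.array([order[sid] for sid in ids], dtype=np.int64)

    loop = _merge_loop_numba if _HAVE_NUMBA else _merge_loop_python
    owner, extents = loop(
        np.ascontiguousarray(distances.matrix, dtype=np.float64),
        min_rank.copy(),
        float(params.d_nn),
        float(params.d_ext),
    )

    partner_of = None
    if table is not None:
        partner_of = {sid: table[sid].partner_id for sid in ids}

    clusters = []
    for k in np.unique(owner):
        syn_ids = frozenset(ids[i] for i in np.nonzero(owner == k)[0])
        partners = (
            frozenset(partner_of[sid] for sid in syn_ids)
            if partner_of is not None
            else frozenset()
        )
        clusters.append(
            SynapseCluster(
                member_synapses=syn_ids, member_partners=partners, extent=float(extents[k])
            )
        )
    # stable deterministic ordering by smallest member id
    clusters.sort(key=lambda c: min(c.member_synapses))
    return ClusterSet(clusters=tuple(clusters), params=params)


def _merge_loop_python(
    dist: np.ndarray, min_rank: np.ndarray, d_nn: float, d_ext: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reference numpy implementation of the constrained merge loop.

    Returns ``(owner, extents)``: for every input point the slot index of its
    final cluster, and per-slot extents.
    """
    n = dist.shape[0]
    sl = dist.copy()  # single linkage between current clusters
    cl = dist.copy()  # complete linkage between current clusters
    extents = np.zeros(n)
    owner = np.arange(n)
    alive = np.ones(n, dtype=bool)
    np.fill_diagonal(sl, np.inf)

    # candidate matrix: single linkage where the merge is admissible, inf
    # elsewhere; kept up to date incrementally (merging a,b alters neither sl
    # nor extents of other pairs)
    cand = np.where(
        (sl <= d_nn)
        & (np.maximum(np.maximum.outer(extents, extents), cl) <= d_ext),
        sl,
        np.inf,
    )

    def refresh_row(k: int) -> None:
        merged = np.maximum(np.maximum(extents[k], extents), cl[k, :])
        row = np.where((sl[k, :] <= d_nn) & (merged <= d_ext) & alive, sl[k, :], np.inf)
        row[k] = np.inf
        cand[k, :] = row
        cand[:, k] = row

    while True:
        best = cand.min()
        if not np.isfinite(best):
            break
        ii, jj = np.nonzero(cand == best)
        upper = ii < jj
        ii, jj = ii[upper], jj[upper]
        keys = [
            tuple(sorted((int(min_rank[i]), int(min_rank[j]))))
            for i, j in zip(ii, jj)
        ]
        pick = min(range(len(keys)), key=keys.__getitem__)
        a, b = int(ii[pick]), int(jj[pick])
        extents[a] = max(extents[a], extents[b], cl[a, b])
        owner[owner == b] = a
        min_rank[a] = min(min_rank[a], min_rank[b])
        sl[a, :] = np.minimum(sl[a, :], sl[b, :])
        sl[:, a] = sl[a, :]
        cl[a, :] = np.maximum(cl[a, :], cl[b, :])
        cl[:, a] = cl[a, :]
        sl[a, a] = np.inf
        alive[b] = False
        cand[b, :] = np.inf
        cand[:, b] = np.inf
        refresh_row(a)
    return owner, extents


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _merge_loop_numba(
        dist: np.ndarray, min_rank: np.ndarray, d_nn: float, d_ext: float
    ):  # pragma: no cover - exercised via cluster_synapses
        n = dist.shape[0]
        sl = dist.copy()
        cl = dist.copy()
        extents = np.zeros(n)
        owner = np.arange(n)
        alive = np.ones(n, dtype=numba.boolean)
        while True:
            best = np.inf
            a = -1
            b = -1
            key_lo = -1
            key_hi = -1
            for i in range(n):
                if not alive[i]:
                    continue
                for j in range(i + 1, n):
                    if not alive[j]:
                        continue
                    s = sl[i, j]
                    if s > d_nn:
                        continue
                    ext = extents[i]
                    if extents[j] > ext:
                        ext = extents[j]
                    if cl[i, j] > ext:
                        ext = cl[i, j]
                    if ext > d_ext:
                        continue
                    lo = min(min_rank[i], min_rank[j])
                    hi = max(min_rank[i], min_rank[j])
                    if s < best or (
                        s == best and (lo < key_lo or (lo == key_lo and hi < key_hi))
                    ):
                        best = s
                        a = i
                        b = j
                        key_lo = lo
                        key_hi = hi
            if a < 0:
                break
            ext = extents[a]
            if extents[b] > ext:
                ext = extents[b]
            if cl[a, b] > ext:
                ext = cl[a, b]
            extents[a] = ext
            for k in range(n):
                if owner[k] == b:
                    owner[k] = a
            if min_rank[b] < min_rank[a]:
                min_rank[a] = min_rank[b]
            for k in range(n):
                if sl[b, k] < sl[a, k]:
                    sl[a, k] = sl[b, k]
                    sl[k, a] = sl[b, k]
                if cl[b, k] > cl[a, k]:
                    cl[a, k] = cl[b, k]
                    cl[k, a] = cl[b, k]
            sl[a, a] = np.inf
            alive[b] = False
        return owner, extents


def filter_for_fratio(clusters: ClusterSet, table: SynapseTable) -> ClusterSet:
    """Drop clusters with a single synapse or synapses from a single partner.

    Clusters entering the F-ratio must carry information about within-cluster
    functional similarity, which requires at least two synapses from at least
    two distinct presynaptic partners.
    """
    kept = []
    for cluster in clusters:
        partners = frozenset(table[sid].partner_id for sid in cluster.member_synapses)
        if cluster.n_synapses >= 2 and len(partners) >= 2:
            kept.append(
                SynapseCluster(
                    member_synapses=cluster.member_synapses,
                    member_partners=partners,
                    extent=cluster.extent,
                )
            )
    return ClusterSet(clusters=tuple(kept), params=clusters.params)


def filter_multi_synapse(clusters: ClusterSet) -> ClusterSet:
    """Drop single-synapse clusters (used for cluster-frequency tabulation)."""
    kept = tuple(c for c in clusters if c.n_synapses >= 2)
    return ClusterSet(clusters=kept, params=clusters.params)


def cluster_size_table(clusters: ClusterSet, table: SynapseTable) -> pd.DataFrame:
    """Frequency of clusters of each synapse count.

    Returns one row per synapse count with columns ``synapse_count``,
    ``frequency`` and ``n_partners`` — the multiset of distinct-partner counts
    formatted like ``"1 (6x), 2 (3x)"``.
    """
    by_size: dict[int, list[int]] = {}
    for cluster in clusters:
        partners = frozenset(table[sid].partner_id for sid in cluster.member_synapses)
        by_size.setdefault(cluster.n_synapses, []).append(len(partners))
    rows = []
    for size in sorted(by_size):
        partner_counts = by_size[size]
        uniq = sorted(set(partner_counts))
        formatted = ", ".join(f"{u} ({partner_counts.count(u)}x)" for u in uniq)
        rows.append(
            {
                "synapse_count": size,
                "frequency": len(partner_counts),
                "n_partners": formatted,
            }
        )
    return pd.DataFrame(rows, columns=["synapse_count", "frequency", "n_partners"])
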