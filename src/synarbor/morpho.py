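"""Skeleton trees and along-neurite path metrics.

A traced neuron is represented as a rooted tree of 3D sample points (the SWC
convention): every node except the root points to a parent, and the edge to the
parent has the Euclidean length between the two sample positions.  All
distances used by the downstream analyses are *path* distances measured along
the neurites of this tree, never straight-line distances through the tissue
volume.

The root is the soma.  One node may additionally be tagged as the axon exit
point (where the axon leaves the ganglion); the unique root-to-exit path is the
*primary neurite*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "SkeletonNode",
    "Skeleton",
    "SynapseRecord",
    "SynapseTable",
    "SkeletonError",
    "SwcParseError",
    "read_swc",
    "write_swc",
]

#: SWC structure-type codes understood by the reader.
SWC_SOMA = 1
SWC_AXON = 2  # repurposed: flags the axon-exit node of the primary neurite

VALENCES = ("excitatory", "inhibitory", "unknown")
BEHAVIOR_LABELS = ("swim", "crawl", "local_bend", "unassigned")


class SkeletonError(ValueError):
    """Structural problem with a skeleton tree."""


class SwcParseError(SkeletonError):
    """Malformed SWC content; the message names the offending line or node."""


@dataclass(frozen=True)
class SkeletonNode:
    """One sample point of a skeletonized neurite.

    Parameters
    ----------
    node_id : int
        Positive integer identifier (SWC column 1).
    parent_id : int or None
        Identifier of the parent node; ``None`` for the root.
    position : ndarray, shape (3,)
        Coordinates in micrometres.
    radius : float
        Local neurite radius in micrometres (0 if unknown).
    tag : str
        One of ``soma`` (the root), ``neurite`` or ``axon_exit``.
    """

    node_id: int
    parent_id: int | None
    position: np.ndarray
    radius: float = 0.0
    tag: str = "neurite"

    def __post_init__(self) -> None:
        if self.node_id <= 0:
            raise SkeletonError(f"node ids must be positive, got {self.node_id}")
        if self.radius < 0:
            raise SkeletonError(f"node {self.node_id}: negative radius")
        if self.tag not in ("soma", "neurite", "axon_exit"):
            raise SkeletonError(f"node {self.node_id}: unknown tag {self.tag!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise SkeletonError(f"node {self.node_id}: position must be 3D")


class Skeleton:
    """A single connected rooted tree of :class:`SkeletonNode`.

    Edge lengths are Euclidean distances between a node and its parent.  The
    class pre-computes the distance of every node to the root, which makes the
    along-neurite metric between two nodes an O(depth) lowest-common-ancestor
    walk, and exposes a vectorized all-pairs routine based on Dijkstra on the
    sparse adjacency for batch queries.
    """

    def __init__(self, nodes: Iterable[SkeletonNode]):
        self.nodes: dict[int, SkeletonNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise SkeletonError(f"duplicate node id {node.node_id}")
            self.nodes[node.node_id] = node
        if not self.nodes:
            raise SkeletonError("skeleton has no nodes")

        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise SkeletonError(f"expected exactly one root, found {len(roots)}")
        self.root_id: int = roots[0].node_id
        if roots[0].tag != "soma":
            raise SkeletonError("the root node must be tagged 'soma'")
        if sum(1 for n in self.nodes.values() if n.tag == "soma") != 1:
            raise SkeletonError("exactly one node may be tagged 'soma'")
        exits = [n.node_id for n in self.nodes.values() if n.tag == "axon_exit"]
        if len(exits) > 1:
            raise SkeletonError(f"at most one axon_exit node allowed, found {len(exits)}")
        self.axon_exit_id: int | None = exits[0] if exits else None

        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise SwcParseError(
                    f"node {node.node_id} references absent parent {node.parent_id}"
                )

        # Edge lengths and depth (path distance to the root) per node; a walk
        # that revisits a node exposes a parent-pointer cycle.
        self.edge_length: dict[int, float] = {}
        self._depth: dict[int, float] = {self.root_id: 0.0}
        for node in self.nodes.values():
            if node.parent_id is None:
                continue
            parent = self.nodes[node.parent_id]
            length = float(np.linalg.norm(node.position - parent.position))
            if length <= 0:
                raise SkeletonError(
                    f"node {node.node_id}: zero-length edge to parent {node.parent_id}"
                )
            self.edge_length[node.node_id] = length
        self._compute_depths()

    def _compute_depths(self) -> None:
        for node_id in self.nodes:
            if node_id in self._depth:
                continue
            chain: list[int] = []
            current: int | None = node_id
            seen = set()
            while current is not None and current not in self._depth:
                if current in seen:
                    raise SkeletonError(f"cyclic parent links involving node {current}")
                seen.add(current)
                chain.append(current)
                current = self.nodes[current].parent_id
            for nid in reversed(chain):
                parent = self.nodes[nid].parent_id
                assert parent is not None
                self._depth[nid] = self._depth[parent] + self.edge_length[nid]

    # ------------------------------------------------------------------ basic

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.nodes)

    def cable_length(self) -> float:
        """Total path length of the arborization in µm (sum of edge lengths)."""
        return float(sum(self.edge_length.values()))

    def depth(self, node_id: int) -> float:
        """Path distance from ``node_id`` to the root in µm."""
        self._check(node_id)
        return self._depth[node_id]

    def _check(self, node_id: int) -> None:
        if node_id not in self.nodes:
            raise KeyError(f"unknown node id {node_id}")

    # ----------------------------------------------------------------- metric

    def path_distance(self, node_a: int, node_b: int) -> float:
        """Length in µm of the unique tree path between two nodes."""
        self._check(node_a)
        self._check(node_b)
        if node_a == node_b:
            return 0.0
        lca = self._lowest_common_ancestor(node_a, node_b)
        return self._depth[node_a] + self._depth[node_b] - 2.0 * self._depth[lca]

    def _lowest_common_ancestor(self, a: int, b: int) -> int:
        while a != b:
            if self._depth[a] >= self._depth[b]:
                a = self.nodes[a].parent_id if self.nodes[a].parent_id is not None else a
            else:
                b = self.nodes[b].parent_id if self.nodes[b].parent_id is not None else b
            if self.nodes[a].parent_id is None and self.nodes[b].parent_id is None:
                break
        return a

    def path_to_root(self, node_id: int) -> list[int]:
        """Node ids from ``node_id`` up to and including the root."""
        self._check(node_id)
        path = [node_id]
        while self.nodes[path[-1]].parent_id is not None:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def _adjacency(self):
        """Cached (node order, index map, CSR weighted adjacency)."""
        if not hasattr(self, "_adj_cache"):
            order = self.node_ids
            index = {nid: i for i, nid in enumerate(order)}
            rows, cols, weights = [], [], []
            for child, length in self.edge_length.items():
                parent = self.nodes[child].parent_id
                rows.append(index[child])
                cols.append(index[parent])
                weights.append(length)
            n = len(order)
            adj = coo_matrix(
                (weights + weights, (rows + cols, cols + rows)), shape=(n, n)
            ).tocsr()
            self._adj_cache = (order, index, adj)
        return self._adj_cache

    def pairwise_path_distances(self, node_ids: Sequence[int]) -> np.ndarray:
        """Matrix of path distances (µm) between the given nodes.

        Runs multi-source Dijkstra on the sparse weighted adjacency; on a tree
        this returns the exact unique-path lengths.
        """
        for nid in node_ids:
            self._check(nid)
        order, index, adj = self._adjacency()
        sources = np.array([index[nid] for nid in node_ids])
        if adj.nnz == 0:  # single-node tree
            return np.zeros((len(node_ids), len(node_ids)))
        full = dijkstra(adj, directed=False, indices=sources)
        return np.asarray(full[:, sources])

    def distances_from(self, node_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Path distances (µm) from one node to every node.

        Returns ``(node_ids, distances)`` over all skeleton nodes in sorted-id
        order; a single-source Dijkstra on the cached adjacency.
        """
        self._check(node_id)
        order, index, adj = self._adjacency()
        if adj.nnz == 0:
            return np.array(order), np.zeros(len(order))
        d = dijkstra(adj, directed=False, indices=index[node_id])
        return np.array(order), np.asarray(d)

    # -------------------------------------------------------- primary neurite

    def primary_neurite(self) -> list[int]:
        """Ordered node ids of the root→axon-exit path (the primary neurite)."""
        if self.axon_exit_id is None:
            raise SkeletonError(
                "no node is tagged 'axon_exit'; designate the exit node via the "
                "SWC axon type code or a config override"
            )
        return list(reversed(self.path_to_root(self.axon_exit_id)))

    def distance_to_primary_neurite(self, node_id: int) -> float:
        """Minimum path distance (µm) from a node to any primary-neurite node."""
        self._check(node_id)
        on_path = self._primary_set()
        # Walking rootward from the node, the first primary-neurite node hit is
        # the closest one: path distance to any other primary node passes
        # through it.
        dist = 0.0
        current = node_id
        while current not in on_path:
            parent = self.nodes[current].parent_id
            if parent is None:  # root is always on the path
                break
            dist += self.edge_length[current]
            current = parent
        return dist

    def _primary_set(self) -> frozenset[int]:
        if not hasattr(self, "_primary_cache"):
            self._primary_cache = frozenset(self.primary_neurite())
        return self._primary_cache


# --------------------------------------------------------------------- synapses


@dataclass(frozen=True)
class SynapseRecord:
    """One input synapse onto the postsynaptic neuron."""

    synapse_id: str
    attach_node: int
    partner_id: str
    valence: str = "unknown"
    behavior_label: str = "unassigned"

    def __post_init__(self) -> None:
        if not str(self.partner_id):
            raise ValueError(f"synapse {self.synapse_id}: empty partner id")
        if self.valence not in VALENCES:
            raise ValueError(f"synapse {self.synapse_id}: bad valence {self.valence!r}")
        if self.behavior_label not in BEHAVIOR_LABELS:
            raise ValueError(
                f"synapse {self.synapse_id}: bad behavior {self.behavior_label!r}"
            )


class SynapseTable:
    """Collection of :class:`SynapseRecord` keyed by unique synapse id."""

    def __init__(self, records: Iterable[SynapseRecord]):
        self.records: dict[str, SynapseRecord] = {}
        for rec in records:
            if rec.synapse_id in self.records:
                raise ValueError(f"duplicate synapse id {rec.synapse_id}")
            self.records[str(rec.synapse_id)] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __getitem__(self, synapse_id: str) -> SynapseRecord:
        return self.records[synapse_id]

    @property
    def synapse_ids(self) -> list[str]:
        return list(self.records)

    def validate_against(self, skeleton: Skeleton) -> None:
        for rec in self:
            if rec.attach_node not in skeleton:
                raise SkeletonError(
                    f"synapse {rec.synapse_id} attaches to unknown node {rec.attach_node}"
                )

    def partner_counts(self) -> pd.Series:
        """Number of synapses per presynaptic partner."""
        return self.to_frame().groupby("partner_id").size().sort_index()

    def by_partner(self) -> Mapping[str, list[SynapseRecord]]:
        out: dict[str, list[SynapseRecord]] = {}
        for rec in self:
            out.setdefault(rec.partner_id, []).append(rec)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "synapse_id": [r.synapse_id for r in self],
                "attach_node": [r.attach_node for r in self],
                "partner_id": [r.partner_id for r in self],
                "valence": [r.valence for r in self],
                "behavior_label": [r.behavior_label for r in self],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SynapseTable":
        required = {"synapse_id", "attach_node", "partner_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"synapse table missing columns: {sorted(missing)}")
        records = []
        for row in frame.itertuples(index=False):
            records.append(
                SynapseRecord(
                    synapse_id=str(row.synapse_id),
                    attach_node=int(row.attach_node),
                    partner_id=str(row.partner_id),
                    valence=getattr(row, "valence", "unknown") or "unknown",
                    behavior_label=getattr(row, "behavior_label", "unassigned")
                    or "unassigned",
                )
            )
        return cls(records)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SynapseTable":
        frame = pd.read_csv(path, dtype={"synapse_id": str, "partner_id": str})
        frame = frame.fillna(
            {"valence": "unknown", "behavior_label": "unassigned"}
        )
        return cls.from_frame(frame)


# ---------------------------------------------------------------- convenience


def distance_to_soma(skeleton: Skeleton, synapse: SynapseRecord) -> float:
    """Along-neurite distance in µm from a synapse's attachment node to the soma."""
    return skeleton.depth(synapse.attach_node)


def distance_to_primary_neurite(skeleton: Skeleton, synapse: SynapseRecord) -> float:
    """Along-neurite distance in µm from a synapse to the primary neurite."""
    return skeleton.distance_to_primary_neurite(synapse.attach_node)


# ------------------------------------------------------------------------ SWC


def read_swc(path: str | Path, axon_exit: int | None = None) -> Skeleton:
    """Read a 7-column SWC file into a :class:`Skeleton`.

    Columns are ``id type x y z radius parent`` (whitespace separated, ``#``
    comments, parent −1 for the root).  Type code 1 marks the soma; type code 2
    flags the axon-exit node.  ``axon_exit`` overrides/sets the exit node when
    the file does not carry the flag.
    """
    nodes: list[SkeletonNode] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                node_id = int(parts[0])
                type_code = int(parts[1])
                x, y, z, radius = map(float, parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"line {lineno}: {exc}") from None
            if type_code == SWC_SOMA:
                tag = "soma"
            elif type_code == SWC_AXON or node_id == axon_exit:
                tag = "axon_exit"
            else:
                tag = "neurite"
            nodes.append(
                SkeletonNode(
                    node_id=node_id,
                    parent_id=None if parent < 0 else parent,
                    position=np.array([x, y, z]),
                    radius=radius,
                    tag=tag,
                )
            )
    if axon_exit is not None and not any(n.tag == "axon_exit" for n in nodes):
        raise SwcParseError(f"axon_exit override names absent node {axon_exit}")
    return Skeleton(nodes)


def write_swc(skeleton: Skeleton, path: str | Path) -> None:
    """Write a skeleton as 7-column SWC (soma type 1, axon-exit type 2)."""
    with open(path, "w") as handle:
        handle.write("# id type x y z radius parent\n")
        for node_id in skeleton.node_ids:
            node = skeleton.nodes[node_id]
            if node.tag == "soma":
                code = SWC_SOMA
            elif node.tag == "axon_exit":
                code = SWC_AXON
            else:
                code = 3
            parent = -1 if node.parent_id is None else node.parent_id
            x, y, z = node.position
            handle.write(
                f"{node_id} {code} {x:.6f} {y:.6f} {z:.6f} {node.radius:.6f} {parent}\n"
            )


def cable_length(skeleton: Skeleton) -> float:
    """Total cable length of the skeleton in µm."""
    return skeleton.cable_length()


def primary_neurite(skeleton: Skeleton) -> list[int]:
    """Ordered node ids of the soma→axon-exit path."""
    return skeleton.primary_neurite()


def path_distance(skeleton: Skeleton, node_a: int, node_b: int) -> float:
    """Along-neurite distance between two skeleton nodes in µm."""
    return skeleton.path_distance(node_a, node_b)
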