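"""Shared fixtures: small hand-built skeletons and synapse tables."""

from __future__ import annotations

import numpy as np
import pytest

from synarbor.morpho import Skeleton, SkeletonNode, SynapseRecord, SynapseTable


@pytest.fixture
def chain_skeleton() -> Skeleton:
    """Root—a—b chain with edge lengths 2 µm and 3 µm; b is the axon exit."""
    return Skeleton(
        [
            SkeletonNode(1, None, [0.0, 0.0, 0.0], tag="soma"),
            SkeletonNode(2, 1, [2.0, 0.0, 0.0]),
            SkeletonNode(3, 2, [5.0, 0.0, 0.0], tag="axon_exit"),
        ]
    )


@pytest.fixture
def y_skeleton() -> Skeleton:
    """Y-shaped tree: root with a 4 µm trunk splitting into 7 µm and 5 µm arms.

    The 7 µm left arm tip is the axon exit.
    """
    return Skeleton(
        [
            SkeletonNode(1, None, [0.0, 0.0, 0.0], tag="soma"),
            SkeletonNode(2, 1, [4.0, 0.0, 0.0]),
            SkeletonNode(3, 2, [4.0, 7.0, 0.0], tag="axon_exit"),
            SkeletonNode(4, 2, [4.0, 0.0, 5.0]),
        ]
    )


def random_tree(rng: np.random.Generator, n_nodes: int) -> Skeleton:
    """Random rooted tree with uniform random parent choice and 3D positions."""
    nodes = [SkeletonNode(1, None, rng.normal(size=3), tag="soma")]
    for node_id in range(2, n_nodes + 1):
        parent = int(rng.integers(1, node_id))
        pos = nodes[parent - 1].position + rng.normal(size=3) * rng.uniform(0.5, 3.0)
        nodes.append(SkeletonNode(node_id, parent, pos))
    return Skeleton(nodes)


@pytest.fixture
def tree_factory():
    return random_tree


def table_on_nodes(node_ids, partners=None) -> SynapseTable:
    """Synapse table with one synapse per given node."""
    partners = partners or [f"P{i}" for i in range(len(node_ids))]
    return SynapseTable(
        [
            SynapseRecord(synapse_id=f"s{i:02d}", attach_node=int(n), partner_id=p)
            for i, (n, p) in enumerate(zip(node_ids, partners))
        ]
    )
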