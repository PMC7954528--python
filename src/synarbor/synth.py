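"""Synthetic data with known ground truth for the anatomy–activity pipeline.

The generators emulate the statistical structure the analysis assumes, at the
scale of the real preparation: a ~6,000 µm arborization carrying a few hundred
synapses from ~50 presynaptic partners, per-partner complex coherence values
organized in Gaussian clouds in the complex plane, and rhythmic optical traces
(~2 Hz swim-like or slower crawl-like) with bleaching trends and noise.

In ``clustered`` placement mode each planted spatial cluster is built from a
small set of partners whose synapses are locally concentrated (partner
"runs"), which mirrors how an axon innervates a stretch of neurite with
several nearby boutons, and a configurable fraction of background synapses
from randomly chosen partners is sprinkled uniformly over the arbor.  With
``aligned`` signal coupling the partners of one planted cluster share one
functional group (their coherence values cluster in the complex plane);
``independent`` coupling breaks that link while keeping the spatial structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from synarbor.coherence import TrialRecording
from synarbor.morpho import Skeleton, SkeletonNode, SynapseRecord, SynapseTable

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "synth_skeleton",
    "synth_synapses",
    "synth_coherence",
    "synth_timeseries",
]


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic-data generators (units in field names/comments)."""

    seed: int = 0
    # skeleton
    n_branch_points: int = 40
    mean_segment_um: float = 150.0
    target_cable_um: float = 6000.0
    node_spacing_um: float = 0.5
    # synapses
    n_partners: int = 50
    n_synapses: int = 450
    placement_mode: str = "uniform"  # or "clustered"
    planted_extent_um: float = 60.0
    planted_n_clusters: int = 14
    partners_per_cluster: int = 2
    cross_gap_um: float = 6.2  # synapse-free gap between adjacent bouton runs
    decoy_offsets_um: tuple[float, ...] = (7.0,)  # decoy pairs beyond each end
    background_fraction: float = 0.05  # synapses from random partners off the clusters
    background_margin_um: float = 10.0  # clearance between regions and background
    # functional groups in the complex plane
    n_functional_groups: int = 3
    group_phases: tuple[float, ...] = (0.0, 2.0 * math.pi / 3.0, -2.0 * math.pi / 3.0)
    group_magnitudes: tuple[float, ...] = (0.6, 0.6, 0.6)
    z_noise_sd: float = 0.05
    signal_coupling: str = "aligned"  # or "independent"
    # time series
    rhythm_hz: float = 2.0
    trial_s: float = 30.0
    dt_s: float = 0.02
    snr: float = 10.0
    bleach_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.placement_mode not in ("uniform", "clustered"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")
        if self.signal_coupling not in ("aligned", "independent"):
            raise ValueError(f"unknown signal_coupling {self.signal_coupling!r}")
        if min(self.n_partners, self.n_synapses, self.planted_n_clusters) <= 0:
            raise ValueError("counts must be positive")
        if self.placement_mode == "clustered" and self.planted_extent_um <= 0:
            raise ValueError("planted_extent_um must be positive in clustered mode")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")
        if any(not (0.0 <= m <= 1.0) for m in self.group_magnitudes):
            raise ValueError("group magnitudes must lie in [0, 1]")
        if len(self.group_phases) < self.n_functional_groups:
            raise ValueError("need a phase per functional group")
        if len(self.group_magnitudes) < self.n_functional_groups:
            raise ValueError("need a magnitude per functional group")


@dataclass
class GroundTruth:
    """What the generator planted, for test harnesses and recovery checks."""

    planted_extent_um: float = 0.0
    rhythm_hz: float = 0.0
    synapse_to_cluster: dict[str, int] = field(default_factory=dict)
    partner_to_group: dict[str, int] = field(default_factory=dict)
    cluster_to_group: dict[int, int] = field(default_factory=dict)
    cluster_center_node: dict[int, int] = field(default_factory=dict)
    partner_phase: dict[str, float] = field(default_factory=dict)
    partner_magnitude: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["synapse_to_cluster"] = {str(k): v for k, v in self.synapse_to_cluster.items()}
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, default=str)


# ------------------------------------------------------------------- skeleton


def synth_skeleton(config: SynthConfig) -> Skeleton:
    """Random rooted tree with the configured total cable length.

    Segments with exponentially distributed lengths (mean ``mean_segment_um``)
    are attached to randomly chosen existing branch endpoints (at most two
    children each, giving a binary tree) and sampled into nodes every
    ``node_spacing_um`` so that synapses can attach anywhere along the cable.
    Growth stops when the cable length first reaches ``target_cable_um``; one
    randomly chosen leaf is flagged as the axon exit.
    """
    rng = np.random.default_rng(config.seed)
    nodes: list[SkeletonNode] = [
        SkeletonNode(node_id=1, parent_id=None, position=np.zeros(3), tag="soma")
    ]
    positions = {1: np.zeros(3)}
    children_count = {1: 0}
    endpoints = [1]  # candidates for attaching a new segment
    next_id = 2
    cable = 0.0
    while cable < config.target_cable_um:
        # prefer endpoints with open slots; binary branching: at most 2 children
        open_nodes = [n for n in endpoints if children_count[n] < 2]
        if not open_nodes:
            open_nodes = [n for n in children_count if children_count[n] < 2]
        attach = int(rng.choice(open_nodes))
        length = float(rng.exponential(config.mean_segment_um))
        length = max(length, config.node_spacing_um)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n_steps = max(int(round(length / config.node_spacing_um)), 1)
        step = length / n_steps
        parent = attach
        for k in range(1, n_steps + 1):
            pos = positions[attach] + direction * step * k
            nodes.append(
                SkeletonNode(node_id=next_id, parent_id=parent, position=pos)
            )
            positions[next_id] = pos
            children_count[next_id] = 0
            children_count[parent] += 1
            parent = next_id
            next_id += 1
        endpoints.append(parent)  # the new segment tip is a branch candidate
        cable += length

    # flag a random leaf (a node with no children, other than the root)
    leaves = [n for n, c in children_count.items() if c == 0 and n != 1]
    exit_id = int(rng.choice(leaves))
    final = [
        SkeletonNode(
            node_id=n.node_id,
            parent_id=n.parent_id,
            position=n.position,
            radius=n.radius,
            tag="axon_exit" if n.node_id == exit_id else n.tag,
        )
        for n in nodes
    ]
    return Skeleton(final)


# ------------------------------------------------------------------- synapses


def _edge_weighted_node_choice(
    skeleton: Skeleton, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Sample non-root node ids ~ uniform over cable (weight = edge length)."""
    ids = np.array([nid for nid in skeleton.node_ids if nid != skeleton.root_id])
    weights = np.array([skeleton.edge_length[nid] for nid in ids])
    weights = weights / weights.sum()
    return rng.choice(ids, size=size, p=weights)


def synth_synapses(
    skeleton: Skeleton, config: SynthConfig
) -> tuple[SynapseTable, GroundTruth]:
    """Place synapses on the skeleton and assign presynaptic partners.

    ``uniform`` mode places every synapse uniformly over the cable with a
    uniformly random partner.  ``clustered`` mode plants
    ``planted_n_clusters`` spatial clusters of extent ``planted_extent_um``:
    cluster centers are drawn uniformly over the cable (with rejection so that
    distinct clusters do not overlap), each cluster is served by
    ``partners_per_cluster`` dedicated partners whose synapses form short
    local runs inside the cluster, and a ``background_fraction`` of synapses
    is sprinkled uniformly with random partners.  With ``aligned`` coupling a
    cluster's partners all come from the functional group assigned to that
    cluster; with ``independent`` coupling partner↔group assignment is
    unrelated to space.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    partners = [f"P{k:03d}" for k in range(config.n_partners)]
    truth = GroundTruth(
        planted_extent_um=config.planted_extent_um
        if config.placement_mode == "clustered"
        else 0.0,
        rhythm_hz=config.rhythm_hz,
    )

    records: list[SynapseRecord] = []
    if config.placement_mode == "uniform":
        attach = _edge_weighted_node_choice(skeleton, rng, config.n_synapses)
        chosen = rng.choice(len(partners), size=config.n_synapses)
        for s in range(config.n_synapses):
            sid = f"S{s:04d}"
            records.append(
                SynapseRecord(
                    synapse_id=sid,
                    attach_node=int(attach[s]),
                    partner_id=partners[int(chosen[s])],
                )
            )
            truth.synapse_to_cluster[sid] = -1
        for k, p in enumerate(partners):
            truth.partner_to_group[p] = int(k % config.n_functional_groups)
    else:
        truth = _plant_clusters(skeleton, config, rng, partners, truth)
        records = truth._records  # type: ignore[attr-defined]
        del truth._records  # type: ignore[attr-defined]

    table = SynapseTable(records)
    _fill_functional_truth(config, truth, rng)
    return table, truth


def _plant_clusters(
    skeleton: Skeleton,
    config: SynthConfig,
    rng: np.random.Generator,
    partners: list[str],
    truth: GroundTruth,
) -> GroundTruth:
    """Plant path-shaped synapse clusters with partner bouton runs.

    Each planted cluster occupies a geodesic of length ``planted_extent_um``
    along the arbor.  The cluster's partners innervate consecutive bouton runs
    along that path (for the default two partners: one run at each end,
    separated by a synapse-free middle gap), so the cluster's realized extent
    matches the planted extent and the cluster only assembles, under
    constrained single-linkage, once ``d_ext`` reaches it.  Background
    synapses from random partners are excluded from the tree neighborhood in
    which their absorption would not stretch a cluster beyond its extent;
    beyond the path ends they are allowed and produce the dilution of the
    F-ratio at larger ``d_ext``.
    """
    extent = config.planted_extent_um
    if extent > skeleton.cable_length():
        raise ValueError("planted cluster extent exceeds the total cable length")
    k_partners = max(config.partners_per_cluster, 2)
    # keep at least two partners out of the clusters for background/decoys
    n_clusters = max(
        1, min(config.planted_n_clusters, (len(partners) - 2) // k_partners)
    )
    tol = max(config.node_spacing_um, 1.0)

    order, _ = skeleton.distances_from(skeleton.root_id)
    all_ids = np.array(order)
    not_root = all_ids != skeleton.root_id
    weights = np.array(
        [skeleton.edge_length[int(n)] if n != skeleton.root_id else 0.0 for n in all_ids]
    )
    weights = weights / weights.sum()

    # choose geodesic paths of the planted extent, mutually separated
    min_separation = 1.5 * extent
    paths: list[dict] = []
    blocked = np.zeros(all_ids.shape, dtype=bool)  # too close to an accepted path
    tries = 0
    while len(paths) < n_clusters:
        tries += 1
        if tries > 400 * n_clusters:
            raise ValueError(
                "could not place non-overlapping planted clusters; reduce "
                "planted_n_clusters or planted_extent_um"
            )
        u_pos = int(rng.choice(all_ids.size, p=weights))
        if blocked[u_pos]:
            continue
        u = int(all_ids[u_pos])
        _, d_u = skeleton.distances_from(u)
        candidates = np.nonzero(
            (d_u >= extent - 3.0) & (d_u <= extent - 1.0) & not_root & ~blocked
        )[0]
        if candidates.size == 0:
            continue
        v_pos = int(rng.choice(candidates))
        v = int(all_ids[v_pos])
        _, d_v = skeleton.distances_from(v)
        length = d_u[v_pos]
        on_path = (d_u + d_v <= length + tol) & not_root
        if blocked[on_path].any():
            continue
        paths.append({"u": u, "v": v, "d_u": d_u, "d_v": d_v, "length": length,
                      "on_path": on_path})
        blocked |= np.minimum(d_u, d_v) <= length / 2.0 + min_separation

    # partner bookkeeping: dedicated partners per cluster, remainder = background pool
    n_dedicated = min(k_partners * n_clusters, len(partners))
    dedicated = np.array(partners[:n_dedicated])
    background_pool = partners[n_dedicated:] or partners
    cluster_partners = {
        c: list(dedicated[c * k_partners : (c + 1) * k_partners])
        for c in range(n_clusters)
    }

    # group assignment: aligned -> cluster's partners share the cluster's group;
    # independent -> groups assigned round-robin over partners regardless of space
    for c in range(n_clusters):
        truth.cluster_to_group[c] = int(c % config.n_functional_groups)
    for c in range(n_clusters):
        for p in cluster_partners[c]:
            truth.partner_to_group[p] = truth.cluster_to_group[c]
    # background partners are functionally unrelated to any group: they get
    # diffuse coherence values (group -1)
    for p in background_pool:
        if p not in truth.partner_to_group:
            truth.partner_to_group[p] = -1
    if config.signal_coupling == "independent":
        # same functional value pool, but the partner<->function assignment is
        # shuffled so synapse placement carries no information about function
        keys = sorted(truth.partner_to_group)
        values = [truth.partner_to_group[k] for k in keys]
        perm = rng.permutation(len(keys))
        truth.partner_to_group = {keys[i]: values[int(perm[i])] for i in range(len(keys))}

    n_background = int(round(config.background_fraction * config.n_synapses))
    n_decoys = 2 * 2 * len(config.decoy_offsets_um) * n_clusters
    n_planted = max(config.n_synapses - n_background - n_decoys, 4 * n_clusters)
    per_cluster = np.full(n_clusters, n_planted // n_clusters)
    per_cluster[: n_planted % n_clusters] += 1

    records: list[SynapseRecord] = []
    sid_counter = 0
    bg_allowed = not_root.copy()
    decoy_sites: list[int] = []  # nodes just beyond path ends, for decoy pairs
    gap = config.cross_gap_um
    for c, path in enumerate(paths):
        truth.cluster_center_node[c] = path["u"]
        members = cluster_partners[c]
        k = len(members)
        length = path["length"]
        run_len = (length - (k - 1) * gap) / k
        n_syn = int(per_cluster[c])
        per_partner = np.full(k, n_syn // k)
        per_partner[: n_syn % k] += 1
        d_u = path["d_u"]
        on_path = path["on_path"]
        path_positions = np.nonzero(on_path)[0]
        path_d = d_u[path_positions]
        for p_idx, partner in enumerate(members):
            lo = p_idx * (run_len + gap)
            # boutons: one pinned at each run edge (so the realized extent and
            # the cross-gaps match the construction), the rest stratified
            n_b = int(per_partner[p_idx])
            if n_b >= 2:
                interior = lo + (
                    np.arange(n_b - 2) + rng.uniform(0.05, 0.95, size=max(n_b - 2, 0))
                ) * (run_len / max(n_b - 2, 1))
                offsets = np.concatenate([[lo], interior, [lo + run_len]])
            else:
                offsets = np.array([lo + run_len / 2.0])
            for off in offsets:
                node = int(all_ids[path_positions[np.argmin(np.abs(path_d - off))]])
                sid = f"S{sid_counter:04d}"
                sid_counter += 1
                records.append(
                    SynapseRecord(synapse_id=sid, attach_node=node, partner_id=partner)
                )
                truth.synapse_to_cluster[sid] = c
        # decoy sites on the continuing neurite just beyond each path end
        d_v = path["d_v"]
        for d_end, d_far in ((d_u, d_v), (d_v, d_u)):
            for offset in config.decoy_offsets_um:
                beyond = np.nonzero(
                    not_root
                    & (np.abs(d_far - length - d_end) <= tol)
                    & (np.abs(d_end - offset) <= 2.0)
                )[0]
                if beyond.size:
                    best = beyond[np.argmin(np.abs(d_end[beyond] - offset))]
                    decoy_sites.append(int(all_ids[best]))
        # exclude uniform background wherever its absorption would not stretch
        # the cluster beyond its planted extent
        margin = config.background_margin_um
        bg_allowed &= np.maximum(d_u, d_v) >= length + margin

    # decoy pairs: two synapses from two unrelated partners at each decoy
    # site; they are legitimate (impure) clusters at small d_ext and are
    # absorbed into the planted cluster once d_ext exceeds its extent
    flank_nodes = [site for site in decoy_sites for _ in range(2)]

    # uniform background tops up to exactly n_synapses (decoy sites can fall
    # short when a path end terminates at a leaf)
    n_uniform = config.n_synapses - n_planted - len(flank_nodes)
    outside = all_ids[bg_allowed]
    if outside.size == 0:
        outside = all_ids[not_root]
    out_weights = np.array([skeleton.edge_length[int(n)] for n in outside])
    out_weights = out_weights / out_weights.sum()
    uniform_nodes = rng.choice(outside, size=n_uniform, p=out_weights)
    background_nodes = np.array(flank_nodes + [int(n) for n in uniform_nodes])
    background_partners = []
    pool = sorted(background_pool)
    for k in range(0, len(flank_nodes), 2):
        j = k % max(len(pool) - 1, 1)
        background_partners.extend([pool[j], pool[(j + 1) % len(pool)]])
    background_partners = background_partners[: len(flank_nodes)]
    background_partners.extend(
        str(p) for p in rng.choice(pool, size=n_uniform)
    )
    for k in range(len(background_nodes)):
        sid = f"S{sid_counter:04d}"
        sid_counter += 1
        records.append(
            SynapseRecord(
                synapse_id=sid,
                attach_node=int(background_nodes[k]),
                partner_id=str(background_partners[k]),
            )
        )
        truth.synapse_to_cluster[sid] = -1

    truth._records = records  # type: ignore[attr-defined]
    return truth


def _fill_functional_truth(
    config: SynthConfig, truth: GroundTruth, rng: np.random.Generator
) -> None:
    """Planted phase/magnitude per partner: group values, or diffuse if ungrouped."""
    ungrouped_index = 0
    for partner in sorted(truth.partner_to_group):
        group = truth.partner_to_group[partner]
        if group >= 0:
            truth.partner_phase[partner] = float(config.group_phases[group])
            truth.partner_magnitude[partner] = float(config.group_magnitudes[group])
        else:
            # ungrouped partners alternate between two antiphase lobes, like
            # convergent inputs of opposite sign; consecutive pool partners
            # are therefore maximally dissimilar in the complex plane
            j = ungrouped_index
            ungrouped_index += 1
            truth.partner_phase[partner] = float(
                (j % 2) * math.pi + rng.uniform(-0.4, 0.4)
            )
            truth.partner_magnitude[partner] = float(rng.uniform(0.45, 0.7))


# ------------------------------------------------------------------ coherence


def synth_coherence(
    config: SynthConfig,
    truth: GroundTruth,
    behaviors: Sequence[str] = ("swim",),
) -> dict[str, dict[str, complex]]:
    """Per-partner complex coherence values per behavior.

    A partner in functional group g gets z = m_g·exp(i·φ_g) plus complex
    Gaussian noise (sd ``z_noise_sd`` per axis), clipped to |z| ≤ 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    out: dict[str, dict[str, complex]] = {}
    partners = sorted(truth.partner_to_group)
    for behavior in behaviors:
        z_map: dict[str, complex] = {}
        for partner in partners:
            base = truth.partner_magnitude[partner] * np.exp(
                1j * truth.partner_phase[partner]
            )
            noise = rng.normal(scale=config.z_noise_sd) + 1j * rng.normal(
                scale=config.z_noise_sd
            )
            z = complex(base + noise)
            if abs(z) > 1.0:
                z /= abs(z)
            z_map[partner] = z
        out[behavior] = z_map
    return out


# ----------------------------------------------------------------- timeseries


def synth_timeseries(
    config: SynthConfig,
    truth: GroundTruth,
    behavior: str = "swim",
    trial_id: str = "trial01",
    reference_cell: str = "ref",
) -> TrialRecording:
    """Rhythmic per-cell traces with bleaching and noise.

    Every partner becomes one recorded cell whose trace oscillates at
    ``rhythm_hz`` lagging the reference by its planted coherence phase, with
    amplitude proportional to its planted magnitude, plus an exponential
    bleaching trend (total excursion ``bleach_fraction``) and white noise set
    by ``snr`` (reference RMS amplitude over noise standard deviation).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    n = int(round(config.trial_s / config.dt_s))
    t = np.arange(n) * config.dt_s
    omega = 2.0 * math.pi * config.rhythm_hz
    noise_sd = (1.0 / math.sqrt(2.0)) / config.snr if config.snr > 0 else 0.0
    bleach = -config.bleach_fraction * (1.0 - np.exp(-t / (config.trial_s / 2.0)))

    data: dict[str, np.ndarray] = {}
    data[reference_cell] = (
        np.cos(omega * t) + bleach + rng.normal(scale=noise_sd, size=n)
    )
    for partner in sorted(truth.partner_to_group):
        amp = max(truth.partner_magnitude[partner], 0.05)
        phase = truth.partner_phase[partner]
        data[partner] = (
            amp * np.cos(omega * t - phase)
            + bleach
            + rng.normal(scale=noise_sd, size=n)
        )
    traces = pd.DataFrame(data)
    return TrialRecording(
        trial_id=trial_id,
        behavior=behavior,
        dt=config.dt_s,
        traces=traces,
        reference_cell=reference_cell,
    )
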