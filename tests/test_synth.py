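"""Synthetic-data generators: determinism, planted structure, ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from synarbor import morpho
from synarbor.clustering import pairwise_distances
from synarbor.coherence import coherence_map, default_options, dominant_frequency
from synarbor.cohstats import complex_f_ratio
from synarbor.synth import (
    SynthConfig,
    synth_coherence,
    synth_skeleton,
    synth_synapses,
    synth_timeseries,
)

SMALL = dict(target_cable_um=1200.0, n_synapses=80, n_partners=12,
             planted_n_clusters=3, background_fraction=0.1)


class TestSynthSkeleton:
    def test_stopping_rule(self):
        config = SynthConfig(seed=0, target_cable_um=100.0, mean_segment_um=20.0)
        skeleton = synth_skeleton(config)
        assert skeleton.cable_length() >= 100.0
        # overshoot bounded by one segment; exponential tail bound at 20x mean
        assert skeleton.cable_length() < 100.0 + 20.0 * 20.0

    def test_deterministic_given_seed(self, tmp_path):
        config = SynthConfig(seed=5, target_cable_um=500.0)
        a, b = synth_skeleton(config), synth_skeleton(config)
        pa, pb = tmp_path / "a.swc", tmp_path / "b.swc"
        morpho.write_swc(a, pa)
        morpho.write_swc(b, pb)
        assert pa.read_text() == pb.read_text()

    def test_mean_cable_near_target(self):
        # mean over seeds within 10% of target (overshoot is half a mean
        # segment on average, small relative to the target)
        config = dict(target_cable_um=1500.0, mean_segment_um=150.0)
        cables = [
            synth_skeleton(SynthConfig(seed=s, **config)).cable_length()
            for s in range(25)
        ]
        assert abs(np.mean(cables) - 1500.0) / 1500.0 < 0.10

    def test_has_axon_exit_leaf(self):
        skeleton = synth_skeleton(SynthConfig(seed=1, target_cable_um=300.0))
        assert skeleton.axon_exit_id is not None
        path = skeleton.primary_neurite()
        assert path[0] == skeleton.root_id and path[-1] == skeleton.axon_exit_id


class TestSynthSynapses:
    def test_row_count_exact_both_modes(self):
        for mode in ("uniform", "clustered"):
            config = SynthConfig(seed=2, placement_mode=mode, **SMALL)
            skeleton = synth_skeleton(config)
            table, truth = synth_synapses(skeleton, config)
            assert len(table) == config.n_synapses
            assert set(truth.synapse_to_cluster) == set(table.synapse_ids)

    def test_planted_cluster_diameter_bounded_by_extent(self):
        config = SynthConfig(seed=3, placement_mode="clustered", **SMALL)
        skeleton = synth_skeleton(config)
        table, truth = synth_synapses(skeleton, config)
        matrix = pairwise_distances(skeleton, table)
        index = {sid: i for i, sid in enumerate(matrix.synapse_ids)}
        for c in range(config.planted_n_clusters):
            members = [
                index[s] for s, k in truth.synapse_to_cluster.items() if k == c
            ]
            sub = matrix.matrix[np.ix_(members, members)]
            assert sub.max() <= config.planted_extent_um + 1e-6

    def test_aligned_clusters_are_functionally_pure(self):
        config = SynthConfig(seed=4, placement_mode="clustered",
                             signal_coupling="aligned", **SMALL)
        skeleton = synth_skeleton(config)
        table, truth = synth_synapses(skeleton, config)
        for c, g in truth.cluster_to_group.items():
            partners = {
                table[s].partner_id
                for s, k in truth.synapse_to_cluster.items() if k == c
            }
            assert {truth.partner_to_group[p] for p in partners} == {g}

    def test_independent_coupling_preserves_value_pool(self):
        kwargs = dict(placement_mode="clustered", **SMALL)
        aligned = SynthConfig(seed=5, signal_coupling="aligned", **kwargs)
        independent = SynthConfig(seed=5, signal_coupling="independent", **kwargs)
        sk = synth_skeleton(aligned)
        _, truth_a = synth_synapses(sk, aligned)
        _, truth_i = synth_synapses(sk, independent)
        assert sorted(truth_a.partner_to_group.values()) == sorted(
            truth_i.partner_to_group.values()
        )
        assert truth_a.partner_to_group != truth_i.partner_to_group

    def test_uniform_placement_tracks_cable_density(self):
        # synapse counts per subtree scale with subtree cable length
        config = SynthConfig(seed=6, placement_mode="uniform",
                             target_cable_um=2000.0, n_synapses=1000)
        skeleton = synth_skeleton(config)
        table, _ = synth_synapses(skeleton, config)
        depth_of = {nid: skeleton.depth(nid) for nid in skeleton.node_ids}
        median_depth = float(np.median(list(depth_of.values())))
        cable_near = sum(
            length for nid, length in skeleton.edge_length.items()
            if depth_of[nid] <= median_depth
        )
        frac_cable = cable_near / skeleton.cable_length()
        frac_syn = np.mean(
            [depth_of[rec.attach_node] <= median_depth for rec in table]
        )
        assert abs(frac_syn - frac_cable) < 0.05

    def test_oversized_extent_rejected(self):
        config = SynthConfig(seed=7, placement_mode="clustered",
                             target_cable_um=150.0, mean_segment_um=30.0,
                             planted_extent_um=400.0,
                             planted_n_clusters=1, n_synapses=20, n_partners=4)
        skeleton = synth_skeleton(config)
        with pytest.raises(ValueError):
            synth_synapses(skeleton, config)


class TestSynthCoherence:
    def _truth(self, config):
        skeleton = synth_skeleton(config)
        _, truth = synth_synapses(skeleton, config)
        return truth

    def test_zero_noise_gives_identical_group_values(self):
        config = SynthConfig(seed=8, placement_mode="clustered",
                             z_noise_sd=0.0, **SMALL)
        truth = self._truth(config)
        z = synth_coherence(config, truth, ["swim"])["swim"]
        by_group = {}
        for partner, group in truth.partner_to_group.items():
            if group >= 0:
                by_group.setdefault(group, set()).add(z[partner])
        for values in by_group.values():
            assert len(values) == 1

    def test_single_group_f_ratio_is_one(self):
        config = SynthConfig(seed=9, placement_mode="uniform",
                             n_functional_groups=1, z_noise_sd=0.02,
                             group_phases=(0.5,), group_magnitudes=(0.6,), **SMALL)
        truth = self._truth(config)
        z = synth_coherence(config, truth, ["swim"])["swim"]
        partners = sorted(z)
        res = complex_f_ratio([[z[p] for p in partners[:6]],
                               [z[p] for p in partners[6:]]])
        # same distribution in both clusters: F near 1
        assert res.f == pytest.approx(1.0, abs=0.6)

    def test_three_displaced_groups_elevate_f(self):
        hits = 0
        for seed in range(20):
            config = SynthConfig(seed=seed, placement_mode="uniform",
                                 z_noise_sd=0.1, **SMALL)
            truth = self._truth(config)
            z = synth_coherence(config, truth, ["swim"])["swim"]
            groups = {}
            for partner, g in truth.partner_to_group.items():
                groups.setdefault(g, []).append(z[partner])
            res = complex_f_ratio(list(groups.values()))
            hits += res.f > 1.0
        assert hits >= 19

    def test_planted_grouping_detected_by_permutation(self):
        from synarbor.cohstats import permutation_p

        hits = 0
        for seed in range(20):
            config = SynthConfig(seed=seed, placement_mode="clustered",
                                 signal_coupling="aligned", **SMALL)
            truth = self._truth(config)
            z = synth_coherence(config, truth, ["swim"])["swim"]
            groups: dict[int, list[str]] = {}
            for partner, g in truth.partner_to_group.items():
                if g >= 0:
                    groups.setdefault(g, []).append(partner)
            clusters = [sorted(m) for m in groups.values()]
            res = permutation_p(clusters, z, n_shuffles=400, seed=seed)
            hits += res.p_hat < 0.05
        assert hits >= 19

    def test_magnitudes_clipped_to_unit_disc(self):
        config = SynthConfig(seed=10, placement_mode="uniform",
                             z_noise_sd=0.8, **SMALL)
        truth = self._truth(config)
        z = synth_coherence(config, truth, ["swim"])["swim"]
        assert all(abs(v) <= 1.0 + 1e-12 for v in z.values())


class TestSynthTimeseries:
    def _setup(self, **overrides):
        config = SynthConfig(seed=11, placement_mode="clustered",
                             **{**SMALL, **overrides})
        skeleton = synth_skeleton(config)
        _, truth = synth_synapses(skeleton, config)
        return config, truth

    def test_reference_self_coherence(self):
        config, truth = self._setup()
        trial = synth_timeseries(config, truth)
        records = {r.cell_id: r for r in coherence_map(trial)}
        assert records["ref"].magnitude == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_phases_recovered(self):
        config, truth = self._setup(snr=0.0, bleach_fraction=0.0)
        # snr=0 disables noise in this generator (treated as infinite SNR)
        trial = synth_timeseries(config, truth)
        records = {r.cell_id: r for r in coherence_map(trial)}
        for partner, phase in truth.partner_phase.items():
            err = np.angle(np.exp(1j * (records[partner].phase - phase)))
            assert abs(err) < 0.02

    def test_dominant_frequency_recovered_at_snr10(self):
        config, truth = self._setup(snr=10.0)
        trial = synth_timeseries(config, truth)
        opts = default_options(trial.behavior)
        f = dominant_frequency(
            trial.traces["ref"].to_numpy(), trial.dt, opts
        )
        assert f == pytest.approx(config.rhythm_hz, abs=1.0 / config.trial_s)

    def test_deterministic_given_seed(self):
        config, truth = self._setup()
        a = synth_timeseries(config, truth)
        b = synth_timeseries(config, truth)
        assert a.traces.equals(b.traces)
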