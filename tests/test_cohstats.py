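"""Complex-coherence F-ratio, permutation null, and supporting statistics."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synarbor.cohstats import (
    PartnerProfile,
    assign_behaviors,
    complex_f_ratio,
    partner_coherence_correlation,
    permutation_p,
    proximity_weight,
    spatial_group_comparison,
    trials_ttest,
)


class TestComplexFRatio:
    def test_hand_worked_two_cluster_example(self):
        # clusters {1, i} and {−1, −i}: grand centroid 0; ss_total = 4;
        # within: |1−(1+i)/2|² ×2 + symmetric = 2
        result = complex_f_ratio([[1, 1j], [-1, -1j]])
        assert result.ss_total == pytest.approx(4.0)
        assert result.ss_within == pytest.approx(2.0)
        assert result.f == pytest.approx(2.0)
        assert not result.degenerate

    def test_single_cluster_gives_exactly_one(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=6) + 1j * rng.normal(size=6)
        result = complex_f_ratio([list(z)])
        assert result.f == 1.0

    def test_centroid_matched_clusters_give_one(self):
        # symmetric pairs {c+v, c−v} share centroid c for every cluster
        center = 0.2 + 0.1j
        clusters = [
            [center + v, center - v] for v in (0.3, 0.2j, 0.1 + 0.4j)
        ]
        result = complex_f_ratio(clusters)
        assert result.f == pytest.approx(1.0, abs=1e-9)

    def test_identical_values_flagged_degenerate_f_one(self):
        result = complex_f_ratio([[0.5 + 0.5j] * 3, [0.5 + 0.5j] * 2])
        assert result.degenerate and result.f == 1.0

    def test_zero_within_flagged_infinite(self):
        result = complex_f_ratio([[1.0, 1.0], [1j, 1j]])
        assert result.degenerate and math.isinf(result.f)

    def test_requires_a_multi_member_cluster(self):
        with pytest.raises(ValueError):
            complex_f_ratio([[1.0], [2.0]])
        with pytest.raises(ValueError):
            complex_f_ratio([])

    def test_sum_of_squares_decomposition_and_invariances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            sizes = rng.integers(1, 6, size=rng.integers(2, 5))
            if (sizes < 2).all():
                sizes[0] = 2
            clusters = [
                list(rng.normal(size=s) + 1j * rng.normal(size=s)) for s in sizes
            ]
            res = complex_f_ratio(clusters)
            # ss_between implied: decomposition holds
            between = sum(
                len(c) * abs(np.mean(c) - np.mean(np.concatenate(clusters))) ** 2
                for c in clusters
            )
            assert res.ss_within + between == pytest.approx(res.ss_total, rel=1e-9)
            assert res.f >= 1.0 - 1e-9
            # invariance under global rotation and translation
            phase = np.exp(1j * rng.uniform(0, 2 * np.pi))
            shift = complex(rng.normal(), rng.normal())
            moved = [[phase * z + shift for z in c] for c in clusters]
            assert complex_f_ratio(moved).f == pytest.approx(res.f, rel=1e-9)


class TestPermutationP:
    def test_p_hat_formula_bounds(self):
        z = {f"p{i}": complex(i, -i) for i in range(6)}
        clusters = [["p0", "p1", "p2"], ["p3", "p4", "p5"]]
        res = permutation_p(clusters, z, n_shuffles=250, seed=3)
        assert 1 / 251 <= res.p_hat <= 1.0
        assert res.p_hat == pytest.approx((res.m + 1) / 251)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        z = {f"p{i}": complex(*rng.normal(size=2)) for i in range(8)}
        clusters = [["p0", "p1", "p2"], ["p3", "p4"], ["p5", "p6", "p7"]]
        a = permutation_p(clusters, z, n_shuffles=100, seed=11)
        b = permutation_p(clusters, z, n_shuffles=100, seed=11)
        assert (a.m, a.p_hat) == (b.m, b.p_hat)
        c = permutation_p(clusters, z, n_shuffles=100, seed=12)
        assert (a.m,) != (c.m,) or a.f == c.f  # different seed may differ

    def test_strong_planted_grouping_is_significant(self):
        # three tight groups in the complex plane, clusters matching groups
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = {}
            clusters = []
            for g, center in enumerate([1.0, -0.5 + 0.8j, -0.5 - 0.8j]):
                members = []
                for i in range(5):
                    pid = f"g{g}_{i}"
                    z[pid] = center + complex(*rng.normal(scale=0.05, size=2))
                    members.append(pid)
                clusters.append(members)
            res = permutation_p(clusters, z, n_shuffles=400, seed=seed)
            if res.p_hat >= 0.05:
                failures += 1
        assert failures <= 1

    def test_missing_partner_value_raises(self):
        with pytest.raises(KeyError):
            permutation_p([["a", "b"]], {"a": 1 + 0j}, n_shuffles=10, seed=0)

    def test_null_p_values_roughly_uniform(self):
        # iid z values: p_hat should be uniform on its discrete grid
        n_rep, n_shuffles = 300, 79
        rng = np.random.default_rng(2)
        clusters = [[f"p{i}" for i in range(0, 4)], [f"p{i}" for i in range(4, 9)]]
        p_values = []
        for rep in range(n_rep):
            z = {f"p{i}": complex(*rng.normal(size=2)) for i in range(12)}
            res = permutation_p(clusters, z, n_shuffles=n_shuffles, seed=1000 + rep)
            p_values.append(res.p_hat)
        ks = stats.kstest(p_values, "uniform").statistic
        assert ks < 0.1


class TestProximityWeight:
    def test_closed_form_examples(self):
        assert proximity_weight([10.0, 40.0]) == pytest.approx(0.125, abs=1e-12)
        assert proximity_weight([100.0]) == pytest.approx(0.01, abs=1e-12)

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(1, 500, size=30)
        assert proximity_weight(d) == pytest.approx(float(np.sum(1.0 / d)), rel=1e-12)

    def test_zero_distance_demands_floor(self):
        with pytest.raises(ValueError, match="floor"):
            proximity_weight([10.0, 0.0])


class TestCorrelation:
    def _profiles(self, counts, mags, trial="t1"):
        return [
            PartnerProfile(
                partner_id=f"p{i}",
                synapse_count=int(c),
                proximity_weight=0.01 * c,
                z_by_trial={trial: m + 0j},
            )
            for i, (c, m) in enumerate(zip(counts, mags))
        ]

    def test_perfect_linearity(self):
        r, p = partner_coherence_correlation(
            self._profiles([2, 4, 6], [0.1, 0.2, 0.3]), "t1"
        )
        assert r == pytest.approx(1.0)

    def test_constant_magnitudes_error(self):
        with pytest.raises(ValueError, match="variance"):
            partner_coherence_correlation(
                self._profiles([2, 4, 6], [0.2, 0.2, 0.2]), "t1"
            )

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(21)
        counts = rng.integers(2, 30, size=15)
        mags = rng.uniform(0, 1, size=15)
        r, p = partner_coherence_correlation(self._profiles(counts, mags), "t1")
        x, y = counts.astype(float), mags
        rx = (x - x.mean()) / x.std()
        ry = (y - y.mean()) / y.std()
        expected = float(np.mean(rx * ry))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_inclusion_criteria(self):
        profiles = self._profiles([2, 4, 6, 8], [0.1, 0.3, 0.2, 0.4])
        profiles.append(
            PartnerProfile("solo", 1, 0.01, {"t1": 0.9 + 0j})  # single synapse
        )
        profiles.append(
            PartnerProfile("unseen", 5, 0.05, {"t1": 0.9 + 0j}, vsd_matched=False)
        )
        r_all, _ = partner_coherence_correlation(profiles, "t1")
        r_base, _ = partner_coherence_correlation(profiles[:4], "t1")
        assert r_all == pytest.approx(r_base)


class TestTrialsTTest:
    def test_all_zero_gives_t0_p1(self):
        assert trials_ttest([0.0, 0.0, 0.0]) == (0.0, 1.0)

    def test_antisymmetric_cancels(self):
        t, _ = trials_ttest([0.3, -0.3])
        assert t == pytest.approx(0.0)

    def test_closed_form(self):
        values = [0.1, 0.2, 0.3, 0.4]
        t, p = trials_ttest(values)
        arr = np.array(values)
        expected_t = arr.mean() / (arr.std(ddof=1) / 2.0)
        assert t == pytest.approx(expected_t, abs=1e-12)
        expected_p = 2 * stats.t.sf(abs(expected_t), df=3)
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_zero_sd_flags_infinite(self):
        t, p = trials_ttest([0.5, 0.5])
        assert math.isinf(t) and p == 0.0


class TestAssignBehaviors:
    def test_hand_worked_three_cell_example(self):
        mags = pd.DataFrame(
            [[0.9, 0.5, 0.1], [0.8, 0.7, 0.2], [0.3, 0.4, 0.6]],
            index=["c1", "c2", "c3"],
            columns=["S", "C", "L"],
        )
        result = assign_behaviors(mags)
        assert result.assignment == {"c1": "S", "c2": "C", "c3": "L"}
        assert [entry[0] for entry in result.order_log] == ["c1", "c2", "c3"]

    def test_single_cell_argmax(self):
        mags = pd.DataFrame([[0.2, 0.7, 0.4]], index=["c"], columns=["S", "C", "L"])
        assert assign_behaviors(mags).assignment == {"c": "C"}

    def test_counts_balanced_within_one(self):
        rng = np.random.default_rng(31)
        for n in (4, 7, 11):
            mags = pd.DataFrame(
                rng.uniform(size=(n, 3)),
                index=[f"c{i}" for i in range(n)],
                columns=["S", "C", "L"],
            )
            counts = pd.Series(assign_behaviors(mags).assignment).value_counts()
            assert counts.max() - counts.min() <= 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(33)
        mags = pd.DataFrame(
            rng.uniform(size=(6, 3)),
            index=[f"c{i}" for i in range(6)],
            columns=["S", "C", "L"],
        )
        base = assign_behaviors(mags).assignment
        shuffled = mags.sample(frac=1, random_state=1)
        permuted = assign_behaviors(shuffled).assignment
        assert permuted == base

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            assign_behaviors(pd.DataFrame())


class TestSpatialGroupComparison:
    def test_identical_distributions(self):
        d = list(np.linspace(10, 200, 25))
        result = spatial_group_comparison(
            {"excitatory": d, "unknown": list(d)}, n_permutations=200, seed=0
        )
        stat, p = result["excitatory"]
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports_significant(self):
        rng = np.random.default_rng(3)
        near = list(rng.normal(10, 0.5, size=20))
        far = list(rng.normal(200, 0.5, size=20))
        result = spatial_group_comparison(
            {"inhibitory": near, "unknown": far}, n_permutations=2000, seed=1
        )
        stat, p = result["inhibitory"]
        assert stat == 1.0 and p < 0.01

    def test_shuffled_labels_give_unremarkable_p(self):
        rng = np.random.default_rng(9)
        pooled = rng.normal(100, 30, size=40)
        p_values = []
        for seed in range(30):
            rng_s = np.random.default_rng(seed)
            perm = rng_s.permutation(pooled)
            result = spatial_group_comparison(
                {"a": list(perm[:20]), "unknown": list(perm[20:])},
                n_permutations=200,
                seed=seed,
            )
            p_values.append(result["a"][1])
        assert 0.2 < np.mean(p_values) < 0.8
        assert min(p_values) > 1 / 201 - 1e-12

    def test_small_group_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            result = spatial_group_comparison(
                {"tiny": [5.0], "unknown": [1.0, 2.0, 3.0]}, n_permutations=50
            )
        assert "tiny" not in result
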