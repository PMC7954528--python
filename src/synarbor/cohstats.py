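"""Statistics linking synapse anatomy to presynaptic functional activity.

The centrepiece is an ANOVA-like F-ratio on *complex* spectral coherence
values.  If ``z_ki`` is the coherence of presynaptic cell ``i`` in spatial
cluster ``k``, with cluster centroids ``z_k0`` and grand centroid ``z_0``, then

    F = Σ_ki |z_ki − z_0|² / Σ_ki |z_ki − z_k0|²

is the ratio of total to within-cluster sums of absolute squared deviations.
F > 1 indicates that coherence values within a spatial cluster are more
similar to each other than across clusters.  Because the complex-valued
statistic does not follow an F distribution under the null hypothesis, the
p-value is estimated by permutation: the per-neuron coherence values are
shuffled across partners while the cluster composition is kept fixed, and
p̂ = (m + 1) / (N + 1) where m of N shuffles reach an F at least as large as
the observed one.

The module also provides the proximity weight (sum of inverse synapse-to-soma
path distances per partner), synapse-count/coherence correlations with an
across-trial t-test, the cyclic greedy assignment of cells to behaviors, and a
permutation comparison of spatial synapse distributions between valence
groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PartnerProfile",
    "FRatioResult",
    "BehaviorAssignment",
    "complex_f_ratio",
    "permutation_p",
    "proximity_weight",
    "partner_coherence_correlation",
    "trials_ttest",
    "assign_behaviors",
    "spatial_group_comparison",
]


@dataclass(frozen=True)
class PartnerProfile:
    """Anatomical and functional summary of one presynaptic partner."""

    partner_id: str
    synapse_count: int
    proximity_weight: float  # 1/µm
    z_by_trial: Mapping[str, complex] = field(default_factory=dict)
    vsd_matched: bool = True


@dataclass(frozen=True)
class FRatioResult:
    """Complex-coherence F-ratio with optional permutation p-value.

    ``f`` ≥ 1 up to floating error because ``ss_total = ss_within +
    ss_between``.  ``degenerate`` marks the two pathological cases: all values
    identical (``ss_total = 0``, F defined as 1) and perfect within-cluster
    agreement (``ss_within = 0`` with ``ss_total > 0``, F = +inf).
    """

    f: float
    ss_total: float
    ss_within: float
    degenerate: bool = False
    p_hat: float | None = None
    m: int | None = None
    n_shuffles: int | None = None
    seed: int | None = None

    @property
    def ss_between(self) -> float:
        return self.ss_total - self.ss_within

    def to_dict(self) -> dict:
        return {
            "f": self.f,
            "ss_total": self.ss_total,
            "ss_within": self.ss_within,
            "p_hat": self.p_hat,
            "m": self.m,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def _f_from_values(values: Sequence[np.ndarray]) -> tuple[float, float, float, bool]:
    """F, ss_total, ss_within, degenerate for one list of per-cluster arrays."""
    all_z = np.concatenate(values)
    grand = all_z.mean()
    ss_total = float(np.sum(np.abs(all_z - grand) ** 2))
    ss_within = 0.0
    for cluster in values:
        ss_within += float(np.sum(np.abs(cluster - cluster.mean()) ** 2))
    if ss_total == 0.0:
        return 1.0, ss_total, ss_within, True
    # a relative threshold also catches all-identical clusters whose within
    # sum is pure floating-point residue
    if ss_within <= 1e-12 * ss_total:
        return math.inf, ss_total, ss_within, True
    return ss_total / ss_within, ss_total, ss_within, False


def complex_f_ratio(cluster_partner_values: Sequence[Sequence[complex]]) -> FRatioResult:
    """F-ratio of total to within-cluster sums of absolute squared deviations.

    Parameters
    ----------
    cluster_partner_values : sequence of sequences of complex
        One inner sequence per spatial cluster, holding the coherence value of
        each *distinct* presynaptic partner with synapses in that cluster.
        At least one cluster must have two or more members.
    """
    if len(cluster_partner_values) == 0:
        raise ValueError("need at least one cluster")
    arrays = [np.asarray(list(c), dtype=complex) for c in cluster_partner_values]
    if any(a.size == 0 for a in arrays):
        raise ValueError("clusters must be nonempty")
    if all(a.size < 2 for a in arrays):
        raise ValueError("need at least one cluster with two or more members")
    f, ss_total, ss_within, degenerate = _f_from_values(arrays)
    return FRatioResult(f=f, ss_total=ss_total, ss_within=ss_within, degenerate=degenerate)


def permutation_p(
    clusters: Sequence[Sequence[str]],
    z_values: Mapping[str, complex],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> FRatioResult:
    """Empirical p-value of the F-ratio under partner-label shuffling.

    ``clusters`` lists, per spatial cluster, the distinct partner ids with
    synapses in that cluster; ``z_values`` maps every matched partner (cluster
    member or not) to its complex coherence.  Each shuffle permutes the
    partner→z assignment over all matched partners while the cluster
    composition stays fixed; p̂ = (m + 1)/(N + 1) with m the number of shuffles
    whose F meets or exceeds the observed F.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    partner_pool = sorted(z_values)
    missing = {p for cluster in clusters for p in cluster} - set(partner_pool)
    if missing:
        raise KeyError(f"cluster partners without coherence values: {sorted(missing)}")

    observed = complex_f_ratio(
        [[z_values[p] for p in cluster] for cluster in clusters]
    )

    pool_index = {p: i for i, p in enumerate(partner_pool)}
    z_pool = np.array([z_values[p] for p in partner_pool], dtype=complex)
    mem_idx = np.array(
        [pool_index[p] for cluster in clusters for p in cluster], dtype=int
    )
    sizes = np.array([len(c) for c in clusters], dtype=int)
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    rng = np.random.default_rng(seed)
    # all shuffles at once: row s of `perms` is a permutation of the pool
    perms = np.argsort(rng.random((n_shuffles, len(z_pool))), axis=1)
    z = z_pool[perms[:, mem_idx]]
    grand = z.mean(axis=1, keepdims=True)
    ss_total = np.sum(np.abs(z - grand) ** 2, axis=1)
    centroids = np.add.reduceat(z, bounds, axis=1) / sizes
    ss_within = np.sum(np.abs(z - np.repeat(centroids, sizes, axis=1)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_null = np.where(
            ss_total == 0.0,
            1.0,
            np.where(ss_within <= 1e-12 * ss_total, math.inf, ss_total / ss_within),
        )
    m = int(np.sum(f_null >= observed.f))
    p_hat = (m + 1) / (n_shuffles + 1)
    return FRatioResult(
        f=observed.f,
        ss_total=observed.ss_total,
        ss_within=observed.ss_within,
        degenerate=observed.degenerate,
        p_hat=p_hat,
        m=m,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def proximity_weight(soma_distances: Sequence[float]) -> float:
    """Sum of inverse synapse-to-soma path distances, in 1/µm.

    A synapse sitting exactly on the soma would contribute an infinite weight;
    such inputs are rejected and callers must apply a minimum-distance floor.
    """
    d = np.asarray(list(soma_distances), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one synapse distance")
    if np.any(d <= 0):
        raise ValueError(
            "synapse-to-soma distance of 0 µm; apply a minimum-distance floor "
            "before computing proximity weights"
        )
    return float(np.sum(1.0 / d))


def partner_coherence_correlation(
    profiles: Sequence[PartnerProfile],
    trial: str,
    measure: str = "synapse_count",
) -> tuple[float, float]:
    """Pearson correlation between an anatomical measure and coherence magnitude.

    Includes only VSD-matched partners with at least two synapses, mirroring
    the inclusion criteria used for anatomy/function comparisons.  Returns
    Pearson r and its two-sided p-value.
    """
    if measure not in ("synapse_count", "proximity_weight"):
        raise ValueError(f"unknown measure {measure!r}")
    xs, ys = [], []
    for prof in profiles:
        if not prof.vsd_matched or prof.synapse_count < 2:
            continue
        if trial not in prof.z_by_trial:
            continue
        xs.append(getattr(prof, measure))
        ys.append(abs(prof.z_by_trial[trial]))
    if len(xs) < 3:
        raise ValueError(f"need at least 3 included partners, got {len(xs)}")
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in one of the variables; correlation undefined")
    result = stats.pearsonr(xs, ys)
    return float(result.statistic), float(result.pvalue)


def trials_ttest(r_values: Sequence[float]) -> tuple[float, float]:
    """One-sample two-sided t-test of correlation coefficients against zero.

    Returns (t, p) with n−1 degrees of freedom; a zero standard deviation
    yields t = ±inf (p = 0) unless the mean is also zero (t = 0, p = 1).
    """
    r = np.asarray(list(r_values), dtype=float)
    if r.size < 2:
        raise ValueError("need at least two values")
    sd = r.std(ddof=1)
    if sd == 0.0:
        if r.mean() == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, r.mean()), 0.0
    res = stats.ttest_1samp(r, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class BehaviorAssignment:
    """Result of the cyclic greedy cell→behavior assignment."""

    assignment: Mapping[str, str]
    order_log: tuple[tuple[str, str, float], ...]  # (cell, behavior, magnitude)


def assign_behaviors(magnitudes: pd.DataFrame) -> BehaviorAssignment:
    """Assign each cell to one behavior by cyclic greedy coherence ranking.

    ``magnitudes`` is a cells × behaviors table of coherence magnitudes.  The
    procedure repeatedly picks the unassigned cell with the greatest magnitude
    in any behavior not yet used in the current cycle and assigns it to that
    behavior; once every behavior has been used, a new cycle starts.  This
    balances the per-behavior counts (they differ by at most one) while
    compensating for behavior-specific offsets in absolute coherence.
    """
    if magnitudes.size == 0:
        raise ValueError("empty magnitude matrix")
    remaining_cells = list(magnitudes.index)
    behaviors = list(magnitudes.columns)
    assignment: dict[str, str] = {}
    log: list[tuple[str, str, float]] = []
    open_behaviors: list[str] = []
    while remaining_cells:
        if not open_behaviors:
            open_behaviors = list(behaviors)
        sub = magnitudes.loc[remaining_cells, open_behaviors]
        flat = int(np.argmax(sub.to_numpy()))
        row, col = divmod(flat, len(open_behaviors))
        cell, behavior = remaining_cells[row], open_behaviors[col]
        assignment[cell] = behavior
        log.append((cell, behavior, float(sub.iat[row, col])))
        remaining_cells.remove(cell)
        open_behaviors.remove(behavior)
    return BehaviorAssignment(assignment=assignment, order_log=tuple(log))


def spatial_group_comparison(
    distance_groups: Mapping[str, Sequence[float]],
    reference_group: str = "unknown",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Compare each labeled group's spatial distribution to the reference group.

    For each group other than ``reference_group``, computes the two-sample
    Kolmogorov–Smirnov statistic against the reference distances and a
    permutation p-value from ``n_permutations`` label shuffles:
    p = (m + 1)/(N + 1) with m the number of shuffled statistics at or above
    the observed one.  Groups with fewer than two samples are skipped with a
    warning.
    """
    if reference_group not in distance_groups:
        raise ValueError(f"reference group {reference_group!r} missing")
    if len(distance_groups) < 2:
        raise ValueError("need at least two groups")
    reference = np.asarray(list(distance_groups[reference_group]), dtype=float)
    rng = np.random.default_rng(seed)
    results: dict[str, tuple[float, float]] = {}
    for group, values in distance_groups.items():
        if group == reference_group:
            continue
        sample = np.asarray(list(values), dtype=float)
        if sample.size < 2 or reference.size < 2:
            warnings.warn(f"group {group!r} skipped: fewer than 2 samples")
            continue
        observed = _ks_statistic(sample, reference)
        pooled = np.concatenate([sample, reference])
        n1 = sample.size
        m = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _ks_statistic(perm[:n1], perm[n1:]) >= observed:
                m += 1
        results[group] = (observed, (m + 1) / (n_permutations + 1))
    return results


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic sup |ECDF_x − ECDF_y|."""
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))
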