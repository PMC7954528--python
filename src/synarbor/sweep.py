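"""Parameter sweeps over the clustering constraints and peak localization.

The clustering constraints ``(d_nn, d_ext)`` are swept over a grid; at every
grid cell the synapses are clustered, clusters uninformative for the F-ratio
are removed, and the complex-coherence F-ratio with its permutation p-value is
evaluated.  The best-corresponding spatial scale is then localized by taking
the ``d_nn`` row containing the grid's largest F-ratio and fitting

    F(d_ext) = 1 + A · exp(−½ (d_ext − µ)² / σ²)

along that row by nonlinear least squares; µ estimates the cluster extent at
which spatial and functional grouping correspond best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from synarbor.clustering import (
    ClusterParams,
    PathDistanceMatrix,
    cluster_synapses,
    filter_for_fratio,
    pairwise_distances,
)
from synarbor.cohstats import complex_f_ratio, permutation_p
from synarbor.morpho import Skeleton, SynapseTable

__all__ = [
    "ParameterGrid",
    "FRatioGrid",
    "GaussianFit",
    "run_sweep",
    "best_dnn_profile",
    "fit_peak",
    "significant_pairs",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered grids of d_nn and d_ext values (µm) to sweep."""

    d_nn_values: tuple[float, ...]
    d_ext_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, values in (
            ("d_nn_values", self.d_nn_values),
            ("d_ext_values", self.d_ext_values),
        ):
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{name} must be nonempty")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def default(cls) -> "ParameterGrid":
        """d_nn from 5 to 25 µm in 2.5 µm steps; d_ext from 10 to 100 µm in 5 µm steps."""
        return cls(
            d_nn_values=tuple(np.arange(5.0, 25.0 + 1e-9, 2.5)),
            d_ext_values=tuple(np.arange(10.0, 100.0 + 1e-9, 5.0)),
        )


@dataclass(frozen=True)
class FRatioGrid:
    """F-ratio, p̂ and cluster counts over the (d_nn, d_ext) grid for one trial."""

    trial_id: str
    d_nn_values: tuple[float, ...]
    d_ext_values: tuple[float, ...]
    f: np.ndarray  # shape (n_dnn, n_dext)
    p_hat: np.ndarray
    n_clusters: np.ndarray
    degenerate: np.ndarray  # bool; cell had no usable clusters or an undefined F

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, d_nn in enumerate(self.d_nn_values):
            for j, d_ext in enumerate(self.d_ext_values):
                rows.append(
                    {
                        "trial_id": self.trial_id,
                        "d_nn": d_nn,
                        "d_ext": d_ext,
                        "f": self.f[i, j],
                        "p_hat": self.p_hat[i, j],
                        "n_clusters": int(self.n_clusters[i, j]),
                        "degenerate": bool(self.degenerate[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian peak fit of F against d_ext."""

    a: float
    mu: float  # µm
    sigma: float  # µm
    se_mu: float  # µm, from the parameter covariance at the optimum
    converged: bool
    message: str = ""


def cell_seed(master_seed: int, i_nn: int, j_ext: int) -> int:
    """Reproducible sub-seed for one grid cell's permutation test."""
    seq = np.random.SeedSequence(entropy=master_seed, spawn_key=(i_nn, j_ext))
    return int(seq.generate_state(1)[0] % (2**31))


def run_sweep(
    skeleton: Skeleton | None,
    table: SynapseTable,
    z_values: Mapping[str, complex],
    grid: ParameterGrid,
    n_shuffles: int = 1000,
    seed: int = 0,
    trial_id: str = "",
    distances: PathDistanceMatrix | None = None,
) -> FRatioGrid:
    """Evaluate clustering + F-ratio + permutation p̂ at every grid cell.

    The synapse distance matrix is computed once (or supplied precomputed).
    Only partners with a coherence value can contribute to the F-ratio;
    clusters left with fewer than two such partners are dropped.  A cell where
    no usable cluster remains, or where the F-ratio is undefined, is flagged
    degenerate rather than raising.  Cells are statistically independent: each
    gets a sub-seed derived from (seed, row, column), so any evaluation order
    produces the same grid.
    """
    if distances is None:
        if skeleton is None:
            raise ValueError("provide either a skeleton or a precomputed distance matrix")
        distances = pairwise_distances(skeleton, table)

    n_i, n_j = len(grid.d_nn_values), len(grid.d_ext_values)
    f = np.full((n_i, n_j), np.nan)
    p_hat = np.full((n_i, n_j), np.nan)
    n_clusters = np.zeros((n_i, n_j), dtype=int)
    degenerate = np.ones((n_i, n_j), dtype=bool)

    for i, d_nn in enumerate(grid.d_nn_values):
        for j, d_ext in enumerate(grid.d_ext_values):
            params = ClusterParams(d_nn=d_nn, d_ext=d_ext)
            clusters = cluster_synapses(distances, params, table=table)
            usable = filter_for_fratio(clusters, table)
            partner_lists = []
            for cluster in usable:
                with_z = sorted(p for p in cluster.member_partners if p in z_values)
                if len(with_z) >= 2:
                    partner_lists.append(with_z)
            n_clusters[i, j] = len(partner_lists)
            if not partner_lists:
                continue
            result = permutation_p(
                partner_lists,
                z_values,
                n_shuffles=n_shuffles,
                seed=cell_seed(seed, i, j),
            )
            f[i, j] = result.f
            p_hat[i, j] = result.p_hat
            degenerate[i, j] = result.degenerate
    return FRatioGrid(
        trial_id=trial_id,
        d_nn_values=tuple(grid.d_nn_values),
        d_ext_values=tuple(grid.d_ext_values),
        f=f,
        p_hat=p_hat,
        n_clusters=n_clusters,
        degenerate=degenerate,
    )


def best_dnn_profile(grid: FRatioGrid) -> tuple[float, pd.DataFrame]:
    """The d_nn row containing the grid's largest F-ratio, as F versus d_ext.

    Degenerate cells are excluded from the scan; ties across rows resolve to
    the smallest d_nn.  Returns ``(d_nn_star, profile)`` where ``profile`` has
    columns ``d_ext`` and ``f`` for that row's non-degenerate cells.
    """
    valid = ~grid.degenerate & np.isfinite(grid.f)
    if not valid.any():
        raise ValueError("all grid cells are degenerate")
    masked = np.where(valid, grid.f, -np.inf)
    best_value = masked.max()
    best_rows = np.nonzero((masked == best_value).any(axis=1))[0]
    i_star = int(best_rows[0])  # rows ordered by increasing d_nn
    row_valid = valid[i_star]
    profile = pd.DataFrame(
        {
            "d_ext": np.asarray(grid.d_ext_values)[row_valid],
            "f": grid.f[i_star, row_valid],
        }
    )
    return float(grid.d_nn_values[i_star]), profile


def _gauss_model(d: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return 1.0 + a * np.exp(-0.5 * (d - mu) ** 2 / sigma**2)


def fit_peak(profile: pd.DataFrame, min_amplitude: float = 1e-6) -> GaussianFit:
    """Fit F = 1 + A·exp(−½(d_ext−µ)²/σ²) to a best-d_nn profile.

    Initialization: A = max(F)−1, µ at the profile's argmax, σ = span/4.  The
    standard error of µ comes from the parameter covariance at the optimum.  A
    fit with vanishing amplitude (flat profile) is reported with
    ``converged=False`` because µ is not identifiable.
    """
    d = profile["d_ext"].to_numpy(dtype=float)
    f = profile["f"].to_numpy(dtype=float)
    if d.size < 4:
        return GaussianFit(
            a=math.nan, mu=math.nan, sigma=math.nan, se_mu=math.nan,
            converged=False, message=f"only {d.size} points; need at least 4",
        )
    span = d.max() - d.min()
    a0 = max(f.max() - 1.0, min_amplitude)
    mu0 = float(d[int(np.argmax(f))])
    sigma0 = max(span / 4.0, 1e-6)
    try:
        popt, pcov = curve_fit(
            _gauss_model,
            d,
            f,
            p0=[a0, mu0, sigma0],
            bounds=([0.0, d.min() - span, 1e-9], [np.inf, d.max() + span, np.inf]),
            maxfev=20_000,
        )
    except (RuntimeError, ValueError) as exc:
        return GaussianFit(
            a=math.nan, mu=math.nan, sigma=math.nan, se_mu=math.nan,
            converged=False, message=f"least squares failed: {exc}",
        )
    a, mu, sigma = (float(v) for v in popt)
    se_mu = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.inf
    if a <= min_amplitude:
        return GaussianFit(
            a=a, mu=mu, sigma=sigma, se_mu=se_mu, converged=False,
            message="amplitude ≈ 0: flat profile, peak location not identifiable",
        )
    if not np.isfinite(se_mu):
        return GaussianFit(
            a=a, mu=mu, sigma=sigma, se_mu=se_mu, converged=False,
            message="singular covariance: peak location not identifiable",
        )
    return GaussianFit(a=a, mu=mu, sigma=sigma, se_mu=se_mu, converged=True)


def significant_pairs(
    grid: FRatioGrid, alpha: float = 0.05, top_k: int = 10
) -> pd.DataFrame:
    """Grid cells with p̂ < alpha, most significant first, truncated to top_k.

    Sorted by ascending p̂ then descending F; mirrors the per-trial table of
    parameter values with a significant anatomy–activity link.
    """
    frame = grid.to_long_frame()
    hits = frame[(~frame["degenerate"]) & (frame["p_hat"] < alpha)]
    hits = hits.sort_values(["p_hat", "f"], ascending=[True, False], kind="mergesort")
    return hits.head(top_k).reset_index(drop=True)
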