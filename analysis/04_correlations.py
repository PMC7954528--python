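"""Partner-level anatomy/function correlations and supporting statistics.

From the aligned synthetic dataset: builds per-partner profiles (synapse
count, proximity weight, per-trial coherence), correlates each anatomical
measure with coherence magnitude across simulated trials, tests the mean
correlation against zero, compares the spatial distributions of valence
groups, and assigns cells to behaviors by the cyclic greedy procedure.

Writes results/correlations/{correlations.csv, spatial_comparison.csv,
behavior_assignment.csv}.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from synarbor import io as sio
from synarbor import morpho
from synarbor.cohstats import (
    PartnerProfile,
    assign_behaviors,
    partner_coherence_correlation,
    proximity_weight,
    spatial_group_comparison,
    trials_ttest,
)
from synarbor.synth import SynthConfig, synth_coherence, synth_synapses, synth_skeleton

ROOT = Path(__file__).resolve().parents[1]
N_TRIALS = 8  # trials per behavior-like replicate, as in a full imaging session


def build_profiles(skeleton, table, z_by_trial):
    by_partner = table.by_partner()
    profiles = []
    for partner, records in sorted(by_partner.items()):
        distances = [morpho.distance_to_soma(skeleton, r) for r in records]
        distances = [max(d, 1.0) for d in distances]  # 1 µm floor at the soma
        profiles.append(
            PartnerProfile(
                partner_id=partner,
                synapse_count=len(records),
                proximity_weight=proximity_weight(distances),
                z_by_trial={t: z[partner] for t, z in z_by_trial.items()},
            )
        )
    return profiles


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=Path,
                        default=ROOT / "scratch" / "synthetic" / "aligned")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "correlations")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    skeleton = morpho.read_swc(args.data / "skeleton.swc")
    table = morpho.SynapseTable.read_csv(args.data / "synapses.csv")

    # fresh coherence draws per trial from the same functional ground truth
    config = SynthConfig(seed=args.seed, placement_mode="clustered",
                         signal_coupling="aligned", n_synapses=400)
    _, truth = synth_synapses(synth_skeleton(config), config)
    trial_ids = [f"trial{k:02d}" for k in range(N_TRIALS)]
    z_by_trial = {}
    for k, trial_id in enumerate(trial_ids):
        trial_config = SynthConfig(**{**config.__dict__, "seed": args.seed + 100 + k})
        z_by_trial[trial_id] = synth_coherence(trial_config, truth, ["swim"])["swim"]

    profiles = build_profiles(skeleton, table, z_by_trial)

    rows = []
    for measure in ("synapse_count", "proximity_weight"):
        r_values = []
        for trial_id in trial_ids:
            r, p = partner_coherence_correlation(profiles, trial_id, measure)
            r_values.append(r)
            rows.append({"measure": measure, "trial_id": trial_id, "r": r, "p": p})
        t, p = trials_ttest(r_values)
        rows.append({"measure": measure, "trial_id": "ALL(t-test)",
                     "r": float(np.mean(r_values)), "p": p})
        print(
            f"{measure}: mean r = {np.mean(r_values):+.3f} ± "
            f"{np.std(r_values, ddof=1):.3f} over {len(r_values)} trials, "
            f"t = {t:.2f}, p = {p:.3g}"
        )
    pd.DataFrame(rows).to_csv(args.out / "correlations.csv", index=False)

    # spatial comparison of valence groups (synthetic valences are a random
    # 20/20/60 split, so no difference is expected)
    rng = np.random.default_rng(args.seed)
    valences = rng.choice(
        ["excitatory", "inhibitory", "unknown"], p=[0.2, 0.2, 0.6],
        size=len(table),
    )
    groups: dict[str, list[float]] = {}
    for rec, valence in zip(table, valences):
        groups.setdefault(valence, []).append(
            max(morpho.distance_to_soma(skeleton, rec), 1.0)
        )
    comparison = spatial_group_comparison(groups, n_permutations=2000, seed=args.seed)
    comp_rows = [
        {"group": g, "ks_statistic": stat, "p_perm": p}
        for g, (stat, p) in comparison.items()
    ]
    pd.DataFrame(comp_rows).to_csv(args.out / "spatial_comparison.csv", index=False)
    for row in comp_rows:
        print(
            f"spatial {row['group']} vs unknown: KS = {row['ks_statistic']:.3f}, "
            f"permutation p = {row['p_perm']:.3f}"
        )

    # behavior assignment from per-behavior coherence magnitudes
    behaviors = ("swim", "crawl", "local_bend")
    mags = pd.DataFrame(
        {
            b: [abs(synth_coherence(
                SynthConfig(**{**config.__dict__, "seed": args.seed + 200 + i}),
                truth, ["swim"])["swim"][p.partner_id]) for p in profiles]
            for i, b in enumerate(behaviors)
        },
        index=[p.partner_id for p in profiles],
    )
    assignment = assign_behaviors(mags)
    pd.Series(assignment.assignment, name="behavior").rename_axis("cell_id").to_csv(
        args.out / "behavior_assignment.csv"
    )
    counts = pd.Series(assignment.assignment).value_counts()
    print("behavior assignment counts:", dict(counts))
    sio.write_manifest(args.out, "correlations",
                       inputs={"synapses": args.data / "synapses.csv"},
                       seed=args.seed)


if __name__ == "__main__":
    main()
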