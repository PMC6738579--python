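#!/usr/bin/env python
"""Genotype-level statistics: which mutants shift the trade-off, and which
feature clusters a genotype most tightly.

Runs KS tests (Bonferroni-corrected for the number of mutants) of every
mutant's trade-off distribution against wildtype — both on the full
architectures and with the rosette excluded (inflorescence only) — and
computes the coefficient-of-variation matrix across genotypes and features.
Writes results/genotype_stats/*.csv.
"""

from pathlib import Path

import pandas as pd

import shootpareto as sp

FEATURES_CSV = Path("results/front_analysis/features.csv")
COHORT = Path("results/cohort")
OUT = Path("results/genotype_stats")
COV_FEATURES = [
    "tradeoff",
    "total_length",
    "travel_distance",
    "n_rosette",
    "n_branch_points",
    "hull_volume",
]


def tradeoffs_by_genotype(exclude_rosette: bool) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    exclude = {"rosette_leaf"} if exclude_rosette else ()
    for gdir in sorted(COHORT.iterdir()):
        if not gdir.is_dir() or gdir.name == "growth_wildtype":
            continue
        out[gdir.name] = [
            sp.quick_tradeoff(sp.load_skeleton(f), exclude_labels=exclude)
            for f in sorted(gdir.glob("*_rep*.json"))
        ]
    return out


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(FEATURES_CSV)

    # CoV matrix: the trade-off should be the tightest column per genotype
    ensembles = []
    for name, sub in df.groupby("genotype"):
        recs = [
            sp.FeatureRecord(**{k: row[k] for k in sp.stats.FEATURE_COLUMNS})
            for _, row in sub.iterrows()
        ]
        ensembles.append(sp.GenotypeEnsemble(genotype=name, records=recs))
    cov = sp.cov_comparison(ensembles, features=COV_FEATURES)
    cov.round(3).to_csv(OUT / "cov_matrix.csv")
    print("coefficient of variation (rows: genotype):")
    print(cov.round(3).to_string())
    n_tightest = int((cov["tradeoff"] == cov.min(axis=1)).sum())
    print(f"\ntrade-off is the tightest feature in {n_tightest}/{len(cov)} genotypes")

    for tag, exclude in (("full", False), ("no_rosette", True)):
        groups = tradeoffs_by_genotype(exclude)
        wt = groups.pop("wildtype")
        n_comp = len(groups)
        rows = []
        for name, vals in groups.items():
            r = sp.ks_vs_wildtype(wt, vals, n_comparisons=n_comp, feature="tradeoff")
            rows.append({"genotype": name, **r.as_dict()})
        res = pd.DataFrame(rows)
        res.to_csv(OUT / f"ks_{tag}.csv", index=False)
        print(f"\nKS vs wildtype on the trade-off ({tag}):")
        print(
            res[["genotype", "statistic", "p_value", "significant"]]
            .round(4)
            .to_string(index=False)
        )


if __name__ == "__main__":
    main()
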