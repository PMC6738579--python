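#!/usr/bin/env python
"""Simulate the study cohort: a wildtype-like genotype plus mutants whose
prioritization weight alpha* is shifted one way or the other.

Writes skeleton JSON files and per-genotype manifests under
results/cohort/<genotype>/, plus a growth-series set for the development
analysis.  Downstream scripts (02-05) consume these files.
"""

from pathlib import Path

import shootpareto as sp

OUT = Path("results/cohort")
SEED = 20_250_901
N_REPLICATES = 8

# alpha* values span the range the genotype panel occupies: length-
# prioritizing (low alpha) through travel-prioritizing (higher alpha)
GENOTYPES = [
    sp.GenotypeParams(name="wildtype", alpha_star=0.143),
    sp.GenotypeParams(name="mut_low_alpha", alpha_star=0.05, n_rosette=21, n_flowers=16),
    sp.GenotypeParams(name="mut_high_alpha", alpha_star=0.25, n_rosette=12, n_flowers=10),
    sp.GenotypeParams(name="mut_leafy", alpha_star=0.10, n_rosette=38, n_flowers=18),
]


def main() -> None:
    import numpy as np

    ss = np.random.SeedSequence(SEED)
    for params, child in zip(GENOTYPES, ss.spawn(len(GENOTYPES) + 1)):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        _, plants = sp.generate_genotype_ensemble(
            params, N_REPLICATES, child_seed, out_dir=OUT / params.name, analyze=False
        )
        sizes = sorted(len(p.terminal_ids()) for p in plants)
        print(
            f"{params.name}: {len(plants)} replicates, terminal counts "
            f"{sizes[0]}-{sizes[-1]} (alpha* = {params.alpha_star})"
        )
    # one wildtype individual followed through four time points
    growth_seed = int(ss.spawn(len(GENOTYPES) + 1)[-1].generate_state(1)[0] % 2**31)
    series = sp.generate_growth_series(GENOTYPES[0], 4, growth_seed)
    gdir = OUT / "growth_wildtype"
    gdir.mkdir(parents=True, exist_ok=True)
    for t, skel in enumerate(series):
        sp.save_skeleton(skel, gdir / f"wildtype_t{t}.json")
    print(
        f"growth series: 4 time points, "
        f"{len(series[0].terminal_ids())} -> {len(series[-1].terminal_ids())} terminals"
    )


if __name__ == "__main__":
    main()
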