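#!/usr/bin/env python
"""Plant versus baseline architectures on the same input points.

For each wildtype scan, compares the plant's front distance against the
Stable tree and against 200 preferential-attachment and 200 uniform-random
spanning trees (mean epsilon per scan), then tests the plant's advantage
with the one-sided binomial front test.  Writes
results/baselines/epsilons.csv and binomial_tests.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import shootpareto as sp

COHORT = Path("results/cohort")
OUT = Path("results/baselines")
N_DRAWS = 200
SEED = 31


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    files = sorted((COHORT / "wildtype").glob("*_rep*.json"))
    ss = np.random.SeedSequence(SEED)
    rows = []
    for f, child in zip(files, ss.spawn(len(files))):
        seeds = child.generate_state(2 * N_DRAWS) % 2**31
        res = sp.analyze_plant(sp.load_skeleton(f))
        ts = sp.extract_terminals(sp.load_skeleton(f))

        def eps(tree):
            return sp.epsilon_distance(
                res.front,
                sp.ObjectivePair(tree.total_length(), tree.travel_distance()),
            )

        rows.append(
            {
                "file": f.name,
                "plant": res.features.epsilon,
                "stable": eps(sp.stable_tree(ts)),
                "pref_attach": float(
                    np.mean(
                        [eps(sp.pref_attach_tree(ts, int(s))) for s in seeds[:N_DRAWS]]
                    )
                ),
                "random": float(
                    np.mean(
                        [
                            eps(sp.random_spanning_tree(ts, int(s)))
                            for s in seeds[N_DRAWS:]
                        ]
                    )
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "epsilons.csv", index=False)
    print("mean epsilon by architecture:")
    print(df[["plant", "stable", "pref_attach", "random"]].mean().round(3).to_string())
    tests = []
    for base in ("stable", "pref_attach", "random"):
        r = sp.binomial_front_test(df["plant"], df[base], feature=base)
        tests.append(r.as_dict())
        print(
            f"plant vs {base}: baseline closer in {int(r.statistic)}/{len(df)} "
            f"scans, one-sided p = {r.p_value:.2e}"
        )
    pd.DataFrame(tests).to_csv(OUT / "binomial_tests.csv", index=False)


if __name__ == "__main__":
    main()
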