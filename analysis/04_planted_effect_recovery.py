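#!/usr/bin/env python
"""Power check: recovery of a planted group difference in synchrony.

Ten seeded cohorts each carry one spherical region (radius 2.5 voxels)
whose shared-signal weight is 0.8 in group1 vs 0.2 in group2; everything
else matches the null-calibration conditions.  The pipeline should report
a significant cluster of the correct sign overlapping the sphere
(Dice > 0.3) in at least 9 of 10 cohorts.
"""

from pathlib import Path

import pandas as pd

from rehopipe.experiments import planted_effect_recovery

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    res = planted_effect_recovery(n_seeds=10, w_group1=0.8, w_group2=0.2,
                                  n_iterations=1000, seed=1)
    RESULTS.mkdir(exist_ok=True)
    table = pd.DataFrame(
        {
            "seed_index": range(res.n_seeds),
            "best_dice": res.dice,
            "cluster_size": res.cluster_sizes,
            "recovered": [d > 0.3 for d in res.dice],
        }
    )
    table.to_csv(RESULTS / "planted_recovery.tsv", sep="\t", index=False,
                 float_format="%.3f")
    print(table.to_string(index=False))
    print(f"\nrecovered in {res.n_recovered}/{res.n_seeds} cohorts "
          f"(criterion: Dice > 0.3 with the planted sphere, >= 9/10)")
    print(f"table written to {RESULTS / 'planted_recovery.tsv'}")


if __name__ == "__main__":
    main()
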