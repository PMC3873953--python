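#!/usr/bin/env python
"""Robustness sweep over master seeds.

Repeats the full study across independent master seeds, once with the dose
attenuation and once with identical coupling everywhere, and tabulates how
often the gamma-band dose pattern is recovered and how often a day-1
PRO-vs-control difference appears under the null.  Writes
results/seed_sweep.csv.
"""

import argparse

import pandas as pd

import common
from dtfnet.experiments import (
    any_pro_control_significant,
    headline_pattern_holds,
    run_study,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-seeds", type=int, default=20)
    parser.add_argument("--first-seed", type=int, default=0)
    args = parser.parse_args()

    rows = []
    for i in range(args.n_seeds):
        seed = args.first_seed + i
        dosed = run_study(seed)
        null = run_study(10_000 + seed, attenuated=False)
        rows.append(
            {
                "seed": seed,
                "gamma_pattern": headline_pattern_holds(dosed, band="gamma"),
                "theta_pattern": headline_pattern_holds(dosed, band="theta"),
                "null_day1_false_positive": any_pro_control_significant(null, "gamma", 1),
            }
        )
        print(f"seed {seed}: gamma pattern {rows[-1]['gamma_pattern']}, "
              f"null false positive {rows[-1]['null_day1_false_positive']}", flush=True)

    table = pd.DataFrame(rows)
    out = common.results_dir() / "seed_sweep.csv"
    table.to_csv(out, index=False)
    n = len(table)
    print(f"\ngamma dose pattern recovered in {table.gamma_pattern.sum()}/{n} seeds")
    print(f"theta dose pattern recovered in {table.theta_pattern.sum()}/{n} seeds")
    print(f"spurious day-1 significance under the null in "
          f"{table.null_day1_false_positive.sum()}/{n} seeds")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
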