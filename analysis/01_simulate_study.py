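#!/usr/bin/env python
"""Simulate the synthetic working-memory LFP study.

Generates the full dosed experiment — 3 groups x 3 days x 6 subjects x 10
sections of 16-channel, 3 s epochs at 2 kHz, with the high-dose group's
directed coupling attenuated to 0.3x (day 1) and 0.6x (day 2) — caches the
epochs under scratch/ and writes a design summary table to results/.
"""

import argparse

import pandas as pd

import common


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=common.DEFAULT_SEED)
    args = parser.parse_args()

    epochs = common.study_epochs(args.seed)
    counts = (
        epochs.labels.groupby(["group", "day"])
        .agg(n_sections=("section", "size"), n_subjects=("subject", "nunique"))
        .reset_index()
    )
    out = common.results_dir() / "study_design.csv"
    counts.to_csv(out, index=False)

    print(f"study seed {args.seed}: {epochs.n_epochs} epochs of "
          f"{epochs.n_samples} samples x {epochs.n_channels} channels "
          f"at {epochs.sampling_rate_hz:.0f} Hz")
    print(f"event sample index within epoch: {epochs.event_index} (2 s pre / 1 s post)")
    with pd.option_context("display.width", 120):
        print(counts.to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
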