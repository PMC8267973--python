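#!/usr/bin/env python
"""Materialise the four synthetic study cohorts.

Generates one delimited-text cohort per preset — reproducing each study
group's observation count, age window, bilateral structure and noise level —
under results/cohorts/, and a 10x-scaled aggregate cohort used by the
refitting step.  Deterministic for a given --seed.
"""

import argparse
import pathlib

from imtlogistic import generate_cohort, presets, write_dataset
from imtlogistic.cohorts import scaled_preset

OUT = pathlib.Path("results/cohorts")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    for name, spec in presets(seed=args.seed).items():
        df = generate_cohort(spec)
        write_dataset(df, OUT / f"{name}.csv")
        print(
            f"{name}: {len(df)} observations, ages "
            f"{df['age_years'].min():.0f}-{df['age_years'].max():.0f} y, "
            f"IMT {df['imt_mm'].min():.2f}-{df['imt_mm'].max():.2f} mm"
        )
    big = scaled_preset("aggregate", 10, seed=args.seed)
    write_dataset(generate_cohort(big), OUT / "aggregate_x10.csv")
    print(f"aggregate_x10: {big.n_observations} observations (recovery-study size)")


if __name__ == "__main__":
    main()
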