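#!/usr/bin/env python
"""Refit the logistic curve to each synthetic cohort.

Runs the multi-start bounded least-squares calibration on every cohort file
produced by 02_simulate_cohorts.py, writes the fitted parameters and
goodness-of-fit statistics to results/fits.json, and reports how well the
10x aggregate refit recovers its generating curve.
"""

import argparse
import json
import pathlib

import numpy as np

from imtlogistic import (
    REFERENCE_CURVES,
    FitConfig,
    fit_logistic,
    imt_at_age,
    read_dataset,
)

COHORTS = pathlib.Path("results/cohorts")
OUT = pathlib.Path("results/fits.json")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-starts", type=int, default=12)
    args = parser.parse_args()

    fits = {}
    for path in sorted(COHORTS.glob("*.csv")):
        data = read_dataset(path)
        # the legacy sample's RMSE convention divides by n, not n-1
        dialect = "n" if "dialysis" in path.stem else "n_minus_1"
        res = fit_logistic(
            data,
            FitConfig(n_starts=args.n_starts, seed=args.seed, rmse_dialect=dialect),
        )
        fits[path.stem] = res.to_dict()
        p = res.params
        print(
            f"{path.stem}: n={res.n}  x0={p.x0:.3f}  c={p.c:.3f}  a={p.a:.4f}  "
            f"sse={res.sse:.3f}  rmse={res.rmse:.4f}  r2={res.r2:.3f}"
        )

    if "aggregate_x10" in fits:
        truth = REFERENCE_CURVES["aggregate"]
        fitted = fits["aggregate_x10"]
        from imtlogistic import LogisticParams

        fp = LogisticParams(fitted["x0"], fitted["c"], fitted["a"])
        ages = np.linspace(19.0, 74.0, 200)
        gap = float(np.max(np.abs(imt_at_age(fp, ages) - imt_at_age(truth, ages))))
        print(
            f"\n10x aggregate refit tracks the generating curve within "
            f"{gap:.3f} mm across the observed ages (noise sd is 0.16 mm)."
        )

    OUT.write_text(json.dumps(fits, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
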