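#!/usr/bin/env python
"""Coral fate under warming across genetic variance and fecundity, no restoration.

Runs the no-supplementation scenarios over a grid of additive genetic
variance V and effective fecundity beta, and reports the median final
(year-500) and median minimum network coral cover.  The headline contrast:
corals with V = 0 go extinct under the 5 degC warming trajectory at every
fecundity, while V = 0.1 populations decline transiently and recover above
90 % cover.  Writes results/biological_scenarios.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from reefrescue import run_scenario
from reefrescue.study import scenario


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=5)
    parser.add_argument("--v-levels", default="0,0.05,0.1")
    parser.add_argument("--betas", default="0.01,0.05,0.1")
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = []
    for V in (float(x) for x in args.v_levels.split(",")):
        for beta in (float(x) for x in args.betas.split(",")):
            result = run_scenario(
                scenario(V=V, beta=beta),
                n_replicates=args.replicates,
                base_seed=args.seed,
            )
            m = result.metrics
            rows.append(
                {
                    "V": V,
                    "beta": beta,
                    "median_final_cover": m["median_final_cover"],
                    "median_min_cover": m["median_min_cover"],
                    "final_q10": m["final_cover_q10"],
                    "final_q90": m["final_cover_q90"],
                }
            )
            print(
                f"V={V:<5g} beta={beta:<5g} final={m['median_final_cover']:.3f} "
                f"min={m['median_min_cover']:.2e}"
            )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out_dir / "biological_scenarios.csv", index=False)
    print(f"wrote {args.out_dir / 'biological_scenarios.csv'}")


if __name__ == "__main__":
    main()
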