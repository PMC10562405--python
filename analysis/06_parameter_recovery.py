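#!/usr/bin/env python
"""Parameter-recovery validation of the full-model fitting pipeline.

Simulates replicate synthetic participants at the group-mean true
parameters and refits the full model, reporting per-parameter bias,
RMSE and the recovery standard error -- the evidence that the pipeline
can separate starting-point from drift-criterion bias at the study's
effect sizes.
"""

import argparse
from pathlib import Path

from maskddm.inference import FitSettings, parameter_recovery
from maskddm.models import GROUP_MEANS


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--reps", type=int, default=10)
    ap.add_argument("--trials-per-cell", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--out", type=Path, default=Path("results/recovery"))
    args = ap.parse_args()

    summary, per_rep = parameter_recovery(
        GROUP_MEANS, n_per_cell=args.trials_per_cell, n_reps=args.reps,
        seed=args.seed, settings=FitSettings())
    args.out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out / "summary.csv", index=False)
    per_rep.to_csv(args.out / "replicates.csv", index=False)

    print(f"{args.reps} replicates, {args.trials_per_cell} trials/cell:")
    for _, r in summary.iterrows():
        print(f"  {r['parameter']:14s} truth {r['truth']:8.3f}  "
              f"mean {r['mean']:8.3f}  bias {r['bias']:+.3f}  "
              f"rmse {r['rmse']:.3f}")
    conv = per_rep[per_rep["converged"]]
    print(f"z_mask sign positive in {(conv['z_mask'] > 0).mean():.0%}, "
          f"vc_mask negative in {(conv['vc_mask'] < 0).mean():.0%} "
          f"of converged replicates")
    print(f"wrote tables under {args.out}/")


if __name__ == "__main__":
    main()
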