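#!/usr/bin/env python
"""AIC/BIC model selection over the fitted four-model family.

Reports, per criterion, the cohort-mean value for each model and the
percentage of participants it fits best (ties resolved toward the model
with fewer free parameters).
"""

import argparse
from pathlib import Path

from maskddm.inference import select_models
from maskddm.io import read_fits


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/selection.csv"))
    args = ap.parse_args()

    fits = read_fits(args.fits)
    table = select_models(fits)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    for crit in ("AIC", "BIC"):
        sub = table[table.criterion == crit].set_index("model")
        best = sub["mean"].idxmin()
        print(f"{crit}: " + "  ".join(
            f"{m} {sub.loc[m, 'mean']:.1f} ({sub.loc[m, 'pct_best']:.0f}%)"
            for m in sub.index) + f"   -> lowest mean: {best}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
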