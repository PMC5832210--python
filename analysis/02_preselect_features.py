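#!/usr/bin/env python
"""Pre-select robust and surrogate features.

Stage 1 (robustness): keep a tumor feature only if its ICC(2,1) exceeds
0.85 in BOTH the test-retest and the inter-observer replicate contexts.
Stage 2 (surrogacy): among the robust features, keep a merged-node
feature only if it agrees with the largest node AND the most active
node (ICC > 0.85 and Bland-Altman 95% limits of agreement within
+/-10%).  Writes per-feature reports and the retained lists under
results/selection/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nodal_petrad import preselection as presel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "selection")
    ap.add_argument("--icc-cutoff", type=float, default=0.85)
    ap.add_argument("--loa", type=float, default=10.0)
    args = ap.parse_args()

    load = lambda name: pd.read_csv(args.data / name)
    tumor = load("dev_structure_tumor.csv")
    contexts = {
        "retest": (tumor, load("dev_tumor_retest_b.csv")),
        "observer": (load("dev_tumor_observer_a.csv"),
                     load("dev_tumor_observer_b.csv")),
    }
    robust = presel.robustness_filter(list(tumor.columns), contexts,
                                      icc_cutoff=args.icc_cutoff)
    keep = robust.retained
    surrogate = presel.surrogate_filter(
        load("dev_structure_ln_merged.csv")[keep],
        load("dev_structure_ln_volume.csv")[keep],
        load("dev_structure_ln_max.csv")[keep],
        icc_cutoff=args.icc_cutoff, loa_bound=args.loa)

    args.out.mkdir(parents=True, exist_ok=True)
    robust.to_csv(args.out / "robustness.csv")
    surrogate.to_csv(args.out / "surrogacy.csv")
    (args.out / "retained_tumor.txt").write_text("\n".join(robust.retained) + "\n")
    (args.out / "retained_ln.txt").write_text("\n".join(surrogate.retained) + "\n")

    print(f"robustness: {len(robust.retained)}/118 tumor features pass "
          f"ICC > {args.icc_cutoff} in both contexts")
    print(f"surrogacy: {len(surrogate.retained)}/{len(keep)} merged-node features "
          f"are surrogates of both the largest and most active node")
    print("retained LN features:", ", ".join(surrogate.retained) or "(none)")


if __name__ == "__main__":
    main()
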