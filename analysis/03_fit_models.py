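#!/usr/bin/env python
"""Fit the three LASSO-Cox prognostic models and run their diagnostics.

Model 1 selects among the robust tumor features, model 2 among the
surrogate merged-node features, model 3 among the union.  The penalty
of each model is chosen by 10-fold cross-validated partial-likelihood
deviance; selected features are refit unpenalized on the whole
development cohort.  Log-linearity (penalized spline) and proportional
hazards (Schoenfeld residuals vs log time) are checked for every
selected feature.  Writes model JSONs and diagnostics under
results/models/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nodal_petrad import survival as surv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--selection", type=Path, default=ROOT / "results" / "selection")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "models")
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--folds", type=int, default=10)
    args = ap.parse_args()

    cohort = pd.read_csv(args.data / "dev_cohort.csv")
    X = pd.read_csv(args.data / "dev_features.csv").drop(columns="patient_id")
    tumor_feats = (args.selection / "retained_tumor.txt").read_text().split()
    ln_feats = (args.selection / "retained_ln.txt").read_text().split()
    pools = {
        "tumor": [f"tumor__{f}" for f in tumor_feats],
        "ln": [f"ln__{f}" for f in ln_feats],
    }
    pools["combined"] = pools["tumor"] + pools["ln"]

    args.out.mkdir(parents=True, exist_ok=True)
    for model_id, pool in pools.items():
        Xp = X[pool]
        Xp = Xp.loc[:, Xp.std(ddof=0) > 0]
        lasso = surv.lasso_cox_cv(Xp, cohort["time"], cohort["event"],
                                  n_folds=args.folds, seed=args.seed)
        if not lasso.selected:
            print(f"model {model_id}: no features selected at the CV penalty")
            continue
        fit = surv.refit_cox(X, cohort["time"], cohort["event"], lasso.selected,
                             model_id=model_id)
        fit.lasso_alpha = lasso.alpha
        fit.seed = args.seed
        for feat in fit.features:
            diag = surv.check_log_linearity(X[feat].to_numpy(), cohort["time"],
                                            cohort["event"], name=feat)
            fit.diagnostics.setdefault("log_linearity", {})[feat] = {
                "verdict": diag["verdict"], "p_nonlinear": diag["p_nonlinear"]}
        ph = surv.check_ph_schoenfeld(X, cohort["time"], cohort["event"],
                                      fit.features)
        fit.diagnostics["ph_p_values"] = ph["p_values"]
        ph["residuals"].to_csv(args.out / f"{model_id}_schoenfeld.csv", index=False)
        fit.to_json(args.out / f"{model_id}.json")
        feats = ", ".join(f"{f} (HR {fit.hr[f]:.2f})" for f in fit.features)
        print(f"model {model_id}: {feats}")
        print(f"  internal C-index {fit.c_internal:.3f} "
              f"[{fit.c_internal_ci[0]:.3f}-{fit.c_internal_ci[1]:.3f}], "
              f"AIC {fit.aic:.1f}")


if __name__ == "__main__":
    main()
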