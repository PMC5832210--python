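#!/usr/bin/env python
"""External validation and summary report of the study.

Freezes the development-cohort coefficients, scores the validation
cohort, and writes the summary tables under results/report/: the
univariable clinical screen, the common-PET-descriptor table (max/peak/
mean SUV, volumes, tumor load), the descriptor correlation matrix, the
per-model feature table, and the AIC comparison (ascending AIC first).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nodal_petrad import survival as surv
from nodal_petrad.images import tumor_load
from nodal_petrad.pipeline import COMMON_DESCRIPTORS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--models", type=Path, default=ROOT / "results" / "models")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "report")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dev = pd.read_csv(args.data / "dev_cohort.csv")
    Xd = pd.read_csv(args.data / "dev_features.csv").drop(columns="patient_id")
    val = pd.read_csv(args.data / "validation_cohort.csv")
    Xv = pd.read_csv(args.data / "validation_features.csv").drop(columns="patient_id")

    screen = surv.univariable_screen(
        dev, ["age", "gender", "stage", "n_stage", "n_ln_stations", "histology",
              "rt_dose", "chemotherapy"])
    screen.round(4).to_csv(args.out / "table_clinical_univariable.csv", index=False)

    # raw per-structure tables (the modeling matrix log-transforms LN volume)
    structs = {"tumor": pd.read_csv(args.data / "dev_structure_tumor.csv"),
               "ln": pd.read_csv(args.data / "dev_structure_ln_merged.csv")}
    rows, common = [], {}
    for struct, table in structs.items():
        for feat in COMMON_DESCRIPTORS:
            col = table[feat]
            res = surv.univariable_cox(col, dev["time"], dev["event"], name=feat)
            common[f"{struct}_{feat}"] = col
            rows.append(dict(structure=struct, feature=feat,
                             range=f"{col.min():.1f}-{col.max():.1f}",
                             mean_sd=f"{col.mean():.1f}+/-{col.std():.1f}",
                             hr=round(res.hr, 3), p=round(res.p, 4),
                             c_index=round(res.c, 3)))
    load = pd.Series([tumor_load(tv, lv) for tv, lv in
                      zip(structs["tumor"]["shape_volume_cc"],
                          structs["ln"]["shape_volume_cc"])])
    res = surv.univariable_cox(load, dev["time"], dev["event"], name="tumor_load")
    rows.append(dict(structure="both", feature="tumor_load",
                     range=f"{load.min():.1f}-{load.max():.1f}",
                     mean_sd=f"{load.mean():.1f}+/-{load.std():.1f}",
                     hr=round(res.hr, 3), p=round(res.p, 4),
                     c_index=round(res.c, 3)))
    pd.DataFrame(rows).to_csv(args.out / "table_common_descriptors.csv", index=False)

    corr = surv.pearson_correlation_matrix(
        pd.DataFrame({**common, "tumor_load": load}))
    corr.round(3).to_csv(args.out / "correlation_matrix.csv")

    model_rows, aics = [], {}
    for path in sorted(args.models.glob("*.json")):
        payload = json.loads(path.read_text())
        model_id = payload["model_id"]
        aics[model_id] = payload["aic"]
        lp = np.zeros(len(Xv))
        for f in payload["features"]:
            lp += Xv[f].to_numpy() * payload["coef"][f]
        c_ext = surv.concordance_index(lp, val["time"], val["event"]).c
        for f in payload["features"]:
            model_rows.append(dict(
                model=model_id, feature=f, hr=round(payload["hr"][f], 3),
                p=round(payload["p"][f], 4),
                c_internal=round(payload["c_internal"], 3),
                c_external=round(c_ext, 3), aic=round(payload["aic"], 1)))
        print(f"model {model_id}: internal C {payload['c_internal']:.3f}, "
              f"external C {c_ext:.3f}, AIC {payload['aic']:.1f}")
    pd.DataFrame(model_rows).to_csv(args.out / "table_models.csv", index=False)

    order = surv.aic_ordering(aics)
    pd.DataFrame({"model": order, "aic": [round(aics[m], 1) for m in order],
                  "rank": range(1, len(order) + 1)}
                 ).to_csv(args.out / "model_comparison_aic.csv", index=False)
    print("AIC ordering (preferred first):", " < ".join(order))


if __name__ == "__main__":
    main()
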