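"""Logistic diagnostic model with stratified 10-fold cross-validation.

Fits the unpenalized logistic regression on the declarative feature set
(the significant band-power and asymmetry features), reports
coefficients, fold-mean AUC with a stratified bootstrap CI on the pooled
out-of-fold scores, and sensitivity/specificity at training-derived
Youden cut-offs.  Writes model_report.json and the pooled-score ROC
points for plotting.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from eegmdd import model as model_mod

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
ap.add_argument("--k", type=int, default=10)
args = ap.parse_args()

features = pd.read_csv(args.out / "features.csv")
meta = pd.read_csv(args.out / "metadata.csv")

report = model_mod.diagnostic_report(features, meta, k=args.k, seed=args.seed)
(args.out / "model_report.json").write_text(json.dumps(report.to_dict(), indent=1))

X, y, _ = model_mod.design_matrix(features, meta)
cv = model_mod.cross_validated_performance(X, y, k=args.k, seed=args.seed)
roc = model_mod.roc_curve(cv["oof_scores"], y)
pd.DataFrame({"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
              "specificity": roc.specificity}).to_csv(
    args.out / "roc_points.csv", index=False)

print(f"cross-validated ({args.k}-fold) mean AUC: {report.cv_mean_auc:.4f}")
print(f"95% bootstrap CI (pooled out-of-fold AUC): "
      f"[{report.auc_ci_95[0]:.4f}, {report.auc_ci_95[1]:.4f}]")
print(f"sensitivity/specificity at Youden cut-offs: "
      f"{100 * report.cv_sensitivity:.2f}% / {100 * report.cv_specificity:.2f}%")
print(f"pooled-score Youden cut-off: {roc.youden_cutoff:.3f} "
      f"(sens {roc.youden_sens:.3f}, spec {roc.youden_spec:.3f})")
print("largest coefficients:")
coef = sorted(report.to_dict()["coefficients"][1:], key=lambda c: -abs(c["B"]))
for c in coef[:4]:
    print(f"  {c['feature']}: B={c['B']:.3f} SE={c['SE']:.3f} p={c['p']:.4f}")
print(f"wrote {args.out / 'model_report.json'} and roc_points.csv")
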