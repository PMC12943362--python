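#!/usr/bin/env python
"""Differential analysis: univariate screen + PLS-DA/RF multivariate route.

Univariate tests run on the raw (post-QC, pre-treatment) intensities with
BH correction and the FC > 1.2 / < 0.8 rule; the multivariate route fits a
PLS-DA (component count by 10-fold CV Q2, response-permutation test) and a
bagged-tree classifier with OOB permutation importance, then takes the
union of routes.  Writes results/05_differential/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pfasmet.containers import FeatureStudy
from pfasmet.differential import (fit_plsda, permutation_test, rf_classify,
                                  rf_importance_cutoff, select_features,
                                  univariate_screen)
from pfasmet.simulate import GroundTruth

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/03_qc"))
parser.add_argument("--pretreated", type=Path, default=Path("results/04_pretreat"))
parser.add_argument("--truth", type=Path, default=Path("results/01_study/truth_study.json"))
parser.add_argument("--n-perm", type=int, default=999)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/05_differential"))
args = parser.parse_args()

study = FeatureStudy.read(args.study)
groups = study.injections.loc[study.sample_ids, "group"]
uni = univariate_screen(study.intensities[study.sample_ids], groups)

Xp = pd.read_csv(args.pretreated / "pretreated.tsv", sep="\t",
                 index_col="feature_id")[study.sample_ids].T
y = (groups == "high").astype(int).to_numpy()
model = fit_plsda(Xp, y, seed=args.seed)
model.perm_p = permutation_test(Xp, y, model.n_components,
                                n_perm=args.n_perm, seed=args.seed)
rf = rf_classify(Xp, y, n_trees=500, seed=args.seed)
cutoff = rf_importance_cutoff(Xp, y, n_trees=500, seed=args.seed + 1)
sel = select_features(uni, [model], rf, cutoff)

args.out.mkdir(parents=True, exist_ok=True)
table = (uni.rename(columns={"selected": "selected_univariate"})
         .join(model.vip).join(rf.importance).join(sel))
table.to_csv(args.out / "differential.tsv", sep="\t", index_label="feature_id")
(args.out / "models.json").write_text(json.dumps({
    "plsda": {"n_components": model.n_components, "r2": model.r2,
              "q2": model.q2, "auc": model.auc, "perm_p": model.perm_p},
    "rf": {"oob_auc": rf.auc_oob, "importance_cutoff": cutoff}}, indent=1))

print(f"univariate: {int(uni['selected'].sum())} features at FDR<0.05 with FC rule")
print(f"PLS-DA: {model.n_components} comp, R2={model.r2:.2f}, Q2={model.q2:.2f}, "
      f"AUC={model.auc:.2f}, permutation p={model.perm_p:.3f}")
print(f"RF: OOB AUC={rf.auc_oob:.2f}; importance cutoff={cutoff:.4f}")
print(f"union selection: {int(sel['selected'].sum())} features")
if args.truth.exists():
    truth = GroundTruth.read(args.truth)
    planted = set(truth.planted_feature_ids) & set(sel.index)
    selected = set(sel.index[sel["selected"]])
    nulls = set(sel.index) - set(truth.planted_feature_ids)
    print(f"against ground truth: recovered "
          f"{len(selected & planted)}/{len(planted)} planted; "
          f"null selection rate {len(selected & nulls) / len(nulls):.3f}")
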