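#!/usr/bin/env python
"""Exposure association, ROC, and the discriminatory metabolite panel.

For the selected features: Spearman association with total PFAS (with the
|r| strength categories), univariate ROC with 500-bootstrap CIs, Cohen's d
and noncentral-t power; then panel construction (hierarchical clustering ->
PLS-DA VIP ranking over Monte-Carlo subsamples -> highest-AUC champion per
cluster) and linear-SVM MCCV evaluation with class-label permutation.
Writes results/06_biomarker/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pfasmet.biomarker import (build_panel, cluster_features,
                               evaluate_panel_svm, rank_features_mccv,
                               spearman_assoc, univariate_roc)
from pfasmet.containers import CohortTable, FeatureStudy
from pfasmet.stats import cohens_d, power_t

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/03_qc"))
parser.add_argument("--cohort", type=Path, default=Path("results/01_study"))
parser.add_argument("--pretreated", type=Path, default=Path("results/04_pretreat"))
parser.add_argument("--differential", type=Path, default=Path("results/05_differential"))
parser.add_argument("--panel-size", type=int, default=5)
parser.add_argument("--n-iter", type=int, default=100)
parser.add_argument("--n-perm", type=int, default=999)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/06_biomarker"))
args = parser.parse_args()

study = FeatureStudy.read(args.study)
cohort = CohortTable.read(args.cohort)
sel = pd.read_csv(args.differential / "differential.tsv", sep="\t",
                  index_col="feature_id")
candidates = list(sel.index[sel["selected"]])
groups = study.injections.loc[study.sample_ids, "group"]
y = (groups == "high").astype(int).to_numpy()
totals = cohort.subjects.loc[study.sample_ids, "total_pfas"]
pre = pd.read_csv(args.pretreated / "pretreated.tsv", sep="\t",
                  index_col="feature_id")
Xc = pre.loc[candidates, study.sample_ids].T

rows = []
aucs = {}
for fid in candidates:
    raw = study.intensities.loc[fid, study.sample_ids].to_numpy(dtype=float)
    ok = np.isfinite(raw)
    assoc = spearman_assoc(raw[ok], totals.to_numpy()[ok], fid)
    xv = Xc[fid].to_numpy()
    roc = univariate_roc(xv, y, n_boot=500, seed=args.seed, metabolite=fid)
    aucs[fid] = roc.auc
    d = cohens_d(xv[y == 1], xv[y == 0])
    rows.append({"feature_id": fid, "spearman_r": assoc.r, "spearman_p": assoc.p,
                 "category": assoc.category, "auc": roc.auc,
                 "auc_ci_lo": roc.ci[0], "auc_ci_hi": roc.ci[1],
                 "cohens_d": d, "power": power_t(d, 41, 41).power})
table = pd.DataFrame(rows).set_index("feature_id")

clusters = cluster_features(Xc, k=args.panel_size)
freqs = rank_features_mccv(Xc, y, n_iter=args.n_iter, seed=args.seed)
panel = build_panel(clusters, freqs, pd.Series(aucs), panel_size=args.panel_size)
evaluation = evaluate_panel_svm(Xc[panel], y, n_iter=args.n_iter,
                                n_perm=args.n_perm, seed=args.seed)

args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "candidates.tsv", sep="\t")
(args.out / "panel.json").write_text(json.dumps({
    "members": evaluation.members, "auc": evaluation.auc,
    "ci": list(evaluation.ci), "accuracy": evaluation.accuracy,
    "perm_p": evaluation.perm_p,
    "clusters": {f: int(c) for f, c in clusters.items()},
    "frequencies": {f: float(v) for f, v in freqs.items()}}, indent=1))

n_sig = int((table["spearman_p"] < 0.05).sum())
print(f"{len(candidates)} candidates; {n_sig} significantly associated with "
      "total PFAS")
best = table["auc"].idxmax()
print(f"best single feature: {best} (AUC {table.loc[best, 'auc']:.3f})")
print(f"panel ({args.panel_size} members, one per cluster): {panel}")
print(f"panel AUC {evaluation.auc:.3f} "
      f"[{evaluation.ci[0]:.3f}, {evaluation.ci[1]:.3f}], "
      f"mean accuracy {evaluation.accuracy:.3f}, "
      f"permutation p = {evaluation.perm_p:.3f}")
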