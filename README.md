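# pfasmet

Statistical pipeline for **extreme-group untargeted serum metabolomics of
PFAS exposure** — for biostatisticians and exposure scientists who need the
full workflow of such a study as tested, reusable code: censored-exposure
imputation and extreme-group design, pooled-QC feature quality control,
pretreatment, differential analysis, exposure–metabolite association, a
discriminatory metabolite panel with Monte-Carlo cross-validation, power
analysis, and pathway over-representation. A synthetic-data generator with
known ground truth stands in for the (undeposited) cohort, so every stage is
verifiable end to end.

## The statistics at the core

- **Censored exposure.** Per-compound serum PFAS ~ lognormal, left-censored
  at LOD/LOQ. With ≥30% of values observed, (μ, σ) are fitted by maximum
  likelihood (density for observed values, CDF mass for censored intervals)
  and censored entries replaced by single truncated draws. Totals use LOQ/2
  substitution; groups are the lowest/highest 41 subjects by total.
- **Feature QC.** Smoothing cubic spline of QC log-intensity vs injection
  order (smoothing by leave-one-out CV, corrections kept only if the QC RSD
  improves), then blank (10×), detection (75% group / 70% QC), RSD (<30%)
  and D-ratio (<40%) filters, and Tukey-fence sample outliers.
- **Pretreatment.** missForest-style random-forest imputation (QCs by
  median), log transform, probabilistic quotient normalization against the
  pooled-QC median spectrum, Pareto scaling.
- **Differential analysis.** Shapiro-routed t / Mann–Whitney tests with
  Benjamini–Hochberg and an FC > 1.2 or < 0.8 rule on raw intensities;
  PLS-DA with 10-fold-CV Q², VIP (mean VIP² ≡ 1), response-permutation
  test; bagged trees with out-of-bag AUC and permutation importance; union
  of routes.
- **Panel.** Hierarchical clustering (1 − |Spearman|) of candidates into 5
  clusters, PLS-DA VIP ranking over balanced subsamples, the highest-AUC
  member of the top-12 per cluster; linear-SVM Monte-Carlo cross-validation
  (balanced 2/3 : 1/3 splits) with percentile CI and class-label
  permutation p.
- **Effect size and power.** Cohen's d with pooled sd; two-sided power from
  the noncentral t with δ = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2.
- **Pathways.** One-sided Fisher over-representation with BH, plus a
  topology impact score: the matched share of a pathway graph's total
  betweenness centrality.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each stage reads the previous stage's output under `results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_cohort_comparison.py
python analysis/03_feature_qc.py
python analysis/04_pretreatment.py --seed 1
python analysis/05_differential.py --seed 1 --n-perm 499
python analysis/06_biomarker_panel.py --seed 1 --n-perm 499
python analysis/07_enrichment.py --seed 1
```

With seed 1 this prints, among other lines:

```
total PFAS median: low group 3.2 ng/mL, high group 123.0 ng/mL
drift correction: 792 corrected, 1208 left alone, 0 with too few QC observations
median QC RSD: 11.3% before, 9.0% after correction
filters removed {'blank': 0, 'detection': 0, 'rsd': 0, 'dratio': 58}; 1942 features retained
univariate: 12 features at FDR<0.05 with FC rule
PLS-DA: 5 comp, R2=1.00, Q2=0.19, AUC=0.80, permutation p=0.002
union selection: 86 features
against ground truth: recovered 19/30 planted; null selection rate 0.035
panel (5 members, one per cluster): ['F01651', 'F01220', 'F01978', 'F01450', 'F00488']
panel AUC 0.791 [0.637, 0.919], mean accuracy 0.709, permutation p = 0.002
```

Reading this: the two simulated exposure groups differ ~40-fold in total
PFAS; drift correction lowers the pooled-QC median RSD from 11.3% to 9.0%;
the quality filters drop 58 of 2000 features; the differential union
recovers 19 of the 30 planted group effects while selecting only 3.5% of
null features; and the five-metabolite panel separates the groups with a
cross-validated AUC of 0.79 (95% CI 0.64–0.92) that label permutation
rates p = 0.002. The same pipeline is scriptable via the `pfasmet` CLI
(`simulate`, `exposure`, `qc`, `pretreat`, `differential`, `biomarker`,
`enrich`, `run-all`).

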