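#!/usr/bin/env python
"""Simulate the synthetic study: cohort, exposure groups, feature matrix.

Draws a 517-subject cohort with censored per-compound PFAS serum
concentrations, imputes the censored values, totals them (LOQ/2 rule),
selects the 41 lowest- and 41 highest-total subjects, and simulates the
LC-HRMS feature study (2000 features, 30 planted group effects) for those
82 subjects.  Writes everything, including the ground truth, under
results/01_study/.
"""

import argparse
from pathlib import Path

from pfasmet.exposure import assign_extreme_groups, impute_cohort, total_pfas
from pfasmet.simulate import SynthConfig, generate_cohort, generate_feature_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/01_study"))
args = parser.parse_args()

cfg = SynthConfig(n_subjects_total=517, n_per_group=41, n_features=2000,
                  n_planted=30, seed=args.seed)
cohort, truth_cohort = generate_cohort(cfg)
cohort, fits = impute_cohort(cohort, seed=args.seed)
totals = total_pfas(cohort)
cohort.subjects["total_pfas"] = totals
cohort.subjects["group"] = assign_extreme_groups(totals, cfg.n_per_group)
study, truth_study = generate_feature_study(cfg, cohort)

args.out.mkdir(parents=True, exist_ok=True)
cohort.write(args.out)
study.write(args.out)
truth_cohort.write(args.out / "truth_cohort.json")
truth_study.write(args.out / "truth_study.json")

low = totals[cohort.subjects["group"] == "low"]
high = totals[cohort.subjects["group"] == "high"]
imputed = [f.compound for f in fits if f.imputed]
print(f"cohort: {len(cohort.subjects)} subjects, {len(fits)} PFAS compounds "
      f"({len(imputed)} imputable at the 30% rule)")
print(f"total PFAS median: low group {low.median():.1f} ng/mL, "
      f"high group {high.median():.1f} ng/mL")
print(f"study: {study.intensities.shape[0]} features x "
      f"{study.intensities.shape[1]} injections "
      f"({len(study.sample_ids)} samples, {len(study.qc_ids)} QCs, "
      f"{len(study.blank_ids)} blanks); {len(truth_study.planted_feature_ids)} "
      "planted effects")
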