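#!/usr/bin/env python
"""QC the feature study: drift correction, feature filters, sample outliers.

Corrects injection-order drift against the pooled-QC spline, applies the
blank/detection/RSD/D-ratio filters, flags detected-feature-count outlier
samples, and writes the filtered study to results/03_qc/.
"""

import argparse
import json
from pathlib import Path

from pfasmet.containers import FeatureStudy
from pfasmet.qc import (compute_qc_metrics, detect_sample_outliers,
                        drift_correct, filter_features, mask_outlier_samples)

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/01_study"))
parser.add_argument("--out", type=Path, default=Path("results/03_qc"))
args = parser.parse_args()

study = FeatureStudy.read(args.study)
pre_mrsd = compute_qc_metrics(study).mrsd
study, drift_report = drift_correct(study)
metrics = compute_qc_metrics(study)
study, filter_report = filter_features(study, metrics)
outliers = detect_sample_outliers(study)
study = mask_outlier_samples(study, outliers)

args.out.mkdir(parents=True, exist_ok=True)
study.write(args.out)
metrics.table.to_csv(args.out / "qc_metrics.tsv", sep="\t", index_label="feature_id")
filter_report.outlier_flags = {s: bool(f) for s, f in outliers.flags.items()}
filter_report.write(args.out / "filter_report.json")
(args.out / "drift_report.json").write_text(json.dumps(drift_report.as_dict()))

print(f"drift correction: {len(drift_report.corrected)} corrected, "
      f"{len(drift_report.rejected)} left alone, "
      f"{len(drift_report.too_few_qc)} with too few QC observations")
print(f"median QC RSD: {pre_mrsd['apolar']:.1f}% before, "
      f"{metrics.mrsd['apolar']:.1f}% after correction")
print(f"filters removed {dict(filter_report.removed_by)}; "
      f"{len(filter_report.retained)} features retained")
print(f"sample outliers flagged: {int(outliers.flags.sum())}")
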