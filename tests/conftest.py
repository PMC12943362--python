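"""Shared fixtures: small synthetic studies and hand-built containers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pfasmet.containers import CohortTable, FeatureStudy
from pfasmet.exposure import assign_extreme_groups, total_pfas
from pfasmet.simulate import SynthConfig, generate_cohort, generate_feature_study


def make_study(matrix, roles, orders=None, groups=None, feature_ids=None):
    """Build a FeatureStudy from a plain 2D array and role list."""
    matrix = np.asarray(matrix, dtype=float)
    p, n = matrix.shape
    feature_ids = feature_ids or [f"F{j:03d}" for j in range(1, p + 1)]
    inj_ids = [f"I{i:03d}" for i in range(1, n + 1)]
    orders = list(orders) if orders is not None else list(range(1, n + 1))
    groups = list(groups) if groups is not None else ["" for _ in range(n)]
    inj = pd.DataFrame({"role": roles, "order": orders, "group": groups},
                       index=pd.Index(inj_ids, name="injection_id"))
    feats = pd.DataFrame({"mz": np.linspace(100, 900, p),
                          "rt": np.linspace(1, 10, p),
                          "platform": "apolar", "polarity": "pos"},
                         index=pd.Index(feature_ids, name="feature_id"))
    inten = pd.DataFrame(matrix, index=feats.index, columns=inj.index)
    return FeatureStudy(inten, inj, feats)


def make_cohort(sexes, groups, ages=None, bmis=None, times=None, totals=None):
    """Minimal cohort table with covariates and group labels."""
    n = len(sexes)
    rng = np.random.default_rng(0)
    subj = pd.DataFrame({
        "sex": sexes,
        "age": ages if ages is not None else rng.uniform(20, 60, n).round(1),
        "bmi": bmis if bmis is not None else rng.uniform(20, 35, n).round(1),
        "collection_time": times if times is not None else rng.uniform(8, 18, n).round(2),
        "breastfeeding_past": 0, "breastfeeding_current": 0,
        "total_pfas": totals if totals is not None else rng.uniform(1, 200, n).round(2),
        "group": groups,
    }, index=pd.Index([f"S{i:03d}" for i in range(1, n + 1)], name="subject_id"))
    return CohortTable(subj, pd.DataFrame({"lod": [], "loq": []}))


@pytest.fixture(scope="session")
def grouped_cohort():
    """Synthetic cohort with extreme groups assigned (41 + 41 of 200)."""
    cfg = SynthConfig(n_subjects_total=200, n_per_group=41, seed=11)
    cohort, _ = generate_cohort(cfg)
    totals = total_pfas(cohort)
    cohort.subjects["total_pfas"] = totals
    cohort.subjects["group"] = assign_extreme_groups(totals, cfg.n_per_group)
    return cfg, cohort


@pytest.fixture(scope="session")
def small_study(grouped_cohort):
    """One synthetic feature study (200 features, 10 planted) with truth."""
    cfg, cohort = grouped_cohort
    cfg = SynthConfig(n_subjects_total=200, n_per_group=41, n_features=200,
                      n_planted=10, seed=11)
    study, truth = generate_feature_study(cfg, cohort)
    return cfg, cohort, study, truth
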