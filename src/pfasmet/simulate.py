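"""Synthetic cohorts and feature studies with known ground truth.

The generator emulates the statistical structure of an extreme-group serum
metabolomics study of PFAS exposure: per-compound left-censored lognormal
PFAS concentrations driven by a subject-level exposure factor, lognormal
feature intensities with smooth injection-order drift, pooled-QC replicates
at a target RSD, extraction-blank background, detection-limit plus random
missingness, and a configurable set of planted group effects (standardized
mean differences on the log scale) on a feature subset.

Because group assignment is derived from the simulated exposure factor,
planted metabolite shifts and total PFAS are correlated, which exercises
the downstream exposure-association stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortTable, FeatureStudy

# (name, log-median of the base concentration in ng/mL, extra log-sd, LOD, LOQ)
# PFOS dominates the serum profile; the minor carboxylates sit near or below
# the 0.1/0.2 ng/mL detection limits and are therefore heavily censored.
DEFAULT_PFAS = [
    ("PFOS", float(np.log(15.0)), 0.5, 0.1, 0.2),
    ("PFOA", float(np.log(1.5)), 0.5, 0.1, 0.2),
    ("PFHxS", float(np.log(0.8)), 0.5, 0.1, 0.2),
    ("PFNA", float(np.log(0.6)), 0.5, 0.1, 0.2),
    ("PFDA", float(np.log(0.3)), 0.5, 0.1, 0.2),
    ("PFHpS", float(np.log(0.15)), 0.5, 0.1, 0.2),
    ("PFUnA", float(np.log(0.10)), 0.6, 0.1, 0.2),
    ("PFHxA", float(np.log(0.08)), 0.6, 0.1, 0.2),
    ("PFHpA", float(np.log(0.08)), 0.6, 0.1, 0.2),
    ("PFBA", float(np.log(0.05)), 0.6, 0.1, 0.2),
    ("PFPeA", float(np.log(0.05)), 0.6, 0.1, 0.2),
    ("PFDoA", float(np.log(0.05)), 0.6, 0.1, 0.2),
    ("PFBS", float(np.log(0.05)), 0.6, 0.1, 0.2),
]

DEFAULT_COVARIATES = {
    "p_male": 0.33,
    "age_range": (20.0, 59.0),
    "bmi_log_mean": float(np.log(26.5)),
    "bmi_log_sd": 0.17,
    "collection_time_mean": 12.0,   # hours since midnight
    "collection_time_sd": 2.5,
    "p_breastfeeding_past": 0.55,   # among women
    "p_breastfeeding_current": 0.07,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    All rates are fractions in [0, 1]; effect sizes are on the Cohen's d
    scale applied to log intensities; ``drift_amplitude`` is the fractional
    intensity change across the run (1.0 = two-fold).
    """

    n_subjects_total: int = 517
    n_per_group: int = 41
    n_features: int = 500
    n_planted: int = 30
    planted_effect_sizes: list = field(default_factory=list)  # empty -> U(0.8, 1.2)
    qc_every: int = 10
    n_blanks: int = 8
    drift_amplitude: float = 0.3
    drift_shape: str = "random"          # "random" (cubic) or "linear" (monotone)
    qc_rsd_target: float = 0.10
    missing_rate_random: float = 0.02
    detection_quantile: float = 0.05
    blank_level: float = 0.01            # blank background as fraction of feature level
    exposure_log_sd: float = 1.2         # sd of the subject-level log exposure factor
    pfas_compounds: list = field(default_factory=lambda: list(DEFAULT_PFAS))
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("n_planted must not exceed n_features")
        for name, rate in [("qc_rsd_target", self.qc_rsd_target),
                           ("missing_rate_random", self.missing_rate_random),
                           ("detection_quantile", self.detection_quantile)]:
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if 2 * self.n_per_group > self.n_subjects_total:
            raise ValueError("2 * n_per_group must not exceed n_subjects_total")
        for name, _mu, sd, lod, loq in self.pfas_compounds:
            if sd <= 0:
                raise ValueError(f"non-positive log-sd for compound {name}")
            if lod <= 0 or lod > loq:
                raise ValueError(f"invalid LOD/LOQ for compound {name}")
        if self.drift_shape not in ("random", "linear"):
            raise ValueError("drift_shape must be 'random' or 'linear'")


@dataclass
class GroundTruth:
    """Planted effects, drift and censoring parameters of a synthetic study."""

    planted_feature_ids: list = field(default_factory=list)
    true_d: dict = field(default_factory=dict)            # feature id -> signed d
    drift: dict = field(default_factory=dict)             # feature id -> {amp, coeffs}
    n_injections: int = 0
    censored_fractions: dict = field(default_factory=dict)  # compound -> fraction
    exposure_factors: dict = field(default_factory=dict)    # subject id -> factor
    true_group: dict = field(default_factory=dict)          # subject id -> low/high

    def drift_log_factor(self, feature_id: str, orders) -> np.ndarray:
        """Log multiplicative drift factor of one feature at injection orders."""
        info = self.drift[feature_id]
        t = (np.asarray(orders, dtype=float) - 1.0) / max(self.n_injections - 1, 1)
        basis = np.vstack([t, t ** 2, t ** 3])
        return info["amp"] * (np.asarray(info["coeffs"]) @ basis)

    def drift_factor(self, feature_id: str, orders) -> np.ndarray:
        out = np.exp(self.drift_log_factor(feature_id, orders))
        return out

    def write(self, path) -> None:
        payload = {
            "planted_feature_ids": list(self.planted_feature_ids),
            "true_d": self.true_d,
            "drift": self.drift,
            "n_injections": self.n_injections,
            "censored_fractions": self.censored_fractions,
            "exposure_factors": self.exposure_factors,
            "true_group": self.true_group,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def generate_cohort(config: SynthConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw a synthetic cohort of censored per-compound PFAS concentrations.

    Each subject carries a lognormal exposure factor; compound concentrations
    are the compound's base lognormal scaled by that factor.  Values below
    LOD are flagged ``below_lod`` (value withheld), values in [LOD, LOQ)
    ``between_lod_loq``, the rest ``quantified``.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    n = config.n_subjects_total
    cov = {**DEFAULT_COVARIATES, **config.covariate_params}

    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    log_expo = rng.normal(0.0, config.exposure_log_sd, size=n)
    expo = np.exp(log_expo)

    sex = np.where(rng.random(n) < cov["p_male"], "male", "female")
    lo, hi = cov["age_range"]
    age = np.round(rng.uniform(lo, hi, size=n), 1)
    bmi = np.round(np.exp(rng.normal(cov["bmi_log_mean"], cov["bmi_log_sd"], size=n)), 1)
    ctime = np.round(np.clip(rng.normal(cov["collection_time_mean"],
                                        cov["collection_time_sd"], size=n), 7.0, 19.0), 2)
    bf_past = (sex == "female") & (rng.random(n) < cov["p_breastfeeding_past"])
    bf_curr = bf_past & (rng.random(n) < cov["p_breastfeeding_current"]
                         / max(cov["p_breastfeeding_past"], 1e-12))

    data = {
        "sex": sex, "age": age, "bmi": bmi, "collection_time": ctime,
        "breastfeeding_past": bf_past.astype(int),
        "breastfeeding_current": bf_curr.astype(int),
    }
    comp_rows = []
    censored_fractions = {}
    for name, mu, sd, lod, loq in config.pfas_compounds:
        conc = np.exp(mu + log_expo + rng.normal(0.0, sd, size=n))
        flags = np.where(conc < lod, "below_lod",
                         np.where(conc < loq, "between_lod_loq", "quantified"))
        values = np.where(flags == "quantified", np.round(conc, 4), np.nan)
        data[f"{name}_value"] = values
        data[f"{name}_flag"] = flags
        comp_rows.append({"compound": name, "lod": lod, "loq": loq})
        censored_fractions[name] = float(np.mean(flags != "quantified"))

    subjects = pd.DataFrame(data, index=pd.Index(subject_ids, name="subject_id"))
    subjects["total_pfas"] = np.nan
    subjects["group"] = "unassigned"
    compounds = pd.DataFrame(comp_rows).set_index("compound")

    truth = GroundTruth(
        censored_fractions=censored_fractions,
        exposure_factors={s: float(e) for s, e in zip(subject_ids, expo)},
    )
    return CohortTable(subjects, compounds), truth


def _injection_layout(sample_ids: list, config: SynthConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Randomized sample order with interleaved QCs and flanking blanks."""
    if config.qc_every < 2:
        raise ValueError("qc_every must be >= 2")
    order_samples = list(rng.permutation(sample_ids))
    rows = []
    n_lead = config.n_blanks // 2
    for b in range(n_lead):
        rows.append((f"B{b + 1:02d}", "blank", ""))
    rows.append(("QC01", "qc", ""))
    qc_count, since_qc = 1, 0
    for sid in order_samples:
        rows.append((sid, "sample", ""))
        since_qc += 1
        if since_qc == config.qc_every:
            qc_count += 1
            rows.append((f"QC{qc_count:02d}", "qc", ""))
            since_qc = 0
    if since_qc:
        qc_count += 1
        rows.append((f"QC{qc_count:02d}", "qc", ""))
    for b in range(n_lead, config.n_blanks):
        rows.append((f"B{b + 1:02d}", "blank", ""))
    if qc_count == 0:
        raise ValueError("layout produced no QC injections")
    inj = pd.DataFrame(rows, columns=["injection_id", "role", "group"])
    inj["order"] = np.arange(1, len(inj) + 1)
    return inj.set_index("injection_id")


def generate_feature_study(config: SynthConfig,
                           cohort: CohortTable) -> tuple[FeatureStudy, GroundTruth]:
    """Simulate the feature-intensity matrix for the extreme-group subjects.

    Requires the cohort to carry ``low``/``high`` group labels for
    2 * n_per_group subjects (run the exposure stage first).  Returns the
    study plus a ground-truth record of planted effects and drift.
    """
    config.validate()
    grouped = cohort.subjects[cohort.subjects["group"].isin(["low", "high"])]
    if len(grouped) != 2 * config.n_per_group:
        raise ValueError(
            f"cohort must carry group labels for {2 * config.n_per_group} subjects, "
            f"found {len(grouped)}")
    rng = _rng(config.seed, 1)

    sample_ids = list(grouped.index)
    inj = _injection_layout(sample_ids, config, rng)
    inj.loc[inj["role"] == "sample", "group"] = (
        grouped.loc[inj.index[inj["role"] == "sample"], "group"].to_numpy())
    n_inj = len(inj)
    orders = inj["order"].to_numpy()
    is_high = ((inj["role"] == "sample") & (inj["group"] == "high")).to_numpy()
    is_sample = (inj["role"] == "sample").to_numpy()
    is_qc = (inj["role"] == "qc").to_numpy()
    is_blank = (inj["role"] == "blank").to_numpy()

    p = config.n_features
    feature_ids = [f"F{j:05d}" for j in range(1, p + 1)]
    # biological log-sd spans ~35-90% CV, consistent with the within-group
    # spread typical of untargeted serum profiling
    base_mu = rng.normal(np.log(1e5), 1.0, size=p)
    base_sigma = rng.uniform(0.3, 0.8, size=p)

    planted_idx = rng.choice(p, size=config.n_planted, replace=False)
    planted_idx.sort()
    if config.planted_effect_sizes:
        reps = int(np.ceil(config.n_planted / len(config.planted_effect_sizes)))
        d_vals = (list(config.planted_effect_sizes) * reps)[:config.n_planted]
        d_vals = np.asarray(d_vals, dtype=float)
    else:
        d_vals = rng.uniform(0.8, 1.2, size=config.n_planted)
    d_by_feature = np.zeros(p)
    d_by_feature[planted_idx] = d_vals

    # per-feature smooth drift, a low-order polynomial in normalized order
    amp_base = np.log1p(config.drift_amplitude)
    drift_info = {}
    tnorm = (orders - 1.0) / max(n_inj - 1, 1)
    basis = np.vstack([tnorm, tnorm ** 2, tnorm ** 3])       # (3, n_inj)
    coeffs = np.zeros((p, 3))
    amps = np.zeros(p)
    if amp_base > 0:
        signs = rng.choice([-1.0, 1.0], size=p)
        if config.drift_shape == "linear":
            coeffs[:, 0] = 1.0
            amps = amp_base * signs
        else:
            raw = rng.uniform(-1.0, 1.0, size=(p, 3))
            span = np.array([np.ptp(c @ basis) for c in raw])
            span[span == 0] = 1.0
            coeffs = raw / span[:, None]                      # unit peak-to-peak
            amps = amp_base * rng.uniform(0.5, 1.0, size=p) * signs
    log_drift = amps[:, None] * (coeffs @ basis)              # (p, n_inj)

    sigma_qc = float(np.sqrt(np.log1p(config.qc_rsd_target ** 2)))
    frac_high = is_high.sum() / max(is_sample.sum(), 1)

    matrix = np.full((p, n_inj), np.nan)
    for j in range(p):
        frng = _rng(config.seed, 1, j)
        row = np.empty(n_inj)
        # biological samples: lognormal around the feature baseline, group shift
        z = frng.normal(0.0, 1.0, size=n_inj)
        logx = base_mu[j] + base_sigma[j] * z
        logx[is_high] += d_by_feature[j] * base_sigma[j]
        # pooled QC: the pooled-sample level with tight technical noise
        pooled = base_mu[j] + base_sigma[j] ** 2 / 2 + frac_high * d_by_feature[j] * base_sigma[j]
        logx[is_qc] = pooled + sigma_qc * frng.normal(0.0, 1.0, size=int(is_qc.sum()))
        logx[is_blank] = (base_mu[j] + np.log(config.blank_level)
                          + 0.3 * frng.normal(0.0, 1.0, size=int(is_blank.sum())))
        row = np.exp(logx + log_drift[j])
        # detection-limit censoring on the observed (drifted) scale
        obs = row[is_sample | is_qc]
        thr = np.quantile(obs, config.detection_quantile) if config.detection_quantile > 0 else 0.0
        row[(is_sample | is_qc) & (row < thr)] = np.nan
        # random dropout on biological samples only
        if config.missing_rate_random > 0:
            drop = frng.random(n_inj) < config.missing_rate_random
            row[drop & is_sample] = np.nan
        row[is_blank & (frng.random(n_inj) > 0.7)] = np.nan
        matrix[j] = row
        drift_info[feature_ids[j]] = {"amp": float(amps[j]),
                                      "coeffs": [float(c) for c in coeffs[j]]}

    intensities = pd.DataFrame(matrix, index=pd.Index(feature_ids, name="feature_id"),
                               columns=inj.index)
    features = pd.DataFrame({
        "mz": np.round(rng.uniform(80, 1200, size=p), 4),
        "rt": np.round(rng.uniform(0.5, 15.0, size=p), 2),
        "platform": "apolar",
        "polarity": "pos",
    }, index=pd.Index(feature_ids, name="feature_id"))

    truth = GroundTruth(
        planted_feature_ids=[feature_ids[j] for j in planted_idx],
        true_d={feature_ids[j]: float(d_by_feature[j]) for j in planted_idx},
        drift=drift_info,
        n_injections=n_inj,
        true_group={s: str(g) for s, g in grouped["group"].items()},
    )
    return FeatureStudy(intensities, inj, features), truth
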