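"""Central data containers and their delimited-text serialization.

A :class:`FeatureStudy` bundles the aligned feature-intensity matrix
(features x injections, NaN = not detected) with injection metadata
(role sample/qc/blank, injection order, exposure group) and feature
metadata.  A :class:`CohortTable` holds one row per subject with censored
per-compound PFAS concentrations, covariates, totals, and group labels.

Everything round-trips through TSV so that intermediate artifacts stay
diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("sample", "qc", "blank")
CENSOR_FLAGS = ("quantified", "between_lod_loq", "below_lod", "missing")
GROUPS = ("low", "high", "unassigned")


@dataclass
class FeatureStudy:
    """Feature-intensity matrix plus injection and feature metadata.

    Attributes
    ----------
    intensities : DataFrame, index = feature ids, columns = injection ids.
        Positive floats; NaN marks a value missing (not detected).
    injections : DataFrame indexed by injection id with columns
        ``role`` in {sample, qc, blank}, ``order`` (unique positive int) and
        ``group`` (low/high/'' for non-samples).
    features : DataFrame indexed by feature id with columns
        ``mz``, ``rt``, ``platform``, ``polarity``.
    """

    intensities: pd.DataFrame
    injections: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.intensities.columns) != list(self.injections.index):
            raise ValueError("intensity columns must match injection metadata index")
        if list(self.intensities.index) != list(self.features.index):
            raise ValueError("intensity rows must match feature metadata index")
        bad = set(self.injections["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown injection roles: {sorted(bad)}")
        order = self.injections["order"]
        if order.duplicated().any():
            raise ValueError("injection orders must be unique")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("intensities must be positive where present")

    # -- convenient id selectors -------------------------------------------
    def ids_by_role(self, role: str) -> list:
        return list(self.injections.index[self.injections["role"] == role])

    @property
    def sample_ids(self) -> list:
        return self.ids_by_role("sample")

    @property
    def qc_ids(self) -> list:
        return self.ids_by_role("qc")

    @property
    def blank_ids(self) -> list:
        return self.ids_by_role("blank")

    def sample_ids_in_group(self, group: str) -> list:
        inj = self.injections
        mask = (inj["role"] == "sample") & (inj["group"] == group)
        return list(inj.index[mask])

    @property
    def groups(self) -> list:
        g = self.injections.loc[self.injections["role"] == "sample", "group"]
        return sorted(set(g) - {""})

    def copy(self) -> "FeatureStudy":
        return FeatureStudy(self.intensities.copy(), self.injections.copy(),
                            self.features.copy())

    def subset_features(self, feature_ids) -> "FeatureStudy":
        feature_ids = list(feature_ids)
        return FeatureStudy(self.intensities.loc[feature_ids],
                            self.injections.copy(),
                            self.features.loc[feature_ids].copy())

    # -- TSV round trip -----------------------------------------------------
    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.intensities.to_csv(directory / "intensities.tsv", sep="\t",
                                index_label="feature_id")
        self.injections.to_csv(directory / "injections.tsv", sep="\t",
                               index_label="injection_id")
        self.features.to_csv(directory / "features.tsv", sep="\t",
                             index_label="feature_id")

    @classmethod
    def read(cls, directory) -> "FeatureStudy":
        directory = Path(directory)
        inten = pd.read_csv(directory / "intensities.tsv", sep="\t",
                            index_col="feature_id")
        inj = pd.read_csv(directory / "injections.tsv", sep="\t",
                          index_col="injection_id",
                          dtype={"role": str, "group": str}, keep_default_na=False,
                          na_values=[])
        inj["order"] = inj["order"].astype(int)
        feats = pd.read_csv(directory / "features.tsv", sep="\t",
                            index_col="feature_id")
        return cls(inten, inj, feats)


@dataclass
class CohortTable:
    """Subjects with censored PFAS measurements and covariates.

    ``subjects`` is indexed by subject id and carries covariates
    (sex, age, bmi, collection_time, breastfeeding flags), one
    ``<compound>_value`` / ``<compound>_flag`` pair per PFAS compound
    (flag in {quantified, between_lod_loq, below_lod, missing}), and, once
    computed, ``total_pfas`` and ``group``.  ``compounds`` is indexed by
    compound name with columns ``lod`` and ``loq`` (ng/mL).
    """

    subjects: pd.DataFrame
    compounds: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.subjects.index.duplicated().any():
            raise ValueError("duplicate subject ids")
        if len(self.compounds):
            bad = self.compounds["lod"] > self.compounds["loq"]
            if bad.any():
                raise ValueError("LOD must not exceed LOQ")

    @property
    def compound_names(self) -> list:
        return list(self.compounds.index)

    def values_flags(self, compound: str) -> tuple[pd.Series, pd.Series]:
        return (self.subjects[f"{compound}_value"],
                self.subjects[f"{compound}_flag"])

    def copy(self) -> "CohortTable":
        return CohortTable(self.subjects.copy(), self.compounds.copy())

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(directory / "cohort.tsv", sep="\t",
                             index_label="subject_id")
        self.compounds.to_csv(directory / "compounds.tsv", sep="\t",
                              index_label="compound")

    @classmethod
    def read(cls, directory) -> "CohortTable":
        directory = Path(directory)
        subj = pd.read_csv(directory / "cohort.tsv", sep="\t",
                           index_col="subject_id", keep_default_na=False,
                           na_values=["nan", ""])
        comp = pd.read_csv(directory / "compounds.tsv", sep="\t",
                           index_col="compound")
        for col in subj.columns:
            if col.endswith("_value") or col in ("age", "bmi", "collection_time",
                                                 "total_pfas", "exposure_factor"):
                subj[col] = pd.to_numeric(subj[col], errors="coerce")
        return cls(subj, comp)
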