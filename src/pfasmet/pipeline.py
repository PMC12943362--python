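"""End-to-end pipeline orchestration.

Runs the stages in order exposure -> qc -> pretreat -> differential ->
biomarker -> enrich on a (by default simulated) study, writing every
stage's outputs plus a manifest (input hashes, sub-seed, package version)
into a run directory.  All randomness flows from the single top-level seed
through named per-stage sub-seeds, so re-running an identical configuration
reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarker import (build_panel, cluster_features, evaluate_panel_svm,
                        rank_features_mccv, spearman_assoc, univariate_roc)
from .containers import CohortTable, FeatureStudy
from .differential import (fit_plsda, permutation_test, rf_classify,
                           rf_importance_cutoff, select_features,
                           univariate_screen)
from .enrichment import PathwayLibrary, ora_fisher
from .exposure import assign_extreme_groups, compare_groups, impute_cohort, total_pfas
from .pretreat import pretreat
from .qc import (FilterThresholds, compute_qc_metrics, detect_sample_outliers,
                 drift_correct, filter_features, mask_outlier_samples)
from .simulate import SynthConfig, generate_cohort, generate_feature_study
from .stats import cohens_d, power_t

log = logging.getLogger("pfasmet")

STAGES = ("simulate", "exposure", "qc", "pretreat", "differential",
          "biomarker", "enrich")


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    fdr: float = 0.05
    fc_limits: tuple = (0.8, 1.2)
    vip_threshold: float = 1.0
    drift_correction: bool = True
    imputation_variant: str = "forest"        # or "median"
    imputer_trees: int = 100
    imputer_max_iter: int = 10
    pqn_reference: str = "qc_median"
    max_components: int = 5
    n_perm_plsda: int = 1000
    rf_trees: int = 500
    selection_rule: str = "vip_and_rf"
    panel_size: int = 5
    top_n: int = 12
    rank_iter: int = 100
    panel_iter: int = 100
    panel_perm: int = 1000
    null_n_iter: int = 20
    roc_boot: int = 500
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([int(self.seed), idx])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fc_limits"] = list(self.fc_limits)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        thresholds = FilterThresholds(**raw.pop("thresholds", {}))
        if "fc_limits" in raw:
            raw["fc_limits"] = tuple(raw["fc_limits"])
        return cls(synth=synth, thresholds=thresholds, **raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, seed: int, extra: dict = None):
    files = sorted(p for p in stage_dir.iterdir() if p.name != "manifest.json")
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "outputs": {p.name: _hash_file(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                        sort_keys=True))


def run_pipeline(config: PipelineConfig, out_dir, *,
                 cohort: CohortTable | None = None,
                 study: FeatureStudy | None = None,
                 library: PathwayLibrary | None = None) -> dict:
    """Execute the full pipeline into `out_dir`; returns in-memory results.

    With no cohort/study supplied, the synthetic generator provides them
    (the ground truth is written alongside).  A stage failure raises with
    the stage name; completed stages keep their artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    results: dict = {}
    stage = "simulate"
    try:
        # -- simulate -------------------------------------------------------
        truth_cohort = truth_study = None
        if cohort is None:
            cohort, truth_cohort = generate_cohort(config.synth)
        sdir = out / "simulate"
        sdir.mkdir(exist_ok=True)
        cohort.write(sdir)
        if truth_cohort is not None:
            truth_cohort.write(sdir / "truth_cohort.json")
        _write_manifest(sdir, stage, config.synth.seed)

        # -- exposure -------------------------------------------------------
        stage = "exposure"
        seed = config.stage_seed(stage)
        cohort, fits = impute_cohort(cohort, seed=seed)
        totals = total_pfas(cohort)
        cohort.subjects["total_pfas"] = totals
        cohort.subjects["group"] = assign_extreme_groups(totals, config.synth.n_per_group)
        comparison = compare_groups(cohort)
        edir = out / "exposure"
        edir.mkdir(exist_ok=True)
        cohort.write(edir)
        (edir / "comparison.json").write_text(json.dumps({
            "chi2": comparison.chi2, "chi2_p": comparison.chi2_p,
            "phi": comparison.phi, "mwu_p": comparison.mwu_p,
            "cliffs_delta": comparison.cliffs_delta,
            "welch_t_p_time": comparison.welch_t_p_time,
            "cohens_d_time": comparison.cohens_d_time}, indent=1))
        _write_manifest(edir, stage, seed,
                        {"imputed_compounds": [f.compound for f in fits if f.imputed]})
        results["cohort"] = cohort
        results["comparison"] = comparison

        if study is None:
            study, truth_study = generate_feature_study(config.synth, cohort)
            study.write(out / "simulate")
            if truth_study is not None:
                truth_study.write(out / "simulate" / "truth_study.json")
        results["truth"] = truth_study

        # -- qc -------------------------------------------------------------
        stage = "qc"
        seed = config.stage_seed(stage)
        if config.drift_correction:
            study, drift_report = drift_correct(study)
            log.info("drift correction: %d corrected, %d rejected, %d passed through",
                     len(drift_report.corrected), len(drift_report.rejected),
                     len(drift_report.too_few_qc))
        else:
            drift_report = None
        metrics = compute_qc_metrics(study)
        study, filter_report = filter_features(study, metrics, config.thresholds)
        outliers = detect_sample_outliers(study)
        study = mask_outlier_samples(study, outliers)
        filter_report.outlier_flags = {s: bool(f) for s, f in outliers.flags.items()}
        filter_report.fences = {g: list(f) for g, f in outliers.fences.items()}
        qdir = out / "qc"
        qdir.mkdir(exist_ok=True)
        study.write(qdir)
        metrics.table.to_csv(qdir / "qc_metrics.tsv", sep="\t", index_label="feature_id")
        filter_report.write(qdir / "filter_report.json")
        if drift_report is not None:
            (qdir / "drift_report.json").write_text(json.dumps(drift_report.as_dict()))
        _write_manifest(qdir, stage, seed, {
            "drift_correction": config.drift_correction,
            "removed_by": filter_report.removed_by,
            "n_retained": len(filter_report.retained)})
        results["study"] = study
        results["filter_report"] = filter_report
        results["qc_metrics"] = metrics

        # -- pretreat -------------------------------------------------------
        stage = "pretreat"
        seed = config.stage_seed(stage)
        if config.imputation_variant == "median":
            filled = study.copy()
            med = filled.intensities[study.sample_ids].median(axis=1)
            for sid in study.sample_ids + study.qc_ids:
                col = filled.intensities[sid]
                filled.intensities[sid] = col.fillna(med)
            pre = pretreat(filled, seed=seed, n_trees=1, max_iter=0,
                           pqn_reference=config.pqn_reference)
            pre.provenance["imputer"] = {"kind": "median"}
        else:
            pre = pretreat(study, seed=seed, n_trees=config.imputer_trees,
                           max_iter=config.imputer_max_iter,
                           pqn_reference=config.pqn_reference)
        pdir = out / "pretreat"
        pdir.mkdir(exist_ok=True)
        pre.data.to_csv(pdir / "pretreated.tsv", sep="\t", index_label="feature_id")
        (pdir / "provenance.json").write_text(json.dumps(pre.provenance, indent=1))
        _write_manifest(pdir, stage, seed)
        results["pretreated"] = pre

        # -- differential ---------------------------------------------------
        stage = "differential"
        seed = config.stage_seed(stage)
        groups = study.injections.loc[study.sample_ids, "group"]
        uni = univariate_screen(study.intensities[study.sample_ids], groups,
                                fdr=config.fdr, fc_limits=config.fc_limits)
        Xp = pre.data[study.sample_ids].T        # samples x features
        y = (groups == "high").astype(int).to_numpy()
        plsda = fit_plsda(Xp, y, max_components=config.max_components, seed=seed)
        plsda.perm_p = permutation_test(Xp, y, plsda.n_components,
                                        n_perm=config.n_perm_plsda, seed=seed)
        rf = rf_classify(Xp, y, n_trees=config.rf_trees, seed=seed)
        cutoff = rf_importance_cutoff(Xp, y, n_trees=config.rf_trees, seed=seed + 1)
        sel = select_features(uni, [plsda], rf, cutoff, rule=config.selection_rule,
                              vip_threshold=config.vip_threshold)
        ddir = out / "differential"
        ddir.mkdir(exist_ok=True)
        table = (uni.rename(columns={"selected": "selected_univariate"})
                 .join(plsda.vip).join(rf.importance).join(sel))
        table.to_csv(ddir / "differential.tsv", sep="\t", index_label="feature_id")
        (ddir / "plsda.json").write_text(json.dumps({
            "n_components": plsda.n_components, "r2": plsda.r2, "q2": plsda.q2,
            "auc": plsda.auc, "perm_p": plsda.perm_p,
            "rf_auc_oob": rf.auc_oob, "rf_cutoff": cutoff}, indent=1))
        _write_manifest(ddir, stage, seed, {"n_selected": int(sel["selected"].sum())})
        results.update({"univariate": uni, "plsda": plsda, "rf": rf,
                        "selection": sel})

        # -- biomarker ------------------------------------------------------
        stage = "biomarker"
        seed = config.stage_seed(stage)
        candidates = list(sel.index[sel["selected"]])
        bdir = out / "biomarker"
        bdir.mkdir(exist_ok=True)
        if len(candidates) >= 2:
            totals_s = cohort.subjects.loc[study.sample_ids, "total_pfas"]
            raw = study.intensities.loc[candidates, study.sample_ids]
            assoc_rows, roc_rows, power_rows = [], [], []
            aucs = {}
            for fid in candidates:
                v = raw.loc[fid].to_numpy(dtype=float)
                ok = np.isfinite(v)
                assoc = spearman_assoc(v[ok], totals_s.to_numpy()[ok], fid)
                assoc_rows.append({"feature_id": fid, "r": assoc.r, "p": assoc.p,
                                   "category": assoc.category})
                xv = pre.data.loc[fid, study.sample_ids].to_numpy(dtype=float)
                roc = univariate_roc(xv, y, n_boot=config.roc_boot, seed=seed,
                                     metabolite=fid)
                aucs[fid] = roc.auc
                roc_rows.append({"feature_id": fid, "auc": roc.auc,
                                 "ci_lo": roc.ci[0], "ci_hi": roc.ci[1], "p": roc.p})
                d = cohens_d(xv[y == 1], xv[y == 0])
                pw = power_t(d, int((y == 1).sum()), int((y == 0).sum()))
                power_rows.append({"feature_id": fid, "cohens_d": d,
                                   "delta": pw.delta, "power": pw.power})
            pd.DataFrame(assoc_rows).to_csv(bdir / "associations.tsv", sep="\t",
                                            index=False)
            pd.DataFrame(roc_rows).to_csv(bdir / "roc.tsv", sep="\t", index=False)
            pd.DataFrame(power_rows).to_csv(bdir / "effect_power.tsv", sep="\t",
                                            index=False)
            k = min(config.panel_size, len(candidates))
            Xc = pre.data.loc[candidates, study.sample_ids].T
            clusters = cluster_features(Xc, k=k)
            freqs = rank_features_mccv(Xc, y, n_iter=config.rank_iter, seed=seed,
                                       top_n=config.top_n)
            panel = build_panel(clusters, freqs,
                                pd.Series(aucs), top_n=config.top_n, panel_size=k)
            evaluation = evaluate_panel_svm(Xc[panel], y, n_iter=config.panel_iter,
                                            n_perm=config.panel_perm, seed=seed,
                                            null_n_iter=config.null_n_iter)
            (bdir / "panel.json").write_text(json.dumps({
                "members": evaluation.members, "auc": evaluation.auc,
                "ci": list(evaluation.ci), "accuracy": evaluation.accuracy,
                "perm_p": evaluation.perm_p,
                "clusters": {f: int(c) for f, c in clusters.items()},
                "frequencies": {f: float(v) for f, v in freqs.items()}}, indent=1))
            results["panel"] = evaluation
        else:
            log.warning("fewer than 2 selected features; biomarker stage skipped")
            (bdir / "panel.json").write_text(json.dumps({"skipped": True}))
        _write_manifest(bdir, stage, seed)
        results["candidates"] = candidates

        # -- enrich ---------------------------------------------------------
        stage = "enrich"
        seed = config.stage_seed(stage)
        if library is not None:
            enr = ora_fisher(candidates, library, with_topology=bool(library.graphs))
            ndir = out / "enrich"
            ndir.mkdir(exist_ok=True)
            pd.DataFrame([dataclasses.asdict(r) for r in enr]).to_csv(
                ndir / "enrichment.tsv", sep="\t", index=False)
            _write_manifest(ndir, stage, seed)
            results["enrichment"] = enr
    except Exception as err:
        completed = [s for s in STAGES if (out / s / "manifest.json").exists()]
        raise RuntimeError(f"pipeline failed at stage '{stage}' "
                           f"(completed: {completed}): {err}") from err
    return results
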