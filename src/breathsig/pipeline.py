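"""End-to-end orchestration: recordings -> QC -> features -> selection -> models.

A single config drives the whole analysis and every stochastic stage takes its
seed from it, so a rerun with the same config reproduces byte-identical
manifests. The manifest (JSON, content-hashed artifacts) records QC outcomes
per sample, the feature-matrix artifacts, the consensus feature set and the
per-maneuver model reports.

The diagnosis models compare one disease group against controls on the held-out
split; the BDR model is restricted to asthma and COPD subjects, combines
consensus VOC features with clinical biomarkers (FeNO, blood eosinophils, total
IgE, FEV1 %predicted), and is evaluated by leave-one-out cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess as pre
from .cohort import label_bdr
from .raw_io import read_recording
from .select_model import (
    consensus_features, evaluate, resample_importance, split_data, tune_and_fit,
)
from xgboost import XGBClassifier
from .select_model import DEFAULT_LEARNER_PARAMS

logger = logging.getLogger(__name__)

BDR_CLINICAL_COVARIATES = ["feno_ppb", "eos_10e9_l", "ige_iu_ml", "fev1_pct_pred"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs; see module docstring for stage semantics."""

    recordings: list[dict]                  # {path, sample_id, subject_id, maneuver}
    cohort_csv: str | Path | None = None
    out_dir: str | Path = "breathsig_out"
    reference_mzs: tuple = pre.PERMASCAL_MZS
    water_adduct_mz: float = pre.WATER_ADDUCT_MZ
    tracer_mzs: tuple = pre.TRACER_MZS
    eic_window: float = 0.05
    water_threshold: float = pre.WATER_THRESHOLD_CPS
    sg_window: int = 7
    sg_order: int = 3
    min_prominence_rel: float = 1e-3
    min_intensity_cps: float = 50.0
    internal_standard_mz: float = feat.INTERNAL_STANDARD_MZ
    diagnosis_pair: tuple[str, str] = ("asthma", "control")  # (case, reference)
    train_fraction: float = 0.7
    n_iter: int = 1000
    subsample_fraction: float = 2 / 3
    top_k: int = 30
    cv_folds: int = 5
    threshold: float = 0.5
    learner_params: dict = field(default_factory=dict)
    param_grid: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        for entry in self.recordings:
            if not Path(entry["path"]).exists():
                raise PipelineError(f"recording not found: {entry['path']}")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise PipelineError(f"cohort table not found: {self.cohort_csv}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def preprocess_one(path, cfg: PipelineConfig):
    """QC-gate one recording and, if it passes, return its composite spectrum."""
    rec = read_recording(path)
    rec, calib = pre.recalibrate(rec, cfg.reference_mzs)
    water = pre.extract_eic(rec, cfg.water_adduct_mz, cfg.eic_window)
    tracers = [pre.extract_eic(rec, m, cfg.eic_window) for m in cfg.tracer_mzs]
    phase = pre.segment_breaths(water, tracers, cfg.water_threshold)
    report = pre.qc_recording(rec, phase, calib)
    composite = None
    if report.overall_pass and len(phase.selected_indices) > 0:
        composite = feat.composite_spectrum(
            rec, phase.selected_indices, cfg.sg_window, cfg.sg_order)
    return rec, composite, report


def build_feature_matrix(cfg: PipelineConfig, cohort: pd.DataFrame | None
                         ) -> tuple[feat.FeatureMatrix, dict]:
    """Run QC + featurization over all configured recordings."""
    peaklists, meta_rows, qc_summary = {}, [], {}
    for entry in cfg.recordings:
        sid = entry["sample_id"]
        try:
            _, composite, report = preprocess_one(entry["path"], cfg)
        except (pre.CalibrationError, pre.RangeError) as exc:
            raise PipelineError(f"stage preprocess failed for sample {sid}: {exc}") from exc
        qc_summary[sid] = {"pass": bool(report.overall_pass and composite is not None),
                           **report.details}
        if composite is None or not report.overall_pass:
            logger.info("sample %s excluded by QC: %s", sid, report.details)
            continue
        peaklists[sid] = feat.detect_peaks(
            composite, cfg.min_prominence_rel, cfg.min_intensity_cps)
        row = {"subject": entry.get("subject_id", sid),
               "maneuver": entry.get("maneuver", "tidal")}
        if cohort is not None and row["subject"] in cohort.index:
            crow = cohort.loc[row["subject"]]
            row["group"] = crow.get("group")
            try:
                row["bdr"] = label_bdr(crow)
            except Exception:
                row["bdr"] = None
        meta_rows.append({"sample_id": sid, **row})
    if not peaklists:
        raise PipelineError("no samples passed QC")
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = feat.align_features(peaklists, sample_meta)
    matrix = feat.normalize_features(matrix, cfg.internal_standard_mz)
    return matrix, qc_summary


def _model_maneuver(matrix: feat.FeatureMatrix, endpoint_col: str, positive: str,
                    cfg: PipelineConfig) -> dict:
    """Per-maneuver selection + tuned fit + held-out evaluation."""
    model_matrix = feat.filter_model_features(matrix, cfg.reference_mzs)
    meta = model_matrix.sample_meta
    y_all = (meta[endpoint_col] == positive).astype(int)
    strata = meta[endpoint_col].astype(str) + "|" + meta["maneuver"].astype(str)
    train_ids, test_ids = split_data(model_matrix.values.index, strata,
                                     cfg.train_fraction, cfg.seed)
    imps = {}
    for maneuver in ("forced", "tidal"):
        rows = [s for s in train_ids if meta.loc[s, "maneuver"] == maneuver]
        imps[maneuver] = resample_importance(
            model_matrix.values.loc[rows], y_all.loc[rows],
            n_iter=cfg.n_iter, frac=cfg.subsample_fraction,
            learner_params=cfg.learner_params, seed=cfg.seed)
    selection = consensus_features(imps["forced"], imps["tidal"], cfg.top_k,
                                   cfg.n_iter, cfg.subsample_fraction, [cfg.seed])
    if not selection.consensus_features:
        raise PipelineError("consensus feature set is empty")
    reports = {}
    for maneuver in ("forced", "tidal"):
        tr = [s for s in train_ids if meta.loc[s, "maneuver"] == maneuver]
        te = [s for s in test_ids if meta.loc[s, "maneuver"] == maneuver]
        Xtr = model_matrix.values.loc[tr, selection.consensus_features]
        Xte = model_matrix.values.loc[te, selection.consensus_features]
        model = tune_and_fit(Xtr, y_all.loc[tr], cfg.cv_folds, cfg.param_grid, cfg.seed)
        rep = evaluate(model, Xte, y_all.loc[te], cfg.threshold, "holdout",
                       endpoint="diagnosis", n_train=len(tr))
        reports[maneuver] = rep.as_dict()
    return {"consensus_features": [float(f) for f in selection.consensus_features],
            "ranked_lists": {m: [float(f) for f in l]
                             for m, l in selection.ranked_lists.items()},
            "reports": reports}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full diagnosis pipeline; write artifacts + manifest; return manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = None
    if cfg.cohort_csv is not None:
        cohort = pd.read_csv(cfg.cohort_csv, index_col="subject_id")

    matrix, qc_summary = build_feature_matrix(cfg, cohort)
    csv_path, json_path = matrix.write(out / "feature_matrix")

    case, ref = cfg.diagnosis_pair
    keep = matrix.sample_meta["group"].isin([case, ref])
    diag_matrix = feat.FeatureMatrix(
        values=matrix.values.loc[keep.index[keep]],
        prevalence=matrix.prevalence,
        sample_meta=matrix.sample_meta.loc[keep.index[keep]],
        normalized=matrix.normalized)
    modeling = _model_maneuver(diag_matrix, "group", case, cfg)

    manifest = {
        "config": {
            "seed": cfg.seed, "n_iter": cfg.n_iter, "top_k": cfg.top_k,
            "train_fraction": cfg.train_fraction, "diagnosis_pair": list(cfg.diagnosis_pair),
            "water_threshold": cfg.water_threshold,
        },
        "qc": {"n_input": len(cfg.recordings),
               "n_passed": sum(1 for v in qc_summary.values() if v["pass"]),
               "per_sample": qc_summary},
        "artifacts": {
            "feature_matrix_csv": {"path": csv_path.name, "sha256": _sha256(csv_path)},
            "feature_matrix_json": {"path": json_path.name, "sha256": _sha256(json_path)},
        },
        "selection": {"consensus_features": modeling["consensus_features"],
                      "ranked_lists": modeling["ranked_lists"]},
        "models": modeling["reports"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_bdr_pipeline(cohort: pd.DataFrame, matrices: dict[str, feat.FeatureMatrix],
                     n_iter: int = 1000, frac: float = 2 / 3, top_k: int = 30,
                     learner_params: dict | None = None, seed: int = 0,
                     clinical_covariates=BDR_CLINICAL_COVARIATES,
                     threshold: float = 0.5) -> dict:
    """BDR endpoint: asthma + COPD subjects only, LOO-evaluated per maneuver.

    Consensus VOC features (stability selection across both maneuvers) are
    concatenated with the clinical biomarkers before modeling. Controls are
    excluded up front; the positive class is a positive bronchodilator test.
    """
    patients = cohort[cohort["group"].isin(["asthma", "copd"])].copy()
    if patients.empty:
        raise PipelineError("no asthma/COPD subjects with BDR labels")
    y = pd.Series([1 if label_bdr(row) == "positive" else 0
                   for _, row in patients.iterrows()], index=patients.index)
    if y.nunique() < 2:
        raise PipelineError("BDR labels are single-class; nothing to model")

    imps = {}
    for maneuver in ("forced", "tidal"):
        m = feat.filter_model_features(matrices[maneuver])
        X = m.values.loc[patients.index]
        imps[maneuver] = resample_importance(
            X, y, n_iter=n_iter, frac=frac, learner_params=learner_params, seed=seed)
    selection = consensus_features(imps["forced"], imps["tidal"], top_k,
                                   n_iter, frac, [seed])

    params = {**DEFAULT_LEARNER_PARAMS, **(learner_params or {}), "random_state": seed}
    reports = {}
    for maneuver in ("forced", "tidal"):
        m = feat.filter_model_features(matrices[maneuver])
        X = m.values.loc[patients.index, selection.consensus_features]
        X = pd.concat([X, patients[clinical_covariates]], axis=1)
        rep = evaluate(XGBClassifier(**params), X, y, threshold, "loo", endpoint="bdr")
        reports[maneuver] = rep
    return {"selection": selection, "reports": reports,
            "n_subjects": int(len(patients)), "n_positive": int(y.sum())}
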