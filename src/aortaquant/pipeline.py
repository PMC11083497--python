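"""End-to-end orchestration: volume -> segmentation -> landmarks -> centerline
-> diameters -> dissection -> report, plus cohort-level evaluation.

Stages are isolated: a failure in one stage is recorded in the report's
``failures`` list (naming the stage) and the partial results of earlier
stages are retained. A fixed seed makes the whole run deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigurationError, InputError
from .diametry import max_section_diameters
from .dissection import DissectionClassifier, predict_dissection, straighten
from .evalstats import (AgreementStats, DiagnosticCounts, PairedMeasurements,
                        agreement_stats, diagnostic_metrics)
from .geometry import extract_centerline, partition_sections
from .landmarks import LandmarkAgents, detect_landmarks, landmarks_from_json, oracle_landmarks
from .phantom import GroundTruth
from .segmentation import TrainedSegmenter, classical_segment, segment
from .volume import Mask, Volume, resample_mask_isotropic

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_cohort"]

log = logging.getLogger("aortaquant")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    segmenter: str = "classical"            # "classical" | "unet"
    segmenter_checkpoint: str | None = None
    contrast: bool = True                   # classical segmenter intensity regime
    noise_sd_hu: float = 10.0
    cutoff: float = 0.5
    landmark_provider: str = "oracle"       # "oracle" | "agents" | "json"
    landmark_checkpoints: list[str] = field(default_factory=list)
    landmarks_json: str | None = None
    mask_resample_mm: float = 2.0           # geometry/diametry working resolution
    centerline_step_mm: float = 2.0
    edge_exclusion_mm: float = 5.0
    inplane_mm: float = 0.5
    n_rays: int = 90
    window_mm: float = 80.0
    dissection_model: str | None = None
    dissection_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.segmenter not in ("classical", "unet"):
            raise ConfigurationError(f"unknown segmenter {self.segmenter!r}")
        if self.landmark_provider not in ("oracle", "agents", "json"):
            raise ConfigurationError(
                f"unknown landmark provider {self.landmark_provider!r}")
        if self.segmenter == "unet" and not self.segmenter_checkpoint:
            raise ConfigurationError("unet segmenter needs a checkpoint")
        for p in [self.segmenter_checkpoint, self.landmarks_json,
                  self.dissection_model, *self.landmark_checkpoints]:
            if p and not Path(p).exists():
                raise ConfigurationError(f"referenced file missing: {p}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> dict:
    return {"config": asdict(cfg), "config_hash": cfg.config_hash(),
            "seed": cfg.seed, "version": __version__}


def run_pipeline(volume: Volume | str | Path, cfg: PipelineConfig,
                 ground_truth: GroundTruth | str | Path | None = None) -> dict:
    """Run the full quantification pipeline on one volume.

    ``ground_truth`` is required by the oracle landmark provider (phantom
    runs) and ignored otherwise. Returns a JSON-serializable report.
    """
    cfg.validate()
    report: dict = {"provenance": _provenance(cfg), "failures": [],
                    "landmarks": None, "diameters": None, "dissection": None}
    timings: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as e:  # stage isolation: any failure is recorded
                log.warning("stage %s failed: %s", name, e)
                report["failures"].append({"stage": name, "error": str(e)})
                out = None
            timings[name] = round(time.perf_counter() - t0, 3)
            return out
        return deco

    if isinstance(volume, (str, Path)):
        vol = stage("load")(lambda: Volume.load_nifti(volume))
        if vol is None:
            report["timings"] = timings
            return report
    else:
        vol = volume

    if isinstance(ground_truth, (str, Path)):
        ground_truth = GroundTruth.from_json(ground_truth)

    def _segment():
        if cfg.segmenter == "unet":
            model = TrainedSegmenter.load(cfg.segmenter_checkpoint)
            _, mask = segment(model, vol, cfg.cutoff)
            return mask
        mask = classical_segment(vol, contrast=cfg.contrast,
                                 noise_sd_hu=cfg.noise_sd_hu)
        if cfg.mask_resample_mm and cfg.mask_resample_mm != float(mask.spacing_mm[0]):
            mask = resample_mask_isotropic(mask, cfg.mask_resample_mm)
        return mask

    mask = stage("segmentation")(_segment)

    def _landmarks():
        if cfg.landmark_provider == "oracle":
            if ground_truth is None:
                raise InputError("oracle landmark provider needs ground truth")
            return oracle_landmarks(ground_truth)
        if cfg.landmark_provider == "json":
            if not cfg.landmarks_json:
                raise InputError("json landmark provider needs landmarks_json")
            return landmarks_from_json(cfg.landmarks_json)
        agents = [LandmarkAgents.load(p) for p in cfg.landmark_checkpoints]
        return detect_landmarks(agents, vol, seed=cfg.seed)

    lms = stage("landmarks")(_landmarks)
    if lms is not None:
        report["landmarks"] = {k: [float(x) for x in v]
                               for k, v in lms.items() if not k.startswith("_")}

    centerline = None
    if mask is not None and lms is not None:
        def _centerline():
            c = extract_centerline(mask, lms["aortic_root"], lms["celiac"],
                                   step_mm=cfg.centerline_step_mm)
            return partition_sections(c, lms)
        centerline = stage("centerline")(_centerline)

    if mask is not None and centerline is not None:
        def _diameters():
            rep = max_section_diameters(mask, centerline,
                                        edge_exclusion_mm=cfg.edge_exclusion_mm,
                                        inplane_mm=cfg.inplane_mm,
                                        n_rays=cfg.n_rays, window_mm=cfg.window_mm)
            return {"sections": rep.sections,
                    "profile": [[float(a), float(b)] for a, b in rep.profile],
                    "gaps": rep.gaps}
        report["diameters"] = stage("diameters")(_diameters)

    if cfg.dissection_model and mask is not None and centerline is not None:
        def _dissect():
            clf = DissectionClassifier.load(cfg.dissection_model)
            sv = straighten(vol, mask, centerline, window_mm=cfg.window_mm)
            res = predict_dissection(clf, sv, threshold=cfg.dissection_threshold)
            return {"patient_probability": res.patient_probability,
                    "decision": bool(res.decision),
                    "threshold": res.threshold, "top_k": res.top_k,
                    "indeterminate": bool(res.indeterminate),
                    "slice_probabilities": [round(float(p), 4)
                                            for p in res.slice_probabilities]}
        report["dissection"] = stage("dissection")(_dissect)

    report["timings"] = timings
    return report


def evaluate_cohort(cases: list[dict], cfg: PipelineConfig) -> dict:
    """Run the pipeline per case and compare against reference measurements.

    Each case dict needs ``volume`` (Volume or path) and ``ground_truth``
    (GroundTruth or path). Reference diameters are the analytic per-section
    maxima; agreement statistics are computed overall and per section, and
    diagnostic metrics for dissection detection when a classifier is
    configured. Failed cases are excluded and counted.
    """
    rows = []
    excluded = []
    for i, case in enumerate(cases):
        gt = case["ground_truth"]
        if isinstance(gt, (str, Path)):
            gt = GroundTruth.from_json(gt)
        rep = run_pipeline(case["volume"], cfg, ground_truth=gt)
        if rep["diameters"] is None or not rep["diameters"]["sections"]:
            excluded.append({"index": i, "failures": rep["failures"]})
            continue
        case_rows = []
        for sec, vals in rep["diameters"]["sections"].items():
            truth_d, _ = gt.section_max_diameter(sec)
            rows.append({"case": i, "section": sec,
                         "auto_mm": vals["max_avg_diameter_mm"],
                         "reference_mm": truth_d,
                         "dissection_truth": bool(gt.dissection_label)})
            case_rows.append(len(rows) - 1)
        if rep["dissection"] is not None:
            for j in case_rows:
                rows[j]["dissection_pred"] = bool(rep["dissection"]["decision"])

    out: dict = {"n_cases": len(cases), "n_excluded": len(excluded),
                 "excluded": excluded, "rows": rows}
    if len(rows) >= 3:
        auto = np.array([r["auto_mm"] for r in rows])
        ref = np.array([r["reference_mm"] for r in rows])
        out["agreement_overall"] = asdict(
            agreement_stats(PairedMeasurements(auto, ref)))
        for sec in ("ascending", "descending"):
            sel = [r for r in rows if r["section"] == sec]
            if len(sel) >= 3:
                out[f"agreement_{sec}"] = asdict(agreement_stats(
                    PairedMeasurements([r["auto_mm"] for r in sel],
                                       [r["reference_mm"] for r in sel])))
    preds = {r["case"]: r["dissection_pred"] for r in rows if "dissection_pred" in r}
    if preds:
        truths = {r["case"]: r["dissection_truth"] for r in rows}
        tp = sum(1 for c, p in preds.items() if p and truths[c])
        fp = sum(1 for c, p in preds.items() if p and not truths[c])
        tn = sum(1 for c, p in preds.items() if not p and not truths[c])
        fn = sum(1 for c, p in preds.items() if not p and truths[c])
        m = diagnostic_metrics(DiagnosticCounts(tp, fp, tn, fn))
        out["dissection_detection"] = {
            "counts": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
            "sensitivity": m.sensitivity, "sensitivity_ci": m.sensitivity_ci,
            "specificity": m.specificity, "specificity_ci": m.specificity_ci,
            "accuracy": m.accuracy, "accuracy_ci": m.accuracy_ci}
    return out
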