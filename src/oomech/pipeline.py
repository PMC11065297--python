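"""End-to-end orchestration: simulate -> track -> fit -> classify -> safety.

:func:`run_pipeline` ties the stages into one reproducible run.  Every
source of randomness derives from the config seed, a manifest records
the config hash, per-stage row counts and every excluded oocyte with its
reason, and rerunning with the same config reproduces the outputs
bit-for-bit.  Tracking or fitting failures become logged exclusions (the
poor-video-quality pathway), never crashes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .model import fit_zener, FitDegenerateError
from .simulate import (SimulationConfig, generate_cohort, generate_curve,
                       render_frame_stack, generate_pressure_trace)
from .tracking import (extract_curve, NoMotionError, DetectionError,
                       TrackingLossError)
from .classify import (assemble_features, split_by_patient,
                       forward_select_and_train, evaluate)
from .safety import safety_report

log = logging.getLogger("oomech")

__all__ = ["PipelineConfig", "run_pipeline", "fit_measured_oocytes",
           "simulate_curves"]


@dataclass
class PipelineConfig:
    """Flat configuration for a full synthetic run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "pipeline_out"
    feature_set: str = "mechanical"
    fertilized_only: bool = False
    train_fraction: float = 0.70
    render_videos: bool = False   # track depths from rendered frames
    n_rendered: int = 10          # cap when render_videos is on
    continuity_correction: bool = False

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["oocytes_per_patient"] = list(np.atleast_1d(
            d["sim"]["oocytes_per_patient"]).tolist())
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:16]


def simulate_curves(cohort: pd.DataFrame, cfg: SimulationConfig) -> dict:
    """One noisy creep curve per non-excluded measured oocyte, seeded per
    oocyte from the config seed."""
    from .model import ZenerParams
    F0 = cfg.force_newtons
    ss = np.random.SeedSequence([cfg.seed, 1])
    measured = cohort[(cohort["arm"] == "measured") & ~cohort["excluded"]]
    seeds = ss.generate_state(len(measured))
    curves = {}
    for (_, row), s in zip(measured.iterrows(), seeds):
        p = ZenerParams(k0=row["true_k0"], k1=row["true_k1"],
                        eta0=row["true_eta0"], eta1=row["true_eta1"])
        curves[row["oocyte_id"]] = generate_curve(
            p, F0, cfg.frame_rate, cfg.window, cfg.noise_sd_um, seed=int(s) % (2**31))
    return curves


def fit_measured_oocytes(curves: dict, F0: float) -> tuple[pd.DataFrame, list]:
    """Fit every curve; degenerate or failed fits become exclusions."""
    rows, exclusions = [], []
    for oid, curve in curves.items():
        try:
            p = fit_zener(curve, F0)
        except FitDegenerateError as e:
            exclusions.append({"oocyte_id": oid, "stage": "fit", "reason": str(e)})
            continue
        rows.append({"oocyte_id": oid, **p.as_dict()})
    return pd.DataFrame(rows), exclusions


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic pipeline and write all artifacts.

    Returns the run manifest (also written to ``manifest.json``):
    config hash, seeds, per-stage counts, every exclusion with reason,
    and the paths of the written outputs.  The bookkeeping identity
    measured = fitted + excluded holds at every stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    manifest: dict = {"config": config.as_dict(),
                      "config_hash": config.config_hash(),
                      "seed": cfg.seed, "stages": {}, "exclusions": [],
                      "outputs": {}}

    # --- simulate ---------------------------------------------------
    cohort = generate_cohort(cfg)
    oio.write_cohort(cohort, out / "cohort.csv")
    trace = generate_pressure_trace(cfg.suction_psi)
    oio.write_pressure(trace, out / "pressure.csv")
    manifest["outputs"]["cohort"] = "cohort.csv"
    n_measured = int((cohort["arm"] == "measured").sum())
    video_excluded = cohort[cohort["excluded"]]
    for oid in video_excluded["oocyte_id"]:
        manifest["exclusions"].append({"oocyte_id": oid, "stage": "video",
                                       "reason": "poor video quality"})
    manifest["stages"]["simulate"] = {
        "patients": int(cohort["patient_id"].nunique()),
        "oocytes": len(cohort), "measured": n_measured,
        "control": int((cohort["arm"] == "control").sum()),
        "video_excluded": len(video_excluded)}

    # --- curves (direct, or via render + track) ---------------------
    curves = simulate_curves(cohort, cfg)
    if config.render_videos:
        ss = np.random.SeedSequence([cfg.seed, 2])
        chosen = list(curves)[:config.n_rendered]
        seeds = ss.generate_state(len(chosen))
        tracked = {}
        for oid, s in zip(chosen, seeds):
            stack, _ = render_frame_stack(curves[oid], seed=int(s) % (2**31))
            try:
                tracked[oid] = extract_curve(
                    stack, known_inner_diameter_um=cfg.pipette_inner_diameter_um)
            except (NoMotionError, DetectionError, TrackingLossError) as e:
                manifest["exclusions"].append(
                    {"oocyte_id": oid, "stage": "track", "reason": str(e)})
        curves = {**{k: v for k, v in curves.items() if k not in chosen}, **tracked}
        manifest["stages"]["track"] = {"rendered": len(chosen),
                                       "tracked": len(tracked)}
    oio.write_curves(curves, out / "curves.csv")
    manifest["outputs"]["curves"] = "curves.csv"

    # --- fit --------------------------------------------------------
    fits, fit_excl = fit_measured_oocytes(curves, cfg.force_newtons)
    manifest["exclusions"].extend(fit_excl)
    oio.write_fits(fits, out / "fits.csv")
    manifest["outputs"]["fits"] = "fits.csv"
    manifest["stages"]["fit"] = {
        "fitted": len(fits),
        "converged": int(fits["converged"].sum()) if len(fits) else 0,
        "excluded": len(fit_excl)}

    # --- classify ---------------------------------------------------
    table = assemble_features(cohort, fits, config.feature_set,
                              config.fertilized_only)
    split = split_by_patient(table, config.train_fraction, seed=cfg.seed)
    clf = forward_select_and_train(table, split, seed=cfg.seed)
    metrics = evaluate(clf, split)
    report = {"cv": clf.cv_report, "split": {
        "train_patients": sorted(split.train_patients),
        "test_patients": sorted(split.test_patients),
        "n_train": len(split.train_index), "n_test": len(split.test_index)},
        "test_metrics": metrics.as_dict()}
    (out / "classifier.json").write_text(json.dumps(report, indent=1))
    manifest["outputs"]["classifier"] = "classifier.json"
    manifest["stages"]["classify"] = {
        "rows": len(table.y), "selected_features": clf.features,
        "test_acc_pct": metrics.acc}

    # --- safety -----------------------------------------------------
    rep = safety_report(cohort, continuity_correction=config.continuity_correction)
    rep.to_csv(out / "safety.csv", index=False)
    manifest["outputs"]["safety"] = "safety.csv"
    manifest["stages"]["safety"] = {"tests": len(rep)}

    # bookkeeping: measured = fitted + excluded (video + track + fit)
    manifest["stages"]["bookkeeping"] = {
        "measured": n_measured,
        "fitted": len(fits),
        "excluded": len(manifest["exclusions"]),
        "reconciles": n_measured == len(fits) + len(manifest["exclusions"])}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
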