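"""End-to-end orchestration: simulate -> extract -> features -> compare -> predict.

Each stage reads its predecessor's files from the run directory, so any
stage can be re-run in isolation.  QC-failed subjects are excluded from all
downstream stages with a logged reason (mirroring clinical exclusion of,
e.g., Biot's respiration), and every run writes its resolved configuration
and a manifest (seed, config hash, subject counts, exclusions) beside the
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import breaths as br
from . import compare as cmp
from . import metrics as rvm
from . import predict as pr
from . import signal as sig
from . import simulate as simu
from .config import config_hash, resolve_config, save_config
from .errors import RespvarError, StageError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _stage_simulate(config: dict, run_dir: Path) -> Path:
    c = config["simulate"]
    spec = simu.CohortSpec(
        n_patients=c["n_patients"],
        n_controls=c["n_controls"],
        seed=config["seed"],
        fs=c["fs"],
        render_noise_sd=c["render_noise_sd"],
        drift_rate=c["drift_rate"],
        window_s=config["breaths"]["window_s"],
    )
    cohort = simu.simulate_cohort(spec)
    n_biot = int(c.get("inject_biot", 0))
    if n_biot:
        # re-render the first n_biot patients with Biot's respiration so the
        # QC stage has something to exclude
        rng = np.random.default_rng(config["seed"] + 1)
        biot_spec = dataclasses.replace(
            spec.breath_spec_by_group["patient"], pattern="biot",
            duration=config["breaths"]["window_s"] + 30.0,
        )
        for j in range(min(n_biot, spec.n_patients)):
            rec, gt = cohort[j]
            bt = simu.simulate_breath_sequence(biot_spec, seed=int(rng.integers(2**31)))
            rec = simu.render_acceleration(
                bt, fs=c["fs"], noise_sd=c["render_noise_sd"],
                drift_rate=c["drift_rate"], seed=int(rng.integers(2**31)),
                subject_id=gt.subject.subject_id,
            )
            cohort[j] = (rec, simu.GroundTruth(bt, gt.subject, gt.features))
    rec_dir = run_dir / "recordings"
    simu.write_cohort(cohort, rec_dir)
    return rec_dir


def _stage_extract_features(config: dict, run_dir: Path, rec_dir: Path) -> dict:
    subjects = pd.read_csv(rec_dir / "subjects.csv", index_col="subject_id")
    sconf, qconf, bconf = config["signal"], config["qc"], config["breaths"]
    features = {}
    exclusions = []
    proc_dir = run_dir / "processed"
    proc_dir.mkdir(parents=True, exist_ok=True)
    for sid in subjects.index:
        path = rec_dir / f"{sid}.csv"
        try:
            raw = sig.read_recording(path, subject_id=sid)
            conditioned = sig.preprocess(
                raw, band=tuple(sconf["band"]),
                waveform_band=tuple(sconf["waveform_band"]), order=sconf["order"],
                ma_window=sconf["ma_window"], drift_window=sconf["drift_window"],
            )
            qc = sig.quality_check(
                conditioned,
                apnea_amp_frac=qconf["apnea_amp_frac"],
                apnea_frac_threshold=qconf["apnea_frac_threshold"],
                min_duration=qconf["min_duration"],
                snr_db_min=qconf["snr_db_min"],
            )
            (proc_dir / f"{sid}.qc.json").write_text(
                json.dumps(qc.to_dict(), sort_keys=True)
            )
            if not qc.usable:
                exclusions.append({"subject_id": sid, "reason": ",".join(sorted(qc.flags))})
                logger.info("excluding %s: %s", sid, sorted(qc.flags))
                continue
            sig.write_signal(conditioned, proc_dir / f"{sid}.resp.csv")
            bt = br.extract_breaths(
                conditioned,
                min_breath_s=bconf["min_breath_s"],
                min_prominence_frac=bconf["min_prominence_frac"],
                polarity=bconf["polarity"],
            )
            bt = br.window_select(bt, duration=bconf["window_s"])
            br.write_breath_table(bt, proc_dir / f"{sid}.breaths.csv")
            profile = rvm.compute_rv_profile(bt, window_s=bconf["window_s"])
            features[sid] = profile.values
        except RespvarError as exc:
            exclusions.append({"subject_id": sid, "reason": f"{type(exc).__name__}: {exc}"})
            logger.info("excluding %s: %s", sid, exc)
    if not features:
        raise StageError("features: no usable subjects")
    feat = pd.DataFrame.from_dict(features, orient="index")[rvm.feature_names()]
    feat.index.name = "subject_id"
    feat.to_csv(run_dir / "features.csv", float_format="%.10g")
    return {"subjects": subjects, "features": feat, "exclusions": exclusions}


def _stage_compare(config: dict, run_dir: Path, feat: pd.DataFrame, subjects: pd.DataFrame):
    c = config["compare"]
    result = cmp.compare_groups(
        feat, subjects, B=c["B"], seed=config["seed"], alpha=c["alpha"],
        adjust=c["adjust"],
    )
    out = result.table.copy()
    out.to_csv(run_dir / "comparison.csv", float_format="%.10g")
    (run_dir / "comparison.json").write_text(
        json.dumps(result.to_json_dict(), sort_keys=True)
    )
    return result


def _stage_predict(config: dict, run_dir: Path, feat: pd.DataFrame, subjects: pd.DataFrame):
    ml = config["predict"].get("ml") or {}
    seed = config["seed"]
    reports = {}
    X, y = pr.build_matrix(feat, subjects, "crsr")
    reg = pr.train_crsr_models(X, y, config=ml, seed=seed)
    reports["crsr"] = {
        "metrics": reg.metrics,
        "top_features": reg.importances,
    }
    Xo, yo = pr.build_matrix(feat, subjects, "outcome")
    clf = pr.train_outcome_models(Xo, yo, config=ml, seed=seed)
    reports["outcome"] = {
        "metrics": clf.metrics,
        "selected_features": clf.selected_features,
        "split": clf.split,
    }
    (run_dir / "model_reports.json").write_text(json.dumps(reports, sort_keys=True))
    models_dir = run_dir / "models"
    models_dir.mkdir(exist_ok=True)
    pr.save_bundle(
        pr.make_bundle(reg.models["random_forest"], reg.feature_names, "crsr"),
        models_dir / "crsr_rf.bundle",
    )
    rf_out = clf.models["rf_direct"]
    pr.save_bundle(
        pr.make_bundle(rf_out, clf.feature_names, "outcome"),
        models_dir / "outcome_rf.bundle",
    )
    return reports


def run_pipeline(config: dict | None = None, out_dir="run", recordings_dir=None) -> Path:
    """Execute the requested stages; returns the run directory.

    With no ``recordings_dir`` the simulate block generates the cohort.
    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained.
    """
    config = resolve_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, run_dir / "config.yaml")

    stage = "simulate"
    try:
        if recordings_dir is None:
            rec_dir = _stage_simulate(config, run_dir)
        else:
            rec_dir = Path(recordings_dir)
        stage = "features"
        res = _stage_extract_features(config, run_dir, rec_dir)
        stage = "compare"
        _stage_compare(config, run_dir, res["features"], res["subjects"])
        stage = "predict"
        if config["predict"].get("enabled", True):
            _stage_predict(config, run_dir, res["features"], res["subjects"])
    except StageError:
        raise
    except RespvarError as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "respvar_version": __version__,
        "seed": config["seed"],
        "config_sha256": config_hash(config),
        "n_attempted": int(pd.read_csv(rec_dir / "subjects.csv").shape[0]),
        "n_analyzed": int(res["features"].shape[0]),
        "exclusions": res["exclusions"],
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return run_dir
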