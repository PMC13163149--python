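"""Run configuration: one nested mapping drives the whole pipeline.

The resolved configuration (defaults merged with the user file) is written
beside every run's outputs, and round-trips losslessly through YAML.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_patients": 44,
        "n_controls": 44,
        "fs": 10.0,
        "render_noise_sd": 0.05,
        "drift_rate": 0.002,
        "inject_biot": 0,  # patients rendered with Biot's respiration (QC exercise)
    },
    "signal": {
        "band": [0.1, 0.7],
        "waveform_band": [0.05, 1.5],
        "order": 4,
        "ma_window": 0.5,
        "drift_window": 20.0,
    },
    "qc": {
        "apnea_amp_frac": 0.25,
        "apnea_frac_threshold": 0.2,
        "min_duration": 300.0,
        "snr_db_min": 3.0,
    },
    "breaths": {
        "min_breath_s": 1.5,
        "min_prominence_frac": 0.3,
        "polarity": "auto",
        "window_s": 300.0,
    },
    "compare": {"B": 1000, "alpha": 0.05, "adjust": True},
    "predict": {"enabled": True, "ml": {}},
}


def merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def resolve_config(user: dict | None = None) -> dict:
    return merge(DEFAULT_CONFIG, user)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return resolve_config(user)


def save_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()
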