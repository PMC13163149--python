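"""Synthetic respiratory cohorts with known ground truth.

No public accelerometry cohort exists for this analysis, so this module is
a first-class generator: it produces ground-truth breath sequences, renders
them as triaxial accelerometer recordings, and attaches covariates, CRS-R
scores and binary clinical outcomes with a known statistical structure, so
every downstream stage (detection, metrics, adjustment, testing, prediction)
can be validated against truth.

Generative model
----------------
Breath timing follows a stationary Gaussian AR(1) process per parameter:
the latent z-series has lag-1 autocorrelation ``ar1_rho`` and unit marginal
variance, and Ti/Te/amplitude are ``mean + sd * z`` floored at 0.3 s
(times) or a small positive value (amplitude).  This is the simplest process
with independently tunable mean, SD and breath-to-breath autocorrelation.
Each breath is rendered as a raised-cosine rise over Ti and fall over Te,
projected onto the three sensor axes by a fixed unit orientation vector,
plus per-axis gravity offset, white noise, and linear drift.

Pathological patterns: ``biot`` alternates clusters of 3-5 normal breaths
with 10-30 s apnoeic pauses (used to exercise quality control);
``cheyne_stokes`` waxes and wanes amplitude on a ~60 s cycle with apnoeas at
the nadir; ``ataxic`` triples the timing/amplitude SDs and inserts irregular
short pauses.

Clinical links (invented plumbing, with the patient-vs-control direction of
the group difference fixed to elevated I/E-ratio SD2 in patients): CRS-R =
clamp(round(linear link on true RV features + Gaussian noise), 0, 23);
improvement is Bernoulli through a logistic link on the same features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as rvmetrics
from .breaths import make_breath_table, window_select
from .compare import SubjectRecord
from .errors import ParameterError
from .signal import RawRecording, write_recording

MIN_BREATH_TIME = 0.3  # s; truncation floor for Ti and Te

PATTERNS = ("eupnea", "biot", "cheyne_stokes", "ataxic")


@dataclass
class BreathProcessSpec:
    """Parameters of the breath-to-breath generative process."""

    mean_ti: float = 1.7  # s
    mean_te: float = 2.3  # s
    sd_ti: float = 0.15  # s
    sd_te: float = 0.20  # s
    mean_amp: float = 1.0  # arbitrary acceleration units
    sd_amp: float = 0.10
    ar1_rho: float = 0.3  # lag-1 autocorrelation of breath timing
    duration: float = 330.0  # s
    pattern: str = "eupnea"

    def __post_init__(self) -> None:
        for name in ("mean_ti", "mean_te", "duration"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("sd_ti", "sd_te", "sd_amp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not abs(self.ar1_rho) < 1:
            raise ParameterError("ar1_rho must satisfy |rho| < 1")
        if self.mean_amp <= 0:
            raise ParameterError("mean_amp must be positive")
        if self.pattern not in PATTERNS:
            raise ParameterError(f"pattern must be one of {PATTERNS}")


@dataclass
class GroundTruth:
    """True breath table, subject record and true RV features for one subject."""

    breath_table: pd.DataFrame
    subject: SubjectRecord
    features: dict[str, float] | None = None


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance Gaussian AR(1) series of length n."""
    from scipy.signal import lfilter

    x = np.empty(n)
    x[0] = rng.standard_normal()
    if n > 1:
        x[1:] = rng.standard_normal(n - 1) * math.sqrt(1 - rho**2)
    return lfilter([1.0], [1.0, -rho], x)


def simulate_breath_sequence(spec: BreathProcessSpec, seed: int = 0) -> pd.DataFrame:
    """Generate a ground-truth breath table covering at least ``spec.duration``.

    Deterministic given ``seed``.  For gapless patterns (eupnea) consecutive
    breaths are contiguous: onset(i+1) = offset(i).
    """
    rng = np.random.default_rng(seed)
    mean_cycle = spec.mean_ti + spec.mean_te
    n = int(spec.duration / mean_cycle * 2) + 30

    sd_scale = 3.0 if spec.pattern == "ataxic" else 1.0
    ti = np.maximum(spec.mean_ti + spec.sd_ti * sd_scale * _ar1(n, spec.ar1_rho, rng),
                    MIN_BREATH_TIME)
    te = np.maximum(spec.mean_te + spec.sd_te * sd_scale * _ar1(n, spec.ar1_rho, rng),
                    MIN_BREATH_TIME)
    amp_floor = 1e-3 * spec.mean_amp
    amp = np.maximum(
        spec.mean_amp + spec.sd_amp * sd_scale * _ar1(n, spec.ar1_rho, rng), amp_floor
    )

    # inter-breath gaps (apnoeic pauses), zero for eupnea
    gaps = np.zeros(n)
    if spec.pattern == "biot":
        i = 0
        while i < n:
            cluster = int(rng.integers(3, 6))
            i += cluster
            if i < n:
                gaps[i] = rng.uniform(10.0, 30.0)
    elif spec.pattern == "ataxic":
        pause = rng.random(n) < 0.15
        gaps[pause] = rng.uniform(2.0, 8.0, size=int(pause.sum()))
        gaps[0] = 0.0

    # gap[i] is the apnoeic pause immediately before breath i
    onset = np.concatenate([[0.0], np.cumsum((ti + te)[:-1])]) + np.cumsum(gaps)

    if spec.pattern == "cheyne_stokes":
        cycle = 60.0
        mod = 0.5 * (1 - np.cos(2 * np.pi * onset / cycle))
        amp = np.maximum(amp * (0.1 + 0.9 * mod), amp_floor)
        keep = mod >= 0.15  # apnoea at the nadir of the cycle
    else:
        keep = np.ones(n, dtype=bool)

    peak = onset + ti
    offset = peak + te
    # cover >= duration, then stop
    covered = np.flatnonzero(offset >= spec.duration)
    if len(covered):
        last = covered[0]
        keep &= np.arange(n) <= last
    bt = make_breath_table(onset[keep], peak[keep], offset[keep], amp[keep])
    return bt


DEFAULT_ORIENTATION = (0.2, 0.3, 0.933)


def render_acceleration(
    truth: pd.DataFrame,
    fs: float = 10.0,
    gravity_offset: tuple[float, float, float] = (0.0, 0.0, 9.81),
    noise_sd: float = 0.05,
    drift_rate: float = 0.0,
    seed: int = 0,
    orientation: tuple[float, float, float] = DEFAULT_ORIENTATION,
    subject_id: str = "sim",
) -> RawRecording:
    """Render a ground-truth breath table as a triaxial recording.

    Each breath is a raised-cosine rise over Ti and fall over Te scaled by
    its amplitude, projected on the axes by a fixed unit orientation vector;
    constant per-axis gravity offset, white noise of ``noise_sd`` and linear
    drift ``drift_rate * t`` are added to every axis.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    max_freq = 1.0 / float(truth["ttot"].min())
    if fs <= 2 * max_freq:
        raise ParameterError(
            f"fs={fs} must exceed twice the max breath frequency {max_freq:.3g} Hz"
        )
    duration = float(truth["offset"].iloc[-1])
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    w = np.zeros(n)
    for onset, peak, offset, ti, te, amp in truth[
        ["onset", "peak", "offset", "ti", "te", "amplitude"]
    ].itertuples(index=False):
        i0, i1 = np.searchsorted(t, [onset, peak])
        i2 = np.searchsorted(t, offset)
        w[i0:i1] = amp * 0.5 * (1 - np.cos(np.pi * (t[i0:i1] - onset) / ti))
        w[i1:i2] = amp * 0.5 * (1 + np.cos(np.pi * (t[i1:i2] - peak) / te))
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    rng = np.random.default_rng(seed)
    chans = []
    for k in range(3):
        chans.append(
            w * u[k]
            + gravity_offset[k]
            + drift_rate * t
            + rng.normal(0.0, noise_sd, size=n)
        )
    return RawRecording(
        t=t, ax=chans[0], ay=chans[1], az=chans[2], fs=fs, subject_id=subject_id
    )


# -- cohort generation --------------------------------------------------------

#: Per-group covariate distributions: mean/SD (age, temperature, HR, pulse
#: pressure difference) and male fraction, matching the reported cohort's
#: baseline table (patients n=44: age 55.8+-17.8, T 36.6+-0.4, HR 83.6+-16,
#: PPD 46.5+-13, 13 male; controls n=44: age 45.8+-17, T 36.4+-0.2,
#: HR 71.6+-11.7, PPD 45.4+-9.8, 22 male).
DEFAULT_COVARIATES = {
    "patient": {
        "age": (55.8, 17.8),
        "temperature": (36.6, 0.4),
        "heart_rate": (83.6, 16.0),
        "pulse_pressure": (46.5, 13.0),
        "male_frac": 13 / 44,
    },
    "control": {
        "age": (45.8, 17.0),
        "temperature": (36.4, 0.2),
        "heart_rate": (71.6, 11.7),
        "pulse_pressure": (45.4, 9.8),
        "male_frac": 22 / 44,
    },
}

#: Patient breathing: slightly faster, more variable and more autocorrelated
#: than controls, giving elevated I/E-ratio SD2 in the patient group (the
#: direction of the reported group difference).
DEFAULT_BREATH_SPECS = {
    "patient": BreathProcessSpec(
        mean_ti=1.5, mean_te=2.0, sd_ti=0.25, sd_te=0.35,
        mean_amp=1.0, sd_amp=0.20, ar1_rho=0.5,
    ),
    "control": BreathProcessSpec(
        mean_ti=1.7, mean_te=2.3, sd_ti=0.15, sd_te=0.20,
        mean_amp=1.0, sd_amp=0.10, ar1_rho=0.3,
    ),
}

#: Covariate -> breathing-process modulation, the confounding structure the
#: GAM stage must remove: respiratory rate rises with heart rate, timing SDs
#: rise nonlinearly (quadratically) away from mid-life age, amplitude SD
#: rises with pulse pressure.
DEFAULT_COVARIATE_EFFECTS = {
    "rate_per_hr": 0.004,  # fractional rate change per beat/min above 75
    "sd_age_quad": 0.35,  # timing-SD multiplier on ((age-48)/27)^2
    "amp_sd_per_ppd": 0.004,  # fractional amplitude-SD change per mmHg above 46
}

DEFAULT_CRSR_LINK = {"intercept": 14.0, "coefs": {"ie_ratio_sd2": -25.0, "rate_cv": -15.0}}
DEFAULT_OUTCOME_LINK = {"intercept": 1.8, "coefs": {"ie_ratio_sd2": -8.0}}


@dataclass
class CohortSpec:
    """Everything needed to simulate one cohort, fully seeded."""

    n_patients: int = 44
    n_controls: int = 44
    breath_spec_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_BREATH_SPECS)
    )
    covariate_distributions: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATES.items()}
    )
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    crsr_link: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_CRSR_LINK)))
    outcome_link: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_OUTCOME_LINK)))
    noise_sd: float = 3.0  # CRS-R score units
    seed: int = 0
    render: bool = True
    fs: float = 10.0
    render_noise_sd: float = 0.05
    drift_rate: float = 0.002
    window_s: float = 300.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ParameterError("cohort counts must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def _draw_covariates(group: str, dists: dict, rng: np.random.Generator) -> dict:
    d = dists[group]
    age = float(np.clip(rng.normal(*d["age"]), 18.0, 75.0))
    return {
        "age": age,
        "sex": int(rng.random() < d["male_frac"]),
        "temperature": float(rng.normal(*d["temperature"])),
        "heart_rate": float(np.clip(rng.normal(*d["heart_rate"]), 40.0, 140.0)),
        "pulse_pressure": float(np.clip(rng.normal(*d["pulse_pressure"]), 15.0, 90.0)),
    }


def _modulate_spec(base: BreathProcessSpec, cov: dict, eff: dict) -> BreathProcessSpec:
    rate_scale = 1.0 + eff.get("rate_per_hr", 0.0) * (cov["heart_rate"] - 75.0)
    rate_scale = max(rate_scale, 0.5)
    sd_scale = 1.0 + eff.get("sd_age_quad", 0.0) * ((cov["age"] - 48.0) / 27.0) ** 2
    amp_sd_scale = max(
        1.0 + eff.get("amp_sd_per_ppd", 0.0) * (cov["pulse_pressure"] - 46.0), 0.1
    )
    return replace(
        base,
        mean_ti=base.mean_ti / rate_scale,
        mean_te=base.mean_te / rate_scale,
        sd_ti=base.sd_ti * sd_scale,
        sd_te=base.sd_te * sd_scale,
        sd_amp=base.sd_amp * amp_sd_scale,
    )


def _linear_link(link: dict, features: dict[str, float]) -> float:
    val = float(link.get("intercept", 0.0))
    for name, coef in link.get("coefs", {}).items():
        val += float(coef) * features[name]
    return val


def simulate_cohort(spec: CohortSpec) -> list[tuple[RawRecording | None, GroundTruth]]:
    """Simulate n_patients + n_controls subjects (patients first).

    Returns one ``(recording, ground_truth)`` pair per subject; the recording
    is ``None`` when ``spec.render`` is false (truth-only fast path for
    statistical studies that do not exercise the waveform stages).
    """
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[RawRecording | None, GroundTruth]] = []
    roster = [("patient", i) for i in range(spec.n_patients)] + [
        ("control", i) for i in range(spec.n_controls)
    ]
    for group, i in roster:
        sid = f"{'P' if group == 'patient' else 'C'}{i + 1:03d}"
        cov = _draw_covariates(group, spec.covariate_distributions, rng)
        bspec = _modulate_spec(spec.breath_spec_by_group[group], cov, spec.covariate_effects)
        breath_seed = int(rng.integers(0, 2**31 - 1))
        bt = simulate_breath_sequence(bspec, seed=breath_seed)
        profile = rvmetrics.compute_rv_profile(
            window_select(bt, spec.window_s), window_s=spec.window_s
        )
        feats = profile.values

        crsr = latent = outcome = None
        if group == "patient":
            latent = _linear_link(spec.crsr_link, feats) + rng.normal(0.0, spec.noise_sd)
            crsr = int(np.clip(round(latent), 0, 23))
            logit = _linear_link(spec.outcome_link, feats)
            p_improve = 1.0 / (1.0 + math.exp(-logit))
            outcome = "improved" if rng.random() < p_improve else "unimproved"

        subject = SubjectRecord(
            subject_id=sid, group=group, crsr_total=crsr, outcome=outcome,
            crsr_latent=latent, **cov,
        )
        rec = None
        if spec.render:
            rec = render_acceleration(
                bt,
                fs=spec.fs,
                noise_sd=spec.render_noise_sd,
                drift_rate=spec.drift_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=sid,
            )
        out.append((rec, GroundTruth(breath_table=bt, subject=subject, features=feats)))
    return out


def cohort_feature_table(
    cohort: list[tuple[RawRecording | None, GroundTruth]]
) -> pd.DataFrame:
    """True RV features, one row per subject (oracle for recovery tests)."""
    rows = {gt.subject.subject_id: gt.features for _, gt in cohort}
    return pd.DataFrame.from_dict(rows, orient="index")[rvmetrics.feature_names()]


def cohort_subject_records(
    cohort: list[tuple[RawRecording | None, GroundTruth]]
) -> list[SubjectRecord]:
    return [gt.subject for _, gt in cohort]


def write_cohort(cohort, out_dir) -> None:
    """Write recordings (CSV), per-subject truth (JSON sidecar) and subjects.csv."""
    from .compare import subjects_to_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, gt in cohort:
        sid = gt.subject.subject_id
        if rec is not None:
            write_recording(rec, out / f"{sid}.csv")
        sidecar = {
            "subject_id": sid,
            "breath_table": gt.breath_table.round(9).to_dict(orient="list"),
            "features": gt.features,
        }
        (out / f"{sid}.truth.json").write_text(json.dumps(sidecar, sort_keys=True))
    subjects_to_frame(cohort_subject_records(cohort)).to_csv(out / "subjects.csv")
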