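"""Signal conditioning: raw triaxial acceleration -> clean respiratory waveform.

A supine subject's breathing tilts an abdominal IMU quasi-periodically, so
respiration appears as a 0.1-0.7 Hz oscillation superimposed on the static
gravity projection of each axis, sensor noise, and slow baseline drift.
This module selects the most respiration-dominant axis, bandpass-filters it
with a zero-phase Butterworth filter, smooths with a centred moving average,
removes residual drift with a rolling-median baseline, and screens the result
for quality problems (apnoeic fractions, Biot-like clustering, low SNR,
insufficient duration).

Every transformation appends an entry to the signal's ``provenance`` list so
the exact parameter set of a processed waveform can be reconstructed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ParameterError, RecordingFormatError, TooShortError

logger = logging.getLogger(__name__)

#: Default respiratory band (Hz): 6-42 breaths/min, spanning supine adult rates.
DEFAULT_BAND = (0.1, 0.7)


@dataclass
class RawRecording:
    """Time-stamped triaxial acceleration samples from one subject."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)

    def validate(self) -> None:
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise RecordingFormatError("channel lengths differ")
        if n < 2 or np.any(np.diff(self.t) <= 0):
            raise RecordingFormatError("time column is not strictly increasing")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        med_dt = float(np.median(np.diff(self.t)))
        if abs(med_dt * self.fs - 1.0) > 0.01:
            raise RecordingFormatError(
                f"declared fs={self.fs} inconsistent with median dt={med_dt:.4g}"
            )

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.t, "ax": self.ax, "ay": self.ay, "az": self.az}
        )


@dataclass
class RespSignal:
    """One-dimensional respiratory waveform with processing provenance."""

    t: np.ndarray
    x: np.ndarray
    fs: float
    provenance: list[dict] = field(default_factory=list)
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def _derive(self, x: np.ndarray, step: dict) -> "RespSignal":
        return RespSignal(
            t=self.t,
            x=x,
            fs=self.fs,
            provenance=[*self.provenance, step],
            subject_id=self.subject_id,
        )

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, sort_keys=True)


@dataclass
class QCReport:
    """Quality-control summary for one processed recording."""

    flags: frozenset
    apnea_fraction: float
    snr_db: float

    @property
    def usable(self) -> bool:
        return len(self.flags) == 0

    def to_dict(self) -> dict:
        return {
            "flags": sorted(self.flags),
            "apnea_fraction": self.apnea_fraction,
            "snr_db": self.snr_db,
            "usable": self.usable,
        }


def read_recording(path, subject_id: str | None = None) -> RawRecording:
    """Read a ``time,ax,ay,az`` CSV into a validated :class:`RawRecording`.

    Rows with any unparseable field are dropped (count logged). The sampling
    rate is inferred from the median time step.
    """
    df = pd.read_csv(path)
    required = ["time", "ax", "ay", "az"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"missing columns: {missing}")
    df = df[required].apply(pd.to_numeric, errors="coerce")
    n_raw = len(df)
    df = df.dropna()
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d unparseable row(s)", path, n_dropped)
    if len(df) < 2:
        raise RecordingFormatError("fewer than 2 valid samples")
    t = df["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise RecordingFormatError("time column is not strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))
    if t[-1] - t[0] < 30.0:
        raise TooShortError("recording shorter than 30 s")
    rec = RawRecording(
        t=t,
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        fs=fs,
        subject_id=subject_id or str(path),
    )
    rec.validate()
    return rec


def write_recording(rec: RawRecording, path) -> None:
    rec.to_frame().to_csv(path, index=False, float_format="%.8g")


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    nperseg = min(len(x), max(256, int(64 * fs)))
    f, pxx = sps.welch(x - x.mean(), fs=fs, nperseg=nperseg)
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any():
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))


def select_axis(raw: RawRecording, band: tuple[float, float] = DEFAULT_BAND) -> RespSignal:
    """Pick the axis with maximal spectral power in the respiratory band.

    The chosen channel is mean-removed; ties break to the lowest axis index.
    """
    channels = {"x": raw.ax, "y": raw.ay, "z": raw.az}
    powers = [_band_power(v, raw.fs, band) for v in channels.values()]
    idx = int(np.argmax(powers))  # argmax returns first max -> lowest index on tie
    name = list(channels)[idx]
    x = channels[name] - channels[name].mean()
    return RespSignal(
        t=raw.t,
        x=x,
        fs=raw.fs,
        provenance=[{"op": "select_axis", "axis": name, "band": list(band)}],
        subject_id=raw.subject_id,
    )


def bandpass_filter(
    sig: RespSignal,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> RespSignal:
    """Zero-phase Butterworth bandpass (forward-backward, so no phase lag).

    Zero-phase filtering matters here: Ti and Te are derived from peak and
    trough *times*, which a causal filter would shift.
    """
    nyq = sig.fs / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sig.fs, output="sos")
    x = sps.sosfiltfilt(sos, sig.x)
    return sig._derive(
        x, {"op": "bandpass_filter", "low": low, "high": high, "order": order}
    )


def moving_average(sig: RespSignal, window: float = 0.5) -> RespSignal:
    """Centred moving mean over ``window`` seconds; edges use shrunken windows."""
    w = int(round(window * sig.fs))
    if w < 1:
        w = 1
    if w > len(sig.x):
        raise ParameterError("moving-average window longer than signal")
    x = (
        pd.Series(sig.x)
        .rolling(w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return sig._derive(x, {"op": "moving_average", "window_s": window, "window_n": w})


def correct_drift(sig: RespSignal, window: float = 20.0) -> RespSignal:
    """Subtract a rolling-median baseline (robust to apnoeas, unlike polynomials)."""
    w = max(1, int(round(window * sig.fs)))
    baseline = (
        pd.Series(sig.x)
        .rolling(w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    x = sig.x - baseline
    return sig._derive(x, {"op": "correct_drift", "window_s": window})


def snr_estimate(sig: RespSignal, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """In-band vs out-of-band power ratio in dB (DC below 0.05 Hz excluded)."""
    nperseg = min(len(sig.x), max(256, int(64 * sig.fs)))
    f, pxx = sps.welch(sig.x - sig.x.mean(), fs=sig.fs, nperseg=nperseg)
    inb = (f >= band[0]) & (f <= band[1])
    outb = (f > 0.05) & ~inb
    p_in = float(np.trapezoid(pxx[inb], f[inb])) if inb.any() else 0.0
    p_out = float(np.trapezoid(pxx[outb], f[outb])) if outb.any() else 0.0
    if p_out <= 0:
        return np.inf if p_in > 0 else 0.0
    if p_in <= 0:
        return -np.inf
    return 10.0 * np.log10(p_in / p_out)


def quality_check(
    sig: RespSignal,
    window_s: float = 5.0,
    apnea_amp_frac: float = 0.25,
    apnea_frac_threshold: float = 0.2,
    min_duration: float = 300.0,
    snr_db_min: float = 3.0,
) -> QCReport:
    """Screen a processed waveform; returns a report, never raises.

    A 5-s window is apnoeic when its peak-to-peak amplitude falls below
    ``apnea_amp_frac`` of the recording's global amplitude scale (the 90th
    percentile of window peak-to-peak amplitudes — robust even when most of
    the recording is apnoeic, which a whole-signal IQR is not).  A Biot-like
    pattern is flagged when the apnoeic fraction exceeds
    ``apnea_frac_threshold`` *and* breathing resumes in clusters (at least
    two separate breathing runs between apnoeic runs), mirroring the
    clinical exclusion of cluster breathing with interposed apnoeas.
    """
    flags = set()
    x = sig.x
    n_win = int(round(window_s * sig.fs))
    n_win = max(1, n_win)
    n_full = len(x) // n_win
    apneic = np.zeros(max(n_full, 1), dtype=bool)
    ptps = np.array(
        [np.ptp(x[i * n_win : (i + 1) * n_win]) for i in range(n_full)]
    )
    if n_full:
        amp_scale = float(np.percentile(ptps, 90))
        apneic = ptps < apnea_amp_frac * amp_scale
    apnea_fraction = float(apneic.mean()) if n_full else 0.0

    if apnea_fraction > apnea_frac_threshold:
        flags.add("apnea_fraction_high")
        # breathing runs: contiguous non-apneic stretches bounded by apnoeas
        changes = np.flatnonzero(np.diff(apneic.astype(int)))
        n_breathing_runs = int(np.sum(np.diff(np.r_[True, apneic, True].astype(int)) == -1))
        if n_breathing_runs >= 2 and len(changes) >= 3:
            flags.add("biot_pattern")

    # duration counts whole samples (n/fs), not last-minus-first timestamps,
    # so an exactly-300-s recording of 3000 samples at 10 Hz is not short
    if sig.duration + 1.0 / sig.fs < min_duration:
        flags.add("too_short")

    snr = snr_estimate(sig)
    if snr < snr_db_min:
        flags.add("low_snr")

    return QCReport(flags=frozenset(flags), apnea_fraction=apnea_fraction, snr_db=float(snr))


#: Band used when filtering the waveform whose extrema give breath *timing*.
#: Wider than the rate band: an asymmetric breath (Ti != Te) carries its
#: asymmetry in harmonics of the breathing frequency, and clipping them at
#: 0.7 Hz shifts peak/trough times by ~0.2 s.
WAVEFORM_BAND = (0.05, 1.5)


def preprocess(
    raw: RawRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    waveform_band: tuple[float, float] = WAVEFORM_BAND,
    order: int = 4,
    ma_window: float = 0.5,
    drift_window: float = 20.0,
) -> RespSignal:
    """Standard conditioning chain: axis selection, drift removal, bandpass, smoothing.

    ``band`` governs axis selection (where respiration power lives);
    ``waveform_band`` governs the Butterworth filter applied to the retained
    waveform, kept wide to preserve breath-shape harmonics and hence timing.
    """
    sig = select_axis(raw, band=band)
    sig = correct_drift(sig, window=drift_window)
    sig = bandpass_filter(sig, low=waveform_band[0], high=waveform_band[1], order=order)
    sig = moving_average(sig, window=ma_window)
    return sig


def write_signal(sig: RespSignal, path) -> None:
    pd.DataFrame({"time": sig.t, "x": sig.x}).to_csv(
        path, index=False, float_format="%.8g"
    )
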