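"""Seizure-envelope data features: the target the model inversion fits.

The recipe, applied per channel in this exact order:

1. slice the recording from ``pad_before_s`` before seizure onset to
   ``pad_after_s`` after offset;
2. replace outlier samples (|v - mean| beyond ``outlier_sd`` standard
   deviations) with the pre-replacement mean;
3. high-pass filter (zero-phase Butterworth, default cutoff 10 Hz) to
   remove slow drifts;
4. sliding window of ``window_len`` samples: square, average, log
   (natural log, epsilon-guarded); the default stride equals the window
   length, so the envelope is decimated;
5. despike the envelope again;
6. low-pass filter the envelope (default cutoff 0.05 Hz);
7. subtract a baseline: the mean over the first ``baseline_s`` seconds.

SEEG input must already be bipolar-referenced.  For EEG the *gain matrix*
used downstream in the inversion takes elementwise absolute values; the
feature recipe itself is identical.

Filters are zero-phase (forward-backward second-order sections,
Butterworth order 4) so that envelope onset times -- which the
epileptogenicity values are built from -- are not delayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .forward import SensorTimeSeries

__all__ = [
    "FeatureConfig",
    "FeatureSeries",
    "TargetBundle",
    "despike_outliers",
    "log_power_envelope",
    "compute_envelope_feature",
    "feature_target_pack",
]

LOG_EPS = 1e-12


@dataclass
class FeatureConfig:
    """Envelope-extraction settings (defaults follow the clinical recipe)."""

    pad_before_s: float = 10.0
    pad_after_s: float = 10.0
    outlier_sd: float = 2.0
    hp_cutoff_hz: float = 10.0
    window_len: int = 100
    window_stride: int | None = None  # None -> window_len (decimating)
    lp_cutoff_hz: float = 0.05
    baseline_s: float = 5.0

    def __post_init__(self):
        vals = (self.pad_before_s, self.pad_after_s, self.outlier_sd,
                self.hp_cutoff_hz, self.window_len, self.lp_cutoff_hz,
                self.baseline_s)
        if any(v <= 0 for v in vals):
            raise ValueError("all feature parameters must be positive")
        if self.window_stride is None:
            self.window_stride = self.window_len


@dataclass
class FeatureSeries:
    """Per-channel log-power envelope on a decimated time grid."""

    labels: list[str]
    times_s: np.ndarray
    values: np.ndarray  # (n_channels, n_times)
    modality: str  # "seeg" | "eeg"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope features must be finite")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def to_tsv(self, path):
        rows = pd.DataFrame({
            "channel": np.repeat(self.labels, len(self.times_s)),
            "time_s": np.tile(self.times_s, len(self.labels)),
            "value": self.values.ravel(),
        })
        rows.to_csv(path, sep="\t", index=False)


def despike_outliers(trace: np.ndarray, outlier_sd: float = 2.0) -> np.ndarray:
    """Replace samples at or beyond ``outlier_sd`` standard deviations.

    Outliers become the (pre-replacement) trace mean; mean and standard
    deviation are those of the input trace, single pass.  A constant
    trace is returned unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    mu, sd = trace.mean(), trace.std()
    if sd == 0:
        return trace.copy()
    out = trace.copy()
    out[np.abs(trace - mu) >= outlier_sd * sd] = mu
    return out


def _zero_phase(x: np.ndarray, cutoff_hz: float, fs: float, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"{btype} cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = butter(4, cutoff_hz / nyq, btype=btype, output="sos")
    padlen = min(x.shape[-1] - 1, 3 * 15)
    return sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def log_power_envelope(x: np.ndarray, fs: float,
                       cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pre-baseline log-power envelope of already-sliced traces.

    Despike -> high-pass -> windowed square/average/log -> despike ->
    low-pass.  Returns (envelope (C, n_win), window-center sample
    indices).  Scaling the input by k shifts this envelope by 2 log k
    (up to filter edge effects); the baseline subtraction in
    :func:`compute_envelope_feature` removes that shift for stationary
    signals.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x = np.stack([despike_outliers(ch, cfg.outlier_sd) for ch in x])
    x = _zero_phase(x, cfg.hp_cutoff_hz, fs, "highpass")

    n_win = (x.shape[1] - cfg.window_len) // cfg.window_stride + 1
    if n_win < 2:
        raise ValueError("recording too short for the envelope window")
    idx = np.arange(n_win) * cfg.window_stride
    power = np.stack([np.mean(x[:, i:i + cfg.window_len] ** 2, axis=1)
                      for i in idx], axis=1)
    env = np.log(LOG_EPS + power)

    env = np.stack([despike_outliers(ch, cfg.outlier_sd) for ch in env])
    fs_env = fs / cfg.window_stride
    if cfg.lp_cutoff_hz < fs_env / 2.0:
        env = _zero_phase(env, cfg.lp_cutoff_hz, fs_env, "lowpass")
    else:
        warnings.warn("envelope low-pass cutoff at or above Nyquist; skipped")
    return env, idx + cfg.window_len // 2


def compute_envelope_feature(series: SensorTimeSeries,
                             seizure_window_s: tuple[float, float],
                             config: FeatureConfig | None = None,
                             modality: str | None = None) -> FeatureSeries:
    """Run the full envelope recipe on a (bipolar SEEG or EEG) recording."""
    cfg = config or FeatureConfig()
    modality = modality or series.kind
    if series.kind == "seeg" and series.montage != "bipolar":
        raise ValueError("SEEG input must be bipolar-referenced first")
    fs = series.sampling_rate_hz
    onset_s, offset_s = seizure_window_s
    t0 = max(series.times_s[0], onset_s - cfg.pad_before_s)
    t1 = min(series.times_s[-1], offset_s + cfg.pad_after_s)
    if onset_s < series.times_s[0] or offset_s > series.times_s[-1]:
        raise ValueError("seizure window lies outside the recording")
    sel = (series.times_s >= t0) & (series.times_s <= t1)
    times = series.times_s[sel]
    env, centers = log_power_envelope(series.values[:, sel], fs, cfg)
    env_times = times[centers]

    fs_env = fs / cfg.window_stride
    n_base = max(1, int(round(cfg.baseline_s * fs_env)))
    env = env - env[:, :n_base].mean(axis=1, keepdims=True)
    return FeatureSeries(labels=list(series.labels), times_s=env_times,
                         values=env, modality=modality)


@dataclass
class TargetBlock:
    """One modality of the inversion target, aligned with its gain rows."""

    modality: str
    labels: list[str]
    times_s: np.ndarray
    values: np.ndarray  # (n_channels, n_times)
    gain: np.ndarray  # (L, n_channels), EEG already elementwise-absolute


@dataclass
class TargetBundle:
    """Stacked single- or multi-modality inversion target."""

    blocks: list[TargetBlock]

    @property
    def n_times(self) -> int:
        return len(self.blocks[0].times_s)


def feature_target_pack(features: list[FeatureSeries], gains: list) -> TargetBundle:
    """Align features with gain matrices by channel label and stack them.

    Channel order inside each feature series is irrelevant: rows are
    reordered to the gain's sensor order.  EEG gains enter as elementwise
    absolute values (the envelope accumulates signal power regardless of
    dipole polarity at the scalp).  Mismatched labels are rejected.
    """
    if len(features) != len(gains):
        raise ValueError("one gain matrix per feature series required")
    blocks = []
    n_times = None
    for feat, gain in zip(features, gains):
        missing = set(gain.sensor_labels) - set(feat.labels)
        if missing:
            raise ValueError(f"feature series lacks channels {sorted(missing)}")
        order = [feat.labels.index(lab) for lab in gain.sensor_labels]
        values = feat.values[order]
        if n_times is None:
            n_times = values.shape[1]
        elif values.shape[1] != n_times:
            raise ValueError("feature blocks must share one time grid length")
        g = np.asarray(gain.values, dtype=float)
        if feat.modality == "eeg":
            g = np.abs(g)
        blocks.append(TargetBlock(modality=feat.modality,
                                  labels=list(gain.sensor_labels),
                                  times_s=feat.times_s, values=values, gain=g))
    return TargetBundle(blocks=blocks)
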