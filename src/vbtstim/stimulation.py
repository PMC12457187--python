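"""Stimulation protocols, field maps and the per-node stimulus input.

Two routes produce the time-varying drive ``I_stim``:

* SEEG bipolar stimulation: a charge-balanced biphasic pulse train psi(t)
  (clinically 50 Hz, 3 mA, 2 ms pulses) scaled at every vertex by an
  inverse-square sensor-to-source field map of the stimulated contact
  pair, with the per-region maximum broadcast uniformly to all vertices
  of the region.

* Temporal interference (TI): two scalp electrode pairs driven at kHz
  carriers f and f + delta_f.  The summed field beats at delta_f; the
  beat envelope -- extracted by spline interpolation through peaks of the
  absolute signal -- is the effective drive, since tissue is insensitive
  to the kHz carriers themselves.  Pair-field amplitudes at the cortex
  come from a quasi-static two-point-source model projected on vertex
  normals (a desk-scale stand-in for finite-element head-model fields;
  real field maps can be loaded from file).

The physical-to-model amplitude conversion is deliberately a free
parameter (``amplitude_scale``); clinical units never fix the Epileptor's
input scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, periodogram

from .anatomy import Mesh, SensorSet
from .dynamics import SECONDS_PER_TIME_UNIT

__all__ = [
    "PulseProtocol",
    "TIProtocol",
    "FieldMap",
    "StimulusInput",
    "pulse_train",
    "seeg_field_map",
    "ti_pair_field_amplitudes",
    "ti_interference_field",
    "extract_ti_envelope",
    "ti_field_map",
    "build_stimulus_input",
    "dominant_frequency",
]

#: distance floor for inverse-square kernels, mm
MIN_DISTANCE_MM = 0.5


@dataclass
class PulseProtocol:
    """Biphasic SEEG pulse train (clinical defaults: 50 Hz, 3 mA, 2 ms)."""

    frequency_hz: float = 50.0
    amplitude_ma: float = 3.0
    pulse_width_ms: float = 2.0
    duration_s: float = 3.5
    shape: str = "biphasic"

    def __post_init__(self):
        if min(self.frequency_hz, self.amplitude_ma,
               self.pulse_width_ms, self.duration_s) <= 0:
            raise ValueError("all protocol parameters must be positive")
        if self.frequency_hz * self.pulse_width_ms * 1e-3 > 1.0:
            raise ValueError("pulses do not fit the period")
        if self.shape != "biphasic":
            raise ValueError("only biphasic pulse trains are supported")


@dataclass
class TIProtocol:
    """Temporal-interference protocol (two kHz carriers, beat at delta_f)."""

    pair_a: tuple[str, str] = ("E1", "E2")
    pair_b: tuple[str, str] = ("E3", "E4")
    f_carrier_hz: float = 1000.0
    delta_f_hz: float = 5.0
    duration_s: float = 1.0
    sampling_rate_hz: float = 30000.0
    amplitude_scale: float = 1.0

    def __post_init__(self):
        if self.delta_f_hz <= 0:
            raise ValueError("delta_f must be positive")
        if self.sampling_rate_hz < 10.0 * (self.f_carrier_hz + self.delta_f_hz):
            raise ValueError("sampling_rate must be >= 10 * (f_carrier + delta_f)")


@dataclass
class FieldMap:
    """Per-vertex stimulation field strengths (arbitrary V/m-like units).

    ``region_values[l]`` is the maximum over region l's vertices; for SEEG
    maps that maximum is also broadcast back onto every vertex of the
    region, so broadcasting is idempotent.
    """

    vertex_values: np.ndarray
    region_values: np.ndarray
    provenance: str  # "seeg_bipolar" | "ti_envelope"

    def __post_init__(self):
        if np.any(self.vertex_values < 0) or np.any(self.region_values < 0):
            raise ValueError("field strengths must be nonnegative")

    def broadcast_region_max(self, region_of_vertex: np.ndarray) -> "FieldMap":
        region_values = _region_max(self.vertex_values, region_of_vertex,
                                    len(self.region_values))
        return FieldMap(vertex_values=region_values[region_of_vertex],
                        region_values=region_values, provenance=self.provenance)


def _region_max(values: np.ndarray, region_of_vertex: np.ndarray, L: int) -> np.ndarray:
    out = np.zeros(L)
    np.maximum.at(out, region_of_vertex, values)
    return out


@dataclass
class StimulusInput:
    """Factored per-node stimulus I_stim(i, t) = scale * field(i) * drive(t).

    ``drive`` lives on the simulation grid and is exactly zero outside the
    stimulation window.  ``dense()`` materializes the full (n_nodes,
    n_steps) array; the simulator pulls single columns via ``at_step``.
    """

    field_per_node: np.ndarray
    drive: np.ndarray
    amplitude_scale: float = 1.0

    def at_step(self, i: int) -> np.ndarray:
        return self.amplitude_scale * self.drive[i] * self.field_per_node

    def dense(self) -> np.ndarray:
        return self.amplitude_scale * np.outer(self.field_per_node, self.drive)

    @property
    def n_steps(self) -> int:
        return len(self.drive)


# ---------------------------------------------------------------------------
# SEEG pulse stimulation


def pulse_train(protocol: PulseProtocol, dt_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the biphasic pulse train psi(t) on a dt_s grid over duration_s.

    Each cycle holds one charge-balanced pulse: positive then negative
    phase of pulse_width/2 each, exact zero elsewhere.  Phases contain the
    same number of samples, so the mean is zero to machine precision.
    """
    pw_s = protocol.pulse_width_ms * 1e-3
    if dt_s > pw_s / 4.0:
        raise ValueError("dt does not resolve the pulse width (need dt <= pw/4)")
    n = int(round(protocol.duration_s / dt_s))
    t = np.arange(n) * dt_s
    psi = np.zeros(n)
    period = 1.0 / protocol.frequency_hz
    n_half = max(1, int(round(pw_s / 2.0 / dt_s)))
    n_pulses = int(np.floor(protocol.frequency_hz * protocol.duration_s))
    for k in range(n_pulses):
        i0 = int(round(k * period / dt_s))
        if i0 + 2 * n_half > n:
            break
        psi[i0:i0 + n_half] = protocol.amplitude_ma
        psi[i0 + n_half:i0 + 2 * n_half] = -protocol.amplitude_ma
    return t, psi


def _inverse_square_kernel(mesh: Mesh, position: np.ndarray) -> np.ndarray:
    """kappa(i) = a_i / d_i^2 with the distance floored at MIN_DISTANCE_MM."""
    if mesh.vertex_area is None:
        raise ValueError("mesh needs vertex areas (compute_vertex_geometry)")
    d = np.linalg.norm(mesh.vertices - position[None, :], axis=1)
    if np.any(d < MIN_DISTANCE_MM):
        import warnings
        warnings.warn("contact within 0.5 mm of a vertex; distance floored")
        d = np.maximum(d, MIN_DISTANCE_MM)
    return mesh.vertex_area / d**2


def seeg_field_map(mesh: Mesh, seeg: SensorSet, pair: tuple[str, str]) -> FieldMap:
    """Field map of a bipolar contact pair: |kappa_anode - kappa_cathode|.

    The pair must be adjacent contacts of one shaft.  The per-region
    maximum is broadcast uniformly to all vertices of that region, then
    the map is normalized to a global maximum of one (amplitude is applied
    later by the stimulus builder).
    """
    ia, ic = seeg.index_of(pair[0]), seeg.index_of(pair[1])
    if seeg.electrode_group[ia] != seeg.electrode_group[ic] or abs(ia - ic) != 1:
        raise ValueError("stimulation pair must be adjacent contacts on one shaft")
    strength = np.abs(_inverse_square_kernel(mesh, seeg.positions[ia])
                      - _inverse_square_kernel(mesh, seeg.positions[ic]))
    L = mesh.n_regions
    fm = FieldMap(vertex_values=strength,
                  region_values=_region_max(strength, mesh.region_of_vertex, L),
                  provenance="seeg_bipolar")
    fm = fm.broadcast_region_max(mesh.region_of_vertex)
    peak = fm.vertex_values.max()
    if peak > 0:
        fm = FieldMap(fm.vertex_values / peak, fm.region_values / peak,
                      "seeg_bipolar")
    return fm


# ---------------------------------------------------------------------------
# TI stimulation


def ti_pair_field_amplitudes(mesh: Mesh, eeg: SensorSet,
                             pair: tuple[str, str]) -> np.ndarray:
    """Per-vertex field amplitude of one electrode pair, |E . normal|.

    Quasi-static two-point-source field in an unbounded homogeneous
    medium: E(r) = (r - r+)/|r - r+|^3 - (r - r-)/|r - r-|^3, projected
    onto the vertex normal, absolute value taken.
    """
    if mesh.vertex_normal is None:
        raise ValueError("mesh needs vertex normals (compute_vertex_geometry)")
    out = np.zeros(mesh.n_vertices)
    for sign, label in ((1.0, pair[0]), (-1.0, pair[1])):
        rs = eeg.positions[eeg.index_of(label)]
        dv = mesh.vertices - rs[None, :]
        d = np.maximum(np.linalg.norm(dv, axis=1), MIN_DISTANCE_MM)
        out = out + sign * np.einsum("ij,ij->i", dv, mesh.vertex_normal) / d**3
    return np.abs(out)


def ti_interference_field(E1, E2, protocol: TIProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Linearly summed two-carrier signal per vertex.

    signal_i(t) = E1_i sin(2 pi f t) + E2_i sin(2 pi (f + delta_f) t),
    sampled at the protocol rate for its duration.  E1, E2 are
    nonnegative scalars or per-vertex arrays; output is (..., n_samples).
    """
    E1, E2 = np.asarray(E1, float), np.asarray(E2, float)
    if np.any(E1 < 0) or np.any(E2 < 0):
        raise ValueError("pair-field amplitudes must be nonnegative")
    fs = protocol.sampling_rate_hz
    t = np.arange(int(round(protocol.duration_s * fs))) / fs
    f = protocol.f_carrier_hz
    sig = (E1[..., None] * np.sin(2 * np.pi * f * t)
           + E2[..., None] * np.sin(2 * np.pi * (f + protocol.delta_f_hz) * t))
    return t, sig


def extract_ti_envelope(signal: np.ndarray, sampling_rate_hz: float,
                        method: str = "peak_spline") -> np.ndarray:
    """Amplitude envelope of a beating carrier signal (1-D).

    Default: cubic-spline interpolation through successive local maxima of
    |signal| (the peak-envelope recipe).  ``method="hilbert"`` is a
    cross-check alternative, not the default.  Rejects signals with fewer
    than 4 peaks.
    """
    x = np.abs(np.asarray(signal, dtype=float))
    if x.ndim != 1:
        raise ValueError("extract_ti_envelope works on one signal at a time")
    if method == "hilbert":
        from scipy.signal import hilbert
        return np.abs(hilbert(np.asarray(signal, dtype=float)))
    if method != "peak_spline":
        raise ValueError(f"unknown envelope method {method!r}")
    peaks, _ = find_peaks(x)
    if len(peaks) < 4:
        raise ValueError("too few peaks to extract an envelope (< 4)")
    spline = CubicSpline(peaks, x[peaks])
    t = np.arange(len(x))
    env = spline(t)
    # beyond the first/last peak the spline extrapolates; hold the edge value
    env[: peaks[0]] = x[peaks[0]]
    env[peaks[-1]:] = x[peaks[-1]]
    return np.maximum(env, 0.0)


def dominant_frequency(x: np.ndarray, sampling_rate_hz: float) -> float:
    """Periodogram peak frequency of the mean-removed signal, Hz."""
    x = np.asarray(x, dtype=float)
    freqs, power = periodogram(x - x.mean(), fs=sampling_rate_hz)
    return float(freqs[np.argmax(power)])


def ti_field_map(mesh: Mesh, eeg: SensorSet, protocol: TIProtocol) -> FieldMap:
    """Per-vertex TI envelope-modulation amplitude, normalized to max one.

    For carrier amplitudes E1, E2 along a common axis the beat envelope
    oscillates between |E1 - E2| and E1 + E2; the component modulated at
    delta_f has amplitude 2 min(E1, E2), the classic TI effective field.
    Unlike SEEG maps this is applied per vertex (no regional broadcast).
    """
    E1 = ti_pair_field_amplitudes(mesh, eeg, protocol.pair_a)
    E2 = ti_pair_field_amplitudes(mesh, eeg, protocol.pair_b)
    eff = 2.0 * np.minimum(E1, E2)
    L = mesh.n_regions
    peak = eff.max()
    if peak > 0:
        eff = eff / peak
    return FieldMap(vertex_values=eff,
                    region_values=_region_max(eff, mesh.region_of_vertex, L),
                    provenance="ti_envelope")


def reference_ti_drive(protocol: TIProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude TI drive: envelope of an equal-amplitude carrier sum.

    Synthesizes sin(2 pi f t) + sin(2 pi (f + delta_f) t), extracts the
    peak-spline envelope and rescales to a maximum of one.  The kHz
    carrier never enters the neural model; only this envelope does.
    """
    t, sig = ti_interference_field(1.0, 1.0, protocol)
    env = extract_ti_envelope(sig, protocol.sampling_rate_hz)
    return t, env / env.max()


# ---------------------------------------------------------------------------
# stimulus assembly


def build_stimulus_input(
    field_map: FieldMap,
    drive_times_s: np.ndarray,
    drive: np.ndarray,
    dt_model: float,
    n_steps: int,
    onset_s: float = 0.0,
    amplitude_scale: float = 1.0,
    seconds_per_unit: float = SECONDS_PER_TIME_UNIT,
) -> StimulusInput:
    """Place a drive waveform on the simulation grid and attach the field map.

    I_stim(i, t) = amplitude_scale * field(i) * drive(t - onset), with the
    drive linearly resampled from its own (seconds) grid onto the model
    grid and exactly zero outside the stimulation window.  For TI the
    drive must be the extracted envelope, never the kHz carrier.
    """
    t_model_s = np.arange(n_steps) * dt_model * seconds_per_unit
    rel = t_model_s - onset_s
    resampled = np.interp(rel, drive_times_s, drive, left=0.0, right=0.0)
    resampled[(rel < drive_times_s[0]) | (rel > drive_times_s[-1])] = 0.0
    return StimulusInput(field_per_node=np.asarray(field_map.vertex_values, float),
                         drive=resampled, amplitude_scale=float(amplitude_scale))
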