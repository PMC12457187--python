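"""Source-to-sensor forward models: gain matrices, projection, montages.

Two gain families:

* distance gain: g_{j,k} = sum_{i in region j} a_i / d_{i,k}^2 -- vertex
  areas over squared Euclidean distance, summed per region.  Nonnegative;
  the default for model inversion.

* dipole gain: g_{i,k} = a_i / (4 pi sigma) * Q . (r_k - r_i) / |r_k -
  r_i|^3 -- the analytic point-dipole field in an unbounded homogeneous
  medium, with the dipole moment Q constrained to the vertex normal (unit
  moment per unit area; absolute scale is absorbed by the inversion's
  amplitude parameter).  Signed; used for high-fidelity simulation.

Scalp-EEG gains use the same unbounded-medium dipole formula.  This is a
stand-in for a boundary-element head model: the unbounded approximation
errs little for deep sources and nearby electrodes but ignores skull
attenuation for scalp sensors.  External lead-field matrices can be
loaded to override it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .anatomy import Mesh, SensorSet
from .dynamics import SECONDS_PER_TIME_UNIT, SourceActivity

__all__ = [
    "GainMatrix",
    "SensorTimeSeries",
    "gain_region_distance",
    "gain_dipole",
    "sum_gain_to_regions",
    "project_to_sensors",
    "bipolar_pairs",
    "bipolar_montage",
    "bipolar_gain",
]

MIN_DISTANCE_MM = 0.5


@dataclass
class GainMatrix:
    """Sources-by-sensors linear map (M sources x N sensors)."""

    values: np.ndarray
    source_kind: str  # "region" | "vertex"
    method: str  # "distance" | "dipole"
    sensor_kind: str  # "seeg" | "eeg"
    sensor_labels: list[str]

    def __post_init__(self):
        if self.values.shape[1] != len(self.sensor_labels):
            raise ValueError("gain columns must match sensor labels")
        if self.method == "distance" and np.any(self.values < 0):
            raise ValueError("distance-method gains are nonnegative")

    @property
    def n_sources(self) -> int:
        return self.values.shape[0]


@dataclass
class SensorTimeSeries:
    """Channel-by-time sensor signals with times in seconds."""

    labels: list[str]
    times_s: np.ndarray
    values: np.ndarray  # (n_channels, n_times)
    kind: str  # "seeg" | "eeg"
    montage: str = "monopolar"  # "monopolar" | "bipolar"

    def __post_init__(self):
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label count must match value rows")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])


def _floored_distances(mesh: Mesh, sensors: SensorSet) -> np.ndarray:
    d = np.linalg.norm(mesh.vertices[:, None, :] - sensors.positions[None, :, :],
                       axis=2)
    if np.any(d < MIN_DISTANCE_MM):
        warnings.warn("sensor within 0.5 mm of a vertex; distance floored")
        d = np.maximum(d, MIN_DISTANCE_MM)
    return d


def gain_region_distance(mesh: Mesh, sensors: SensorSet) -> GainMatrix:
    """Region-level inverse-square gain: per-region sum of a_i / d_{i,k}^2.

    Subcortical single-node sources are supported as one-vertex regions.
    """
    if mesh.vertex_area is None:
        raise ValueError("mesh needs vertex areas (compute_vertex_geometry)")
    d = _floored_distances(mesh, sensors)
    kappa = mesh.vertex_area[:, None] / d**2  # (N_vert, N_sens)
    L = mesh.n_regions
    values = np.zeros((L, sensors.n_sensors))
    np.add.at(values, mesh.region_of_vertex, kappa)
    return GainMatrix(values=values, source_kind="region", method="distance",
                      sensor_kind=sensors.kind, sensor_labels=list(sensors.labels))


def gain_dipole(mesh: Mesh, sensors: SensorSet, sigma: float = 1.0) -> GainMatrix:
    """Vertex-level dipole gain with normal-constrained unit moments."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if mesh.vertex_normal is None or mesh.vertex_area is None:
        raise ValueError("mesh needs areas and normals (compute_vertex_geometry)")
    dv = sensors.positions[None, :, :] - mesh.vertices[:, None, :]  # (N, S, 3)
    d = np.maximum(np.linalg.norm(dv, axis=2), MIN_DISTANCE_MM)
    qdot = np.einsum("isk,ik->is", dv, mesh.vertex_normal)
    values = mesh.vertex_area[:, None] / (4.0 * np.pi * sigma) * qdot / d**3
    return GainMatrix(values=values, source_kind="vertex", method="dipole",
                      sensor_kind=sensors.kind, sensor_labels=list(sensors.labels))


def sum_gain_to_regions(gain: GainMatrix, region_of_vertex: np.ndarray,
                        n_regions: int) -> GainMatrix:
    """Sum vertex-level gain rows within regions (for region-level sources)."""
    if gain.source_kind != "vertex":
        raise ValueError("gain is already region-level")
    values = np.zeros((n_regions, gain.values.shape[1]))
    np.add.at(values, region_of_vertex, gain.values)
    return GainMatrix(values=values, source_kind="region", method=gain.method,
                      sensor_kind=gain.sensor_kind,
                      sensor_labels=list(gain.sensor_labels))


def project_to_sensors(gain: GainMatrix, activity: SourceActivity,
                       seconds_per_unit: float = SECONDS_PER_TIME_UNIT
                       ) -> SensorTimeSeries:
    """Sensor signals = gain^T . source activity (exactly linear)."""
    if gain.source_kind != activity.node_kind:
        raise ValueError(f"gain source_kind {gain.source_kind!r} does not match "
                         f"activity node_kind {activity.node_kind!r}")
    if gain.n_sources != activity.values.shape[0]:
        raise ValueError("gain rows must match activity nodes")
    return SensorTimeSeries(labels=list(gain.sensor_labels),
                            times_s=activity.times * seconds_per_unit,
                            values=gain.values.T @ activity.values,
                            kind=gain.sensor_kind, montage="monopolar")


def bipolar_pairs(sensors: SensorSet) -> list[tuple[int, int, str]]:
    """Adjacent same-shaft contact pairs, labelled "A1-A2" style."""
    pairs = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(sensors.electrode_group):
        groups.setdefault(g, []).append(i)
    for g, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(f"shaft {g!r} has a single contact: no bipolar pairs")
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            pairs.append((a, b, f"{sensors.labels[a]}-{sensors.labels[b]}"))
    return pairs


def bipolar_montage(series: SensorTimeSeries, sensors: SensorSet) -> SensorTimeSeries:
    """Re-reference monopolar SEEG as differences of adjacent contacts."""
    if series.montage != "monopolar":
        raise ValueError("input must be monopolar")
    pairs = bipolar_pairs(sensors)
    labels = [lab for _, _, lab in pairs]
    idx_a = [a for a, _, _ in pairs]
    idx_b = [b for _, b, _ in pairs]
    return SensorTimeSeries(labels=labels, times_s=series.times_s,
                            values=series.values[idx_a] - series.values[idx_b],
                            kind=series.kind, montage="bipolar")


def bipolar_gain(gain: GainMatrix, sensors: SensorSet) -> GainMatrix:
    """Gain matrix of the bipolar montage: column differences of pairs."""
    pairs = bipolar_pairs(sensors)
    cols = gain.values[:, [a for a, _, _ in pairs]] \
        - gain.values[:, [b for _, b, _ in pairs]]
    return GainMatrix(values=cols, source_kind=gain.source_kind,
                      method=f"{gain.method}_bipolar",
                      sensor_kind=gain.sensor_kind,
                      sensor_labels=[lab for _, _, lab in pairs])
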