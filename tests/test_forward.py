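import numpy as np
import pytest

from vbtstim.anatomy import Mesh, SensorSet, compute_vertex_geometry
from vbtstim.dynamics import SourceActivity
from vbtstim.forward import (
    GainMatrix,
    bipolar_gain,
    bipolar_montage,
    bipolar_pairs,
    gain_dipole,
    gain_region_distance,
    project_to_sensors,
    sum_gain_to_regions,
)


def single_vertex_mesh(area=2.0):
    """One target vertex with a prescribed vertex area.

    Vertex 0 sits on one right triangle of area 3 * ``area``, so its
    one-third share is exactly ``area``; its normal is +z.
    """
    s = np.sqrt(6.0 * area)
    verts = np.array([[0.0, 0.0, 0.0], [s, 0.0, 0.0], [0.0, s, 0.0],
                      [s, s, 0.0]])
    tris = np.array([[0, 1, 2], [1, 3, 2]])
    mesh = compute_vertex_geometry(Mesh(vertices=verts, triangles=tris))
    mesh.region_of_vertex = np.array([0, 1, 2, 3])
    return mesh


class TestDistanceGain:
    def test_single_vertex_arithmetic(self):
        # one region = one vertex with a = 2 mm^2 at distance d = 2 mm
        mesh = single_vertex_mesh(area=2.0)
        assert np.isclose(mesh.vertex_area[0], 2.0)
        sensors = SensorSet(kind="seeg", labels=["s"],
                            positions=np.array([[0.0, 0.0, 2.0]]))
        gain = gain_region_distance(mesh, sensors)
        assert np.isclose(gain.values[0, 0], 2.0 / 4.0)

    def test_matches_brute_force_vertex_sum(self, toy_brain):
        mesh, conn, seeg, _ = toy_brain
        gain = gain_region_distance(mesh, seeg)
        # naive double loop over vertices and sensors
        L = conn.n_regions
        expected = np.zeros((L, seeg.n_sensors))
        for i in range(mesh.n_vertices):
            for k in range(seeg.n_sensors):
                d = np.linalg.norm(mesh.vertices[i] - seeg.positions[k])
                d = max(d, 0.5)
                expected[mesh.region_of_vertex[i], k] += \
                    mesh.vertex_area[i] / d**2
        assert np.max(np.abs(gain.values - expected)) < 1e-10

    def test_farther_sensor_smaller_column(self, toy_brain):
        mesh, _, seeg, _ = toy_brain
        near = SensorSet(kind="seeg", labels=["n"],
                         positions=seeg.positions[:1])
        direction = seeg.positions[0] - mesh.vertices.mean(axis=0)
        far = SensorSet(kind="seeg", labels=["f"],
                        positions=(seeg.positions[:1] + 10.0
                                   * direction / np.linalg.norm(direction)))
        g_near = gain_region_distance(mesh, near).values[:, 0]
        g_far = gain_region_distance(mesh, far).values[:, 0]
        assert np.all(g_far < g_near)

    def test_distance_floor_warns(self):
        mesh = single_vertex_mesh()
        sensors = SensorSet(kind="seeg", labels=["s"],
                            positions=mesh.vertices[:1] + 1e-6)
        with pytest.warns(UserWarning, match="floored"):
            gain_region_distance(mesh, sensors)


class TestDipoleGain:
    def test_on_axis_value(self):
        # a = 1, sigma = 1, Q = z-hat, sensor on the axis at distance 1
        mesh = single_vertex_mesh(area=1.0)
        sensors = SensorSet(kind="eeg", labels=["s"],
                            positions=np.array([[0.0, 0.0, 1.0]]))
        gain = gain_dipole(mesh, sensors, sigma=1.0)
        assert np.isclose(abs(gain.values[0, 0]), 1.0 / (4.0 * np.pi))

    def test_perpendicular_sensor_zero(self):
        mesh = single_vertex_mesh(area=1.0)
        sensors = SensorSet(kind="eeg", labels=["s"],
                            positions=np.array([[3.0, 0.0, 0.0]]))
        gain = gain_dipole(mesh, sensors)
        assert np.isclose(gain.values[0, 0], 0.0, atol=1e-12)

    def test_flipping_normal_flips_row(self):
        mesh = single_vertex_mesh(area=1.0)
        sensors = SensorSet(kind="eeg", labels=["a", "b"],
                            positions=np.array([[1.0, 2.0, 3.0],
                                                [0.5, -1.0, 2.0]]))
        g1 = gain_dipole(mesh, sensors).values[0]
        mesh.vertex_normal = -mesh.vertex_normal
        g2 = gain_dipole(mesh, sensors).values[0]
        assert np.allclose(g2, -g1)

    def test_region_sum_matches_brute_force(self, toy_brain):
        mesh, conn, seeg, _ = toy_brain
        gv = gain_dipole(mesh, seeg)
        greg = sum_gain_to_regions(gv, mesh.region_of_vertex, conn.n_regions)
        expected = np.zeros_like(greg.values)
        for i in range(mesh.n_vertices):
            expected[mesh.region_of_vertex[i]] += gv.values[i]
        assert np.max(np.abs(greg.values - expected)) < 1e-10

    def test_rigid_transform_invariance(self, toy_brain):
        mesh, _, seeg, _ = toy_brain
        g0 = gain_region_distance(mesh, seeg).values
        # rotate + translate mesh and sensors jointly
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 11.0])
        mesh2 = Mesh(vertices=mesh.vertices @ R.T + shift,
                     triangles=mesh.triangles,
                     region_of_vertex=mesh.region_of_vertex)
        mesh2 = compute_vertex_geometry(mesh2)
        seeg2 = SensorSet(kind="seeg", labels=list(seeg.labels),
                          positions=seeg.positions @ R.T + shift,
                          electrode_group=list(seeg.electrode_group))
        g1 = gain_region_distance(mesh2, seeg2).values
        assert np.allclose(g0, g1, atol=1e-9)


class TestProjection:
    def _activity(self, n, T=20, seed=0):
        rng = np.random.default_rng(seed)
        return SourceActivity(times=np.arange(T) * 0.1,
                              values=rng.standard_normal((n, T)),
                              node_kind="region")

    def _gain(self, n, m, seed=1):
        rng = np.random.default_rng(seed)
        return GainMatrix(values=np.abs(rng.standard_normal((n, m))),
                          source_kind="region", method="distance",
                          sensor_kind="seeg",
                          sensor_labels=[f"c{i}" for i in range(m)])

    def test_identity_gain(self):
        act = self._activity(4)
        gain = GainMatrix(values=np.eye(4), source_kind="region",
                          method="distance", sensor_kind="seeg",
                          sensor_labels=list("abcd"))
        out = project_to_sensors(gain, act)
        assert np.allclose(out.values, act.values)

    def test_superposition(self):
        a1, a2 = self._activity(5, seed=2), self._activity(5, seed=3)
        gain = self._gain(5, 7)
        summed = SourceActivity(times=a1.times, values=a1.values + a2.values,
                                node_kind="region")
        out = project_to_sensors(gain, summed)
        assert np.allclose(out.values,
                           project_to_sensors(gain, a1).values
                           + project_to_sensors(gain, a2).values)

    def test_single_source_channel_order_follows_gain(self):
        gain = self._gain(3, 6)
        values = np.zeros((3, 10))
        values[1] = 1.0  # only source 1 active
        act = SourceActivity(times=np.arange(10.0), values=values,
                             node_kind="region")
        out = project_to_sensors(gain, act)
        assert np.array_equal(np.argsort(out.values[:, 0]),
                              np.argsort(gain.values[1]))

    def test_kind_mismatch_rejected(self):
        act = self._activity(4)
        gain = self._gain(4, 3)
        object.__setattr__(gain, "source_kind", "vertex")
        with pytest.raises(ValueError, match="node_kind"):
            project_to_sensors(gain, act)


class TestBipolar:
    def _series(self, values, labels, groups):
        from vbtstim.forward import SensorTimeSeries
        return SensorTimeSeries(labels=labels,
                                times_s=np.arange(values.shape[1]) * 1e-3,
                                values=values, kind="seeg"), \
            SensorSet(kind="seeg", labels=labels,
                      positions=np.zeros((len(labels), 3)) + np.arange(
                          len(labels))[:, None],
                      electrode_group=groups)

    def test_identical_traces_cancel(self):
        v = np.tile(np.sin(np.linspace(0, 5, 40)), (2, 1))
        series, sensors = self._series(v, ["A1", "A2"], ["A", "A"])
        out = bipolar_montage(series, sensors)
        assert np.allclose(out.values, 0.0)
        assert out.labels == ["A1-A2"]

    def test_five_contacts_four_channels(self):
        rng = np.random.default_rng(0)
        labels = [f"B{i}" for i in range(1, 6)]
        series, sensors = self._series(rng.standard_normal((5, 30)),
                                       labels, ["B"] * 5)
        out = bipolar_montage(series, sensors)
        assert len(out.labels) == 4
        assert out.labels[0] == "B1-B2"

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((4, 25))
        labels = [f"C{i}" for i in range(1, 5)]
        series, sensors = self._series(v, labels, ["C"] * 4)
        base = bipolar_montage(series, sensors)
        common = np.sin(np.linspace(0, 9, 25))
        series2, _ = self._series(v + common, labels, ["C"] * 4)
        shifted = bipolar_montage(series2, sensors)
        assert np.allclose(base.values, shifted.values, atol=1e-12)

    def test_single_contact_shaft_warns(self):
        labels = ["D1", "E1", "E2"]
        series, sensors = self._series(np.zeros((3, 10)), labels,
                                       ["D", "E", "E"])
        with pytest.warns(UserWarning, match="single contact"):
            pairs = bipolar_pairs(sensors)
        assert [lab for _, _, lab in pairs] == ["E1-E2"]

    def test_bipolar_gain_matches_montage(self, toy_brain):
        mesh, conn, seeg, _ = toy_brain
        gain = gain_region_distance(mesh, seeg)
        gbi = bipolar_gain(gain, seeg)
        rng = np.random.default_rng(4)
        act = SourceActivity(times=np.arange(15.0),
                             values=rng.standard_normal((conn.n_regions, 15)),
                             node_kind="region")
        mono = project_to_sensors(gain, act)
        via_montage = bipolar_montage(mono, seeg)
        via_gain = project_to_sensors(gbi, act)
        assert np.allclose(via_montage.values, via_gain.values)
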