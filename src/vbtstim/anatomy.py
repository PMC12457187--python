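"""Synthetic brain anatomy: meshes, parcellations, connectomes and sensors.

Everything downstream (field simulation, forward models, inversion) runs on
the scaffold produced here, so no patient imaging is required.  The toy
brain is a pair of deformed spheres ("lobes") triangulated on the unit
sphere and radially deformed afterwards, which keeps every generated vertex
in the triangulation.  Region labels come from farthest-point seeding on
each lobe, giving contiguous, parcellation-like patches.

Units are millimetres throughout, in a single right-handed frame shared by
the mesh and all sensors.  Region indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "Mesh",
    "Connectome",
    "SensorSet",
    "GeodesicNeighborhood",
    "BrainModel",
    "compute_vertex_geometry",
    "geodesic_distances",
    "make_toy_brain",
    "save_anatomy",
    "load_anatomy",
]

#: toy-brain lobe radius, mm: human-extent hemispheres, so sensor-source
#: distances (and hence gain contrasts) are realistic even when the
#: vertex density is far below the ~10 mm^2 of clinical-resolution meshes
LOBE_RADIUS_MM = 40.0


@dataclass
class Mesh:
    """Triangulated cortical surface with per-vertex geometry and labels.

    vertices : (N, 3) float, mm.  triangles : (M, 3) int vertex indices.
    vertex_area : (N,) float, mm^2 -- one third of the area of all incident
    triangles.  vertex_normal : (N, 3) unit float.  region_of_vertex :
    (N,) int in [0, L).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_area: np.ndarray | None = None
    vertex_normal: np.ndarray | None = None
    region_of_vertex: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_regions(self) -> int:
        if self.region_of_vertex is None:
            raise ValueError("mesh has no parcellation")
        return int(self.region_of_vertex.max()) + 1

    def validate(self) -> None:
        V, T = np.asarray(self.vertices), np.asarray(self.triangles)
        if V.ndim != 2 or V.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if T.ndim != 2 or T.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if T.min(initial=0) < 0 or T.max(initial=-1) >= len(V):
            raise ValueError("triangle indices out of range")
        if self.vertex_area is not None:
            if np.any(self.vertex_area <= 0):
                raise ValueError("all vertex areas must be positive")
            total = triangle_areas(V, T).sum()
            if not np.isclose(self.vertex_area.sum(), total, rtol=1e-9):
                raise ValueError("vertex areas do not sum to surface area")
        if self.vertex_normal is not None:
            norms = np.linalg.norm(self.vertex_normal, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("vertex normals must have unit length")
        if self.region_of_vertex is not None:
            r = np.asarray(self.region_of_vertex)
            if len(r) != len(V) or r.min() < 0:
                raise ValueError("bad parcellation vector")


@dataclass
class Connectome:
    """Region-by-region structural coupling matrix W.

    Zero diagonal, nonnegative, max-normalized to one.  Generated matrices
    are symmetric (undirected streamline counts); loaded matrices may be
    asymmetric and are used as-is.
    """

    weights: np.ndarray
    region_names: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def validate(self) -> None:
        W = np.asarray(self.weights)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectome must be square")
        if W.shape[0] != len(self.region_names):
            raise ValueError("region_names length mismatch")
        if np.any(np.diag(W) != 0):
            raise ValueError("connectome diagonal must be exactly zero")
        if np.any(W < 0):
            raise ValueError("connectome entries must be nonnegative")
        if W.size and W.max() > 0 and not np.isclose(W.max(), 1.0):
            raise ValueError("connectome must be max-normalized to 1")


@dataclass
class SensorSet:
    """Electrode contacts: SEEG depth shafts or scalp-EEG electrodes.

    ``electrode_group`` identifies the shaft a SEEG contact belongs to;
    bipolar derivations are only formed between adjacent contacts of one
    shaft.
    """

    kind: str  # "seeg" | "eeg"
    labels: list[str]
    positions: np.ndarray
    electrode_group: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("seeg", "eeg"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")
        if not self.electrode_group:
            self.electrode_group = list(self.labels)

    @property
    def n_sensors(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown sensor label {label!r}") from None


@dataclass
class GeodesicNeighborhood:
    """Per-vertex geodesic neighborhoods within a cutoff radius.

    ``dist`` is a sparse (N, N) matrix of shortest-path distances along the
    mesh edge graph for pairs with 0 < d <= cutoff; the zero self-distance
    is implicit.
    """

    dist: csr_matrix
    cutoff_mm: float

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        row = self.dist.getrow(i)
        return row.indices, row.data


@dataclass
class BrainModel:
    """The full anatomical scaffold consumed by the simulator."""

    mesh: Mesh
    connectome: Connectome
    seeg: SensorSet
    eeg: SensorSet
    geodesics: GeodesicNeighborhood | None = None

    @property
    def n_regions(self) -> int:
        return self.connectome.n_regions


# ---------------------------------------------------------------------------
# geometry


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 1]] - vertices[triangles[:, 0]]
    b = vertices[triangles[:, 2]] - vertices[triangles[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def compute_vertex_geometry(mesh: Mesh) -> Mesh:
    """Fill in vertex areas and normals from positions and triangles.

    The area of vertex i is one third of the total area of its incident
    triangles; normals are area-weighted averages of incident face normals,
    renormalized to unit length.  Degenerate (zero-area) triangles
    contribute nothing and trigger a warning.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    T = np.asarray(mesh.triangles, dtype=int)
    e1 = V[T[:, 1]] - V[T[:, 0]]
    e2 = V[T[:, 2]] - V[T[:, 0]]
    cross = np.cross(e1, e2)
    face_area2 = np.linalg.norm(cross, axis=1)  # 2 * area
    if np.any(face_area2 == 0):
        warnings.warn("degenerate zero-area triangle(s); they contribute 0")
    areas = np.zeros(len(V))
    normals = np.zeros_like(V)
    for k in range(3):
        np.add.at(areas, T[:, k], face_area2 / 6.0)  # (area)/3 per corner
        np.add.at(normals, T[:, k], cross / 2.0)  # area-weighted face normal
    nrm = np.linalg.norm(normals, axis=1)
    ok = nrm > 0
    normals[ok] /= nrm[ok, None]
    normals[~ok] = np.array([0.0, 0.0, 1.0])
    return replace(mesh, vertex_area=areas, vertex_normal=normals)


def geodesic_distances(mesh: Mesh, cutoff_mm: float = 20.0) -> GeodesicNeighborhood:
    """Shortest-path distances along mesh edges, truncated at ``cutoff_mm``.

    Dijkstra over the edge graph with Euclidean edge lengths.  This
    overestimates exact polyhedral geodesics by a second-order amount,
    which is negligible under the fast-decaying local coupling kernel.
    """
    if cutoff_mm <= 0:
        raise ValueError("cutoff_mm must be positive")
    V = np.asarray(mesh.vertices, dtype=float)
    T = np.asarray(mesh.triangles, dtype=int)
    edges = np.vstack([T[:, [0, 1]], T[:, [1, 2]], T[:, [2, 0]]])
    lengths = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
    n = len(V)
    graph = coo_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n)).tocsr()
    degree = np.diff(graph.maximum(graph.T).indptr)
    if np.any(degree == 0):
        warnings.warn(
            f"{int((degree == 0).sum())} disconnected vertex(es): empty neighborhood"
        )
    full = dijkstra(graph, directed=False, limit=cutoff_mm)
    full[~np.isfinite(full)] = 0.0
    np.fill_diagonal(full, 0.0)
    return GeodesicNeighborhood(dist=csr_matrix(full), cutoff_mm=float(cutoff_mm))


# ---------------------------------------------------------------------------
# toy brain


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _orient_outward(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Flip hull triangles so normals point away from the centroid."""
    c = points.mean(axis=0)
    tri = simplices.copy()
    a = points[tri[:, 1]] - points[tri[:, 0]]
    b = points[tri[:, 2]] - points[tri[:, 0]]
    nrm = np.cross(a, b)
    mid = points[tri].mean(axis=1) - c
    flip = np.einsum("ij,ij->i", nrm, mid) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


def _farthest_point_seeds(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k vertex indices spread out by greedy farthest-point sampling."""
    idx = [int(rng.integers(len(points)))]
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(idx)


def _lobe(n: int, n_regions: int, center: np.ndarray, radius: float,
          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One closed deformed-sphere lobe with a contiguous parcellation."""
    unit = _fibonacci_sphere(n)
    hull = ConvexHull(unit)
    tri = _orient_outward(unit, hull.simplices)
    # smooth radial deformation applied after triangulation, so every
    # generated vertex stays in the mesh
    th = np.arccos(np.clip(unit[:, 2], -1, 1))
    ph = np.arctan2(unit[:, 1], unit[:, 0])
    bump = 0.06 * np.sin(3 * th) * np.cos(2 * ph) + 0.04 * np.cos(2 * th)
    verts = center + radius * (1.0 + bump)[:, None] * unit
    seeds = _farthest_point_seeds(verts, n_regions, rng)
    _, region = cKDTree(verts[seeds]).query(verts)
    # guarantee non-empty regions (seeds are vertices, each owns itself)
    region[seeds] = np.arange(n_regions)
    return verts, tri, region


def make_toy_brain(
    n_vertices: int = 600,
    n_regions: int = 12,
    n_seeg_shafts: int = 6,
    n_eeg: int = 32,
    seed: int = 0,
    contacts_per_shaft: int = 8,
    contact_spacing_mm: float = 3.5,
) -> tuple[Mesh, Connectome, SensorSet, SensorSet]:
    """Generate a deterministic two-lobe toy brain.

    Two deformed spherical lobes of human extent (radius ~40 mm) carry
    contiguous region patches; the connectome is a sparse symmetric
    nonnegative matrix max-normalized to one, SEEG shafts are collinear
    contact runs penetrating the lobes, and scalp electrodes sit on an
    enclosing sphere.  Vertex density (hence per-vertex area) follows
    ``n_vertices``; clinical-resolution meshes (~10 mm^2 per vertex)
    correspond to n_vertices ~ 40,000.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if n_vertices < 4 * n_regions:
        raise ValueError("n_vertices must be >= 4 * n_regions")
    if n_seeg_shafts < 1 or n_eeg < 1:
        raise ValueError("need at least one SEEG shaft and one EEG sensor")
    rng = np.random.default_rng(seed)

    n_left = n_vertices // 2
    n_right = n_vertices - n_left
    reg_left = max(1, round(n_regions * n_left / n_vertices))
    reg_left = min(reg_left, n_regions - 1)
    reg_right = n_regions - reg_left
    r_left = r_right = LOBE_RADIUS_MM
    gap = 0.25 * (r_left + r_right)
    cl = np.array([-(r_left + gap / 2), 0.0, 0.0])
    cr = np.array([+(r_right + gap / 2), 0.0, 0.0])

    vl, tl, rl = _lobe(n_left, reg_left, cl, r_left, rng)
    vr, tr_, rr = _lobe(n_right, reg_right, cr, r_right, rng)
    vertices = np.vstack([vl, vr])
    triangles = np.vstack([tl, tr_ + n_left])
    region = np.concatenate([rl, rr + reg_left])
    mesh = compute_vertex_geometry(
        Mesh(vertices=vertices, triangles=triangles, region_of_vertex=region)
    )
    mesh.validate()

    names = [f"region-{i:02d}" for i in range(n_regions)]
    A = rng.gamma(2.0, 1.0, size=(n_regions, n_regions))
    mask = rng.random((n_regions, n_regions)) < 0.45
    W = (A * mask + (A * mask).T) / 2.0
    np.fill_diagonal(W, 0.0)
    if W.max() == 0:  # pathological draw: connect the first pair
        W[0, 1] = W[1, 0] = 1.0
    W = W / W.max()
    conn = Connectome(weights=W, region_names=names)
    conn.validate()

    # SEEG shafts: straight runs from outside one lobe toward a region
    # centroid, contacts spaced like clinical depth electrodes
    shaft_letters = [chr(ord("A") + k) + "'" for k in range(n_seeg_shafts)]
    targets = rng.permutation(n_regions)[: n_seeg_shafts] if n_seeg_shafts <= n_regions \
        else rng.integers(0, n_regions, n_seeg_shafts)
    pos, labels, groups = [], [], []
    for k, letter in enumerate(shaft_letters):
        reg_k = int(targets[k % len(targets)])
        centroid = vertices[region == reg_k].mean(axis=0)
        lobe_center = cl if centroid[0] < 0 else cr
        direction = centroid - lobe_center
        direction = direction / np.linalg.norm(direction)
        entry = centroid + direction * (0.35 * (r_left + r_right) / 2)
        for j in range(contacts_per_shaft):
            pos.append(entry - direction * contact_spacing_mm * j)
            labels.append(f"{letter}{j + 1}")
            groups.append(letter)
    seeg = SensorSet(kind="seeg", labels=labels,
                     positions=np.asarray(pos), electrode_group=groups)

    center = vertices.mean(axis=0)
    r_eeg = np.linalg.norm(vertices - center, axis=1).max() + 15.0
    eeg_pos = center + r_eeg * _fibonacci_sphere(n_eeg)
    eeg = SensorSet(kind="eeg", labels=[f"E{i + 1}" for i in range(n_eeg)],
                    positions=eeg_pos,
                    electrode_group=[f"E{i + 1}" for i in range(n_eeg)])
    return mesh, conn, seeg, eeg


# ---------------------------------------------------------------------------
# I/O


def _tsv_header(seed=None) -> str:
    s = "# units: mm; frame: right-handed shared by mesh and sensors; region indices 0-based\n"
    if seed is not None:
        s += f"# seed: {seed}\n"
    return s


def save_anatomy(model: BrainModel, outdir: str | Path, mesh_format: str = "ply",
                 seed: int | None = None) -> dict[str, Path]:
    """Write the scaffold: mesh (PLY/OFF), parcellation, connectome, sensors.

    TSV files carry a comment header with units; the PLY default is binary
    for a bit-exact mesh round trip.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if mesh_format not in ("ply", "off"):
        raise ValueError("mesh_format must be 'ply' or 'off'")
    paths = {}
    tm = trimesh.Trimesh(vertices=model.mesh.vertices,
                         faces=model.mesh.triangles, process=False)
    mesh_path = outdir / f"mesh.{mesh_format}"
    tm.export(mesh_path)
    paths["mesh"] = mesh_path

    parc = pd.DataFrame({
        "vertex_index": np.arange(model.mesh.n_vertices),
        "region_index": model.mesh.region_of_vertex,
        "region_name": [model.connectome.region_names[r]
                        for r in model.mesh.region_of_vertex],
    })
    p = outdir / "parcellation.tsv"
    with open(p, "w") as f:
        f.write(_tsv_header(seed))
        parc.to_csv(f, sep="\t", index=False)
    paths["parcellation"] = p

    p = outdir / "connectome.tsv"
    with open(p, "w") as f:
        f.write(_tsv_header(seed))
        pd.DataFrame(model.connectome.weights,
                     columns=model.connectome.region_names).to_csv(
            f, sep="\t", index=False, float_format="%.17g")
    paths["connectome"] = p

    for name, sensors in (("seeg", model.seeg), ("eeg", model.eeg)):
        p = outdir / f"sensors_{name}.tsv"
        with open(p, "w") as f:
            f.write(_tsv_header(seed))
            pd.DataFrame({
                "label": sensors.labels,
                "group": sensors.electrode_group,
                "x_mm": sensors.positions[:, 0],
                "y_mm": sensors.positions[:, 1],
                "z_mm": sensors.positions[:, 2],
            }).to_csv(f, sep="\t", index=False, float_format="%.17g")
        paths[f"sensors_{name}"] = p
    return paths


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_anatomy(indir: str | Path, mesh_format: str = "ply") -> BrainModel:
    """Load a scaffold written by :func:`save_anatomy`; invariants enforced.

    A mesh without region labels is rejected unless the parcellation table
    is present; a connectome with a nonzero diagonal is rejected.
    """
    indir = Path(indir)
    mesh_path = indir / f"mesh.{mesh_format}"
    tm = trimesh.load(str(mesh_path), process=False)
    parc_path = indir / "parcellation.tsv"
    if not parc_path.exists():
        raise ValueError("mesh carries no region labels and no parcellation "
                         "table was supplied")
    parc = _read_tsv(parc_path).sort_values("vertex_index")
    if len(parc) != len(tm.vertices):
        raise ValueError("parcellation length does not match mesh vertices")

    conn_df = _read_tsv(indir / "connectome.tsv")
    W = conn_df.to_numpy(dtype=float)
    names = list(conn_df.columns)
    if W.shape[0] != W.shape[1]:
        raise ValueError("connectome matrix must be square")
    if np.any(np.diag(W) != 0):
        raise ValueError("connectome diagonal must be exactly zero")
    if int(parc["region_index"].max()) + 1 > len(names):
        raise ValueError("parcellation refers to regions absent from connectome")
    conn = Connectome(weights=W, region_names=names)
    conn.validate()

    sensors = {}
    for kind in ("seeg", "eeg"):
        df = _read_tsv(indir / f"sensors_{kind}.tsv")
        sensors[kind] = SensorSet(
            kind=kind, labels=list(df["label"]),
            positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            electrode_group=list(df["group"]))

    mesh = compute_vertex_geometry(Mesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        triangles=np.asarray(tm.faces, dtype=int),
        region_of_vertex=parc["region_index"].to_numpy(dtype=int),
    ))
    mesh.validate()
    return BrainModel(mesh=mesh, connectome=conn,
                      seeg=sensors["seeg"], eeg=sensors["eeg"])
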