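"""Surface meshes and time-resolved surface fields.

The in-memory model is format-agnostic: a triangulated surface in mm
(:class:`SurfaceMesh`), a per-vertex pressure/WSS time series over one
cardiac cycle (:class:`FieldSeries`) and an inlet cross-section
(:class:`InletPlane`) used as the normalization reference.

On disk, STL and PLY go through :mod:`trimesh`; legacy ASCII VTK POLYDATA is
read and written natively (including per-vertex scalar/vector point data).
Field series are stored either as a single HDF5 file or as a directory of
per-time-step VTK files. Region labels travel inside VTK point data or as a
sidecar CSV ``vertex_id,label``.

Units are fixed: mm for geometry, Pa for pressure and WSS, s for time.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import (
    AlignmentError,
    EmptyInletError,
    FormatError,
    OrderingError,
    TopologyError,
)

# Canonical region labels
BLEB = "bleb"
NONBLEB = "nonbleb"
VESSEL = "vessel"
INLET = "inlet"
REGION_LABELS = (BLEB, NONBLEB, VESSEL, INLET)


@dataclass
class SurfaceMesh:
    """Triangulated vascular surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Triangle vertex-index triples.
    vertex_normals : (n, 3) float array, optional
        Outward unit normals; computed by area-weighted face-normal
        averaging when absent.
    region_label : (n,) str array, optional
        Per-vertex categorical label among ``{bleb, nonbleb, vessel, inlet}``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    region_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise TopologyError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise TopologyError("faces must be an (m, 3) array of triangles")
        if self.vertex_normals is None:
            self.vertex_normals = self._compute_vertex_normals()
        else:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)
        if self.region_label is not None:
            self.region_label = np.asarray(self.region_label, dtype="U16")
        self.validate()

    # -- derived geometry ---------------------------------------------------

    def _compute_vertex_normals(self) -> np.ndarray:
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        normals = np.array(tm.vertex_normals, dtype=float)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return normals / norm

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each incident face."""
        areas = np.zeros(self.n_vertices)
        fa = self.face_areas / 3.0
        for k in range(3):
            np.add.at(areas, self.faces[:, k], fa)
        return areas

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    def edges_unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and their face-incidence counts."""
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        return np.unique(e, axis=0, return_counts=True)

    def boundary_vertices(self) -> np.ndarray:
        """Vertices lying on an open boundary (edges with one incident face)."""
        edges, counts = self.edges_unique()
        return np.unique(edges[counts == 1])

    def vertex_adjacency(self) -> list[np.ndarray]:
        """One-ring neighbour lists per vertex."""
        edges, _ = self.edges_unique()
        nbrs: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, j in edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(n), dtype=np.int64) for n in nbrs]

    def validate(self) -> None:
        f = self.faces
        if f.size and (f.min() < 0 or f.max() >= self.n_vertices):
            raise TopologyError("face references an out-of-range vertex index")
        if f.size and np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise TopologyError("face references duplicate vertex indices")
        _, counts = self.edges_unique()
        if np.any(counts > 2):
            raise TopologyError("mesh is not edge-manifold (edge in >2 faces)")
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise TopologyError("vertex normals are not unit length within 1e-6")
        if self.region_label is not None and len(self.region_label) != self.n_vertices:
            raise AlignmentError("region_label length does not match vertex count")

    def with_labels(self, labels: np.ndarray) -> "SurfaceMesh":
        return replace(self, region_label=np.asarray(labels, dtype="U16"))


@dataclass
class FieldSeries:
    """Per-vertex pressure and WSS over one cardiac cycle.

    ``times`` are seconds, strictly increasing, spanning at most one period
    ``period_T``. ``pressure`` has shape (n_times, n_vertices) in Pa and
    ``wss`` has shape (n_times, n_vertices, 3) in Pa.
    """

    times: np.ndarray
    pressure: np.ndarray
    wss: np.ndarray
    period_T: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.wss = np.asarray(self.wss, dtype=float)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.pressure = self.pressure[order]
        self.wss = self.wss[order]
        if np.any(np.diff(self.times) <= 0):
            raise OrderingError("time stamps must be strictly increasing")
        if self.times[0] < 0:
            raise OrderingError("times must be non-negative")
        if self.times[-1] - self.times[0] > self.period_T * (1 + 1e-9):
            raise OrderingError("time span exceeds the stated period T")
        nt = len(self.times)
        if self.pressure.shape[0] != nt or self.wss.shape[0] != nt:
            raise AlignmentError("field series time dimension mismatch")
        if self.pressure.shape[1] != self.wss.shape[1]:
            raise AlignmentError("pressure and wss vertex counts differ")
        if self.wss.shape[2] != 3:
            raise AlignmentError("wss must store 3-vectors")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_vertices(self) -> int:
        return self.pressure.shape[1]

    def index_at_time(self, t: float) -> int:
        """Index of the stored step nearest ``t`` (phase-folded by period)."""
        phase = self.times[0] + (t - self.times[0]) % self.period_T
        i = int(np.argmin(np.abs(self.times - phase)))
        return i

    def check_alignment(self, mesh: SurfaceMesh) -> None:
        if self.n_vertices != mesh.n_vertices:
            raise AlignmentError(
                f"field has {self.n_vertices} vertices, mesh has {mesh.n_vertices}"
            )


@dataclass
class InletPlane:
    """Inlet cross-section used for pressure/WSS normalization.

    The paper-equivalent location is 1 mm proximal to the aneurysm neck;
    here the plane is user- (or generator-) specified.
    """

    plane_origin: np.ndarray
    plane_normal: np.ndarray
    member_vertices: np.ndarray
    thickness: float = 0.0

    def __post_init__(self) -> None:
        self.plane_origin = np.asarray(self.plane_origin, dtype=float)
        n = np.asarray(self.plane_normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise EmptyInletError("inlet plane normal must be non-zero")
        self.plane_normal = n / nn
        self.member_vertices = np.asarray(self.member_vertices, dtype=np.int64)
        if len(self.member_vertices) == 0:
            raise EmptyInletError("inlet plane selects no vertices")


def define_inlet_plane(
    mesh: SurfaceMesh,
    origin,
    normal,
    thickness: float,
) -> InletPlane:
    """Select mesh vertices within ``thickness/2`` of the given plane."""
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    dist = np.abs((mesh.vertices - origin) @ normal)
    members = np.flatnonzero(dist <= thickness / 2.0)
    if len(members) == 0:
        raise EmptyInletError(
            "no vertices within thickness/2 of the inlet plane; "
            "check the plane location or increase thickness"
        )
    return InletPlane(origin, normal, members, thickness)


# -- legacy ASCII VTK POLYDATA -------------------------------------------


def _write_vtk_polydata(path: Path, mesh: SurfaceMesh, point_data: dict | None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nblebpoint surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                if values.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in values:
                        fh.write(f"{v:.10g}\n")
                elif values.ndim == 2 and values.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for x, y, z in values:
                        fh.write(f"{x:.10g} {y:.10g} {z:.10g}\n")
                else:
                    raise FormatError(f"unsupported point data shape for {name!r}")


def _read_vtk_polydata(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    try:
        text = Path(path).read_text()
    except OSError as exc:  # pragma: no cover - OS dependent
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if "BINARY" in text[:200].upper():
        raise FormatError(f"{path}: binary legacy VTK is not supported")
    tokens = re.split(r"\s+", text.split("DATASET", 1)[-1].strip())
    if not tokens or tokens[0] != "POLYDATA":
        raise FormatError(f"{path} is not a legacy VTK POLYDATA file")
    it = iter(tokens[1:])

    def take(n: int) -> list[str]:
        return [next(it) for _ in range(n)]

    vertices = None
    faces = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    try:
        while True:
            try:
                key = next(it)
            except StopIteration:
                break
            key = key.upper()
            if key == "POINTS":
                n_points = int(next(it))
                next(it)  # dtype
                flat = np.array(take(3 * n_points), dtype=float)
                vertices = flat.reshape(n_points, 3)
            elif key == "POLYGONS":
                n_poly = int(next(it))
                total = int(next(it))
                vals = np.array(take(total), dtype=np.int64)
                faces_list = []
                i = 0
                for _ in range(n_poly):
                    cnt = vals[i]
                    if cnt != 3:
                        raise TopologyError(
                            f"non-triangular face with {cnt} vertices in {path}"
                        )
                    faces_list.append(vals[i + 1 : i + 4])
                    i += cnt + 1
                faces = np.array(faces_list, dtype=np.int64)
            elif key == "POINT_DATA":
                n_points = int(next(it))
            elif key == "SCALARS":
                name = next(it)
                next(it)  # dtype
                ncomp = next(it)
                if not ncomp.isdigit():
                    raise FormatError("SCALARS component count missing")
                lk = next(it)
                if lk.upper() != "LOOKUP_TABLE":
                    raise FormatError("expected LOOKUP_TABLE after SCALARS")
                next(it)  # table name
                point_data[name] = np.array(take(n_points * int(ncomp)), dtype=float)
            elif key == "VECTORS":
                name = next(it)
                next(it)  # dtype
                flat = np.array(take(3 * n_points), dtype=float)
                point_data[name] = flat.reshape(n_points, 3)
            # ignore any other section keywords
    except StopIteration as exc:
        raise FormatError(f"truncated VTK file {path}") from exc
    if vertices is None or faces is None:
        raise FormatError(f"{path} lacks POINTS or POLYGONS sections")
    return vertices, faces, point_data


# -- public mesh I/O ------------------------------------------------------

_VTK_SUFFIXES = {".vtk", ".vtp"}


def load_mesh(path, format: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface from STL, PLY or legacy VTK.

    Units are assumed mm. Vertex normals are computed if the file carries
    none. STL triangle soups are vertex-welded on load.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("vtk", "vtp"):
        vertices, faces, point_data = _read_vtk_polydata(path)
        labels = None
        if "region_label" in point_data:
            codes = point_data["region_label"].astype(int)
            labels = np.array([REGION_LABELS[c] for c in codes], dtype="U16")
        return SurfaceMesh(vertices, faces, region_label=labels)
    if fmt in ("stl", "ply"):
        try:
            tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
        if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
            raise FormatError(f"{path} does not contain a triangle mesh")
        if fmt == "stl":
            tm.merge_vertices()
        faces = np.asarray(tm.faces, dtype=np.int64)
        if faces.shape[1] != 3:
            raise TopologyError(f"{path} contains non-triangular faces")
        return SurfaceMesh(np.asarray(tm.vertices, dtype=float), faces)
    raise FormatError(f"unsupported mesh format: {fmt!r}")


def save_mesh(path, mesh: SurfaceMesh, format: str | None = None) -> None:
    """Write a surface to STL, PLY or legacy VTK (labels only in VTK)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("vtk", "vtp"):
        pd = {}
        if mesh.region_label is not None:
            codes = np.array(
                [REGION_LABELS.index(l) for l in mesh.region_label], dtype=float
            )
            pd["region_label"] = codes
        _write_vtk_polydata(path, mesh, pd)
        return
    if fmt in ("stl", "ply"):
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(str(path), file_type=fmt)
        return
    raise FormatError(f"unsupported mesh format: {fmt!r}")


def save_region_labels(path, labels: np.ndarray) -> None:
    """Write per-vertex labels as a sidecar CSV ``vertex_id,label``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_id", "label"])
        for i, lab in enumerate(labels):
            w.writerow([i, lab])


def load_region_labels(path, mesh: SurfaceMesh) -> np.ndarray:
    """Read a sidecar label CSV and align it to the mesh."""
    labels = np.full(mesh.n_vertices, "", dtype="U16")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["vertex_id", "label"]:
            raise FormatError(f"{path}: expected header vertex_id,label")
        for row in reader:
            i = int(row["vertex_id"])
            if i < 0 or i >= mesh.n_vertices:
                raise AlignmentError(f"{path}: vertex_id {i} out of range")
            labels[i] = row["label"]
    return labels


# -- field series I/O -----------------------------------------------------


def save_field_series(path, series: FieldSeries, layout: str = "hdf5") -> None:
    """Write a field series as HDF5 (single file) or a VTK step directory."""
    path = Path(path)
    if layout == "hdf5":
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("times", data=series.times)
            h5.create_dataset("pressure", data=series.pressure)
            h5.create_dataset("wss", data=series.wss)
            h5.attrs["period_T"] = series.period_T
        return
    if layout == "vtk-series":
        path.mkdir(parents=True, exist_ok=True)
        meta = {"period_T": series.period_T, "times": series.times.tolist()}
        (path / "series.json").write_text(json.dumps(meta, indent=1))
        nv = series.n_vertices
        dummy = SurfaceMesh(
            np.zeros((nv, 3)),
            np.empty((0, 3), dtype=np.int64),
            vertex_normals=np.tile([0.0, 0.0, 1.0], (nv, 1)),
        )
        for k in range(series.n_times):
            _write_vtk_polydata(
                path / f"step_{k:04d}.vtk",
                dummy,
                {"pressure": series.pressure[k], "wss": series.wss[k]},
            )
        return
    raise FormatError(f"unknown field-series layout: {layout!r}")


def load_field_series(path, mesh: SurfaceMesh) -> FieldSeries:
    """Read a field series (HDF5 file or VTK step directory) for ``mesh``."""
    path = Path(path)
    if path.is_dir():
        meta_file = path / "series.json"
        if not meta_file.exists():
            raise FormatError(f"{path} lacks series.json")
        meta = json.loads(meta_file.read_text())
        times = np.asarray(meta["times"], dtype=float)
        pressures, wsses = [], []
        steps = sorted(path.glob("step_*.vtk"))
        if len(steps) != len(times):
            raise AlignmentError("step file count does not match times")
        for f in steps:
            _, _, pd = _read_vtk_polydata(f)
            pressures.append(pd["pressure"])
            wsses.append(pd["wss"])
        series = FieldSeries(
            times, np.array(pressures), np.array(wsses), float(meta["period_T"])
        )
    else:
        import h5py

        try:
            with h5py.File(path, "r") as h5:
                series = FieldSeries(
                    h5["times"][...],
                    h5["pressure"][...],
                    h5["wss"][...],
                    float(h5.attrs["period_T"]),
                )
        except OSError as exc:
            raise FormatError(f"cannot read {path} as HDF5: {exc}") from exc
    series.check_alignment(mesh)
    return series
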