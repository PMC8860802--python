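"""Synthetic aneurysm surfaces and hemodynamic fields with known ground truth.

Real inputs to the pipeline are CFD exports that are not redistributable;
this module emulates their structure so every stage is testable. The
default geometry mirrors the scale of a small middle-cerebral-artery
aneurysm: a spherical dome 3.5 mm in diameter joined at a narrower neck to
a straight parent-vessel tube, with the inlet reference plane 1 mm
proximal to the neck.

The planted field structure reproduces, with known ground truth, the
qualitative picture reported for bleb-forming regions: a high-pressure
patch (Gaussian bump scaled so the maximum normalized pressure hits a
target, 1.04 by default), a low-WSS patch, a radially divergent WSS source
in each region (one in the bleb patch, one outside), an oscillatory WSS
component inside the patch that raises OSI, and Gaussian noise. All fields
are modulated by a two-harmonic positive pulse waveform with a 1.80 s
period standing in for a physiological inlet flow curve; only the period
and the peak location matter downstream.

Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import ConfigError, PlacementError, ResolutionError
from .mesh_io import (
    BLEB,
    NONBLEB,
    VESSEL,
    FieldSeries,
    SurfaceMesh,
    define_inlet_plane,
)
from .indices import inlet_average
from .wss_topology import tangential_projection

_SQ2 = np.sqrt(0.5)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic aneurysm case (mm, Pa, s)."""

    # geometry
    dome_radius_mm: float = 1.75  # 3.5 mm diameter dome
    tube_radius_mm: float = 1.2
    tube_length_mm: float = 3.0
    mesh_edge_length_mm: float = 0.15
    # bleb patch (direction from the dome center, geodesic radius)
    bleb_direction: tuple = (_SQ2, 0.0, _SQ2)
    bleb_geodesic_radius_mm: float = 1.2
    # pressure model
    pressure_base_pa: float = 2000.0
    pressure_bump_sigma_mm: float = 1.0
    target_max_normalized_pressure: float = 1.04
    # WSS model
    wss_base_pa: float = 10.0
    low_wss_factor: float = 0.3
    source_strength_pa: float = 8.0
    source_sigma_mm: float = 0.6
    nonbleb_source_direction: tuple = (-_SQ2, 0.0, _SQ2)
    oscillatory_amplitude_pa: float = 2.0
    # waveform / time discretization
    period_T: float = 1.8
    n_steps: int = 25
    peak_time: float = 0.3
    # noise
    noise_sd_pressure: float = 1.0
    noise_sd_wss: float = 0.1
    # inlet plane: 1 mm proximal to the neck
    inlet_offset_mm: float = 1.0
    inlet_thickness_mm: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_radius_mm >= self.dome_radius_mm:
            raise ConfigError("tube radius must be smaller than the dome radius")
        for name in (
            "dome_radius_mm",
            "tube_radius_mm",
            "tube_length_mm",
            "mesh_edge_length_mm",
            "pressure_base_pa",
            "bleb_geodesic_radius_mm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mesh_edge_length_mm > self.bleb_geodesic_radius_mm:
            raise ResolutionError(
                "mesh edge length exceeds the bleb patch radius; "
                "the patch cannot be resolved"
            )

    @property
    def neck_z(self) -> float:
        """Height of the dome/tube junction below the dome center."""
        return -float(
            np.sqrt(self.dome_radius_mm**2 - self.tube_radius_mm**2)
        )

    def waveform_value(self, t) -> np.ndarray:
        """Two-harmonic positive pulse; peak value 1.8 at ``peak_time``."""
        c = np.cos(2 * np.pi * (np.asarray(t, dtype=float) - self.peak_time) / self.period_T)
        return 0.75 + 0.55 * c + 0.5 * c**2


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``expected_*`` methods evaluate the noise-free field model at arbitrary
    surface points (dense time quadrature for the cycle integrals).
    """

    spec: SyntheticSpec
    bleb_mask: np.ndarray
    dome_mask: np.ndarray
    source_points: np.ndarray  # (2, 3): bleb source, nonbleb source
    source_regions: tuple = (BLEB, NONBLEB)
    inlet_origin: np.ndarray | None = None
    inlet_normal: np.ndarray | None = None
    inlet_thickness: float = 0.2
    bump_amplitude_pa: float | None = None
    inlet_pressure_ave_pa: float | None = None

    # -- noise-free field model at arbitrary points -----------------------

    def _normal(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        n = np.where(
            (xyz[:, 2] >= self.spec.neck_z - 1e-9)[:, None],
            xyz / np.maximum(np.linalg.norm(xyz, axis=1, keepdims=True), 1e-12),
            np.column_stack(
                [
                    xyz[:, 0],
                    xyz[:, 1],
                    np.zeros(len(xyz)),
                ]
            )
            / np.maximum(np.linalg.norm(xyz[:, :2], axis=1, keepdims=True), 1e-12),
        )
        return n

    def _bump(self, xyz: np.ndarray) -> np.ndarray:
        c = self.spec.dome_radius_mm * np.asarray(self.spec.bleb_direction)
        d2 = ((np.atleast_2d(xyz) - c) ** 2).sum(axis=1)
        return np.exp(-d2 / (2 * self.spec.pressure_bump_sigma_mm**2))

    def _wss_spatial(self, xyz: np.ndarray) -> np.ndarray:
        return _wss_spatial_field(self.spec, np.atleast_2d(xyz), self._normal(xyz))

    def _osc_dir(self, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return _osc_component(self.spec, np.atleast_2d(xyz), self._normal(xyz))

    def expected_normalized_pressure(self, xyz) -> np.ndarray:
        if self.bump_amplitude_pa is None:
            raise ConfigError("ground truth lacks field parameters; run make_fields")
        p = self.spec.pressure_base_pa + self.bump_amplitude_pa * self._bump(xyz)
        return p / self.inlet_pressure_ave_pa

    def expected_tawss(self, xyz, n_quad: int = 400) -> np.ndarray:
        spec = self.spec
        t = np.linspace(0, spec.period_T, n_quad)
        s = spec.waveform_value(t) / spec.waveform_value(spec.peak_time)
        base = self._wss_spatial(xyz)  # (n, 3)
        e, w = self._osc_dir(xyz)
        osc_t = spec.oscillatory_amplitude_pa * np.cos(2 * np.pi * t / spec.period_T)
        tau = (
            s[:, None, None] * base[None, :, :]
            + osc_t[:, None, None] * (w[:, None] * e)[None, :, :]
        )
        mag = np.linalg.norm(tau, axis=2)
        return np.trapezoid(mag, t, axis=0) / spec.period_T

    def expected_osi(self, xyz, n_quad: int = 400) -> np.ndarray:
        spec = self.spec
        t = np.linspace(0, spec.period_T, n_quad)
        s = spec.waveform_value(t) / spec.waveform_value(spec.peak_time)
        base = self._wss_spatial(xyz)
        e, w = self._osc_dir(xyz)
        osc_t = spec.oscillatory_amplitude_pa * np.cos(2 * np.pi * t / spec.period_T)
        tau = (
            s[:, None, None] * base[None, :, :]
            + osc_t[:, None, None] * (w[:, None] * e)[None, :, :]
        )
        mag_int = np.trapezoid(np.linalg.norm(tau, axis=2), t, axis=0)
        vec_int = np.linalg.norm(np.trapezoid(tau, t, axis=0), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = 0.5 * (1.0 - vec_int / mag_int)
        return np.clip(val, 0.0, 0.5)


# -- mesh construction ----------------------------------------------------


def _ordered_boundary_loop(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Ordered vertex loop of the (single) open boundary."""
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, cnt = np.unique(e, axis=0, return_counts=True)
    be = uniq[cnt == 1]
    nbrs: dict[int, list[int]] = {}
    for i, j in be:
        nbrs.setdefault(int(i), []).append(int(j))
        nbrs.setdefault(int(j), []).append(int(i))
    start = min(nbrs)
    loop = [start]
    prev = -1
    while True:
        nxt = [n for n in sorted(nbrs[loop[-1]]) if n != prev]
        prev = loop[-1]
        loop.append(nxt[0])
        if loop[-1] == start:
            break
    return np.array(loop[:-1], dtype=np.int64)


def make_dome_mesh(spec: SyntheticSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Build the dome-on-tube surface with bleb labels and ground truth.

    The dome is a sliced icosphere (the spherical cap above the neck
    plane, subtending more than a hemisphere since the neck is narrower
    than the dome); the parent vessel is the neck ring extruded straight
    down. Vertex normals are analytic (spherical on the dome, radial on
    the tube). Deterministic: geometry has no random component.
    """
    r_d = spec.dome_radius_mm
    z0 = spec.neck_z
    # icosphere subdivision matching the requested edge length
    k = max(1, int(np.ceil(np.log2(1.0515 * r_d / spec.mesh_edge_length_mm))))
    sphere = trimesh.creation.icosphere(subdivisions=k, radius=r_d)
    cap = trimesh.intersections.slice_mesh_plane(
        sphere, plane_normal=[0, 0, 1], plane_origin=[0, 0, z0]
    )
    cap.merge_vertices(digits_vertex=8)
    cap.update_faces(cap.nondegenerate_faces(height=1e-10))
    cap.remove_unreferenced_vertices()
    verts = np.asarray(cap.vertices, dtype=float)
    faces = np.asarray(cap.faces, dtype=np.int64)

    loop = _ordered_boundary_loop(verts, faces)
    n_loop = len(loop)
    edge_actual = spec.mesh_edge_length_mm
    n_rings = max(1, int(np.ceil(spec.tube_length_mm / edge_actual)))
    dz = spec.tube_length_mm / n_rings

    all_verts = [verts]
    ring_prev = loop
    tube_faces = []
    n_total = len(verts)
    for r in range(1, n_rings + 1):
        ring_pts = verts[loop] + np.array([0.0, 0.0, -dz * r])
        idx = np.arange(n_total, n_total + n_loop)
        n_total += n_loop
        all_verts.append(ring_pts)
        for i in range(n_loop):
            a, b = ring_prev[i], ring_prev[(i + 1) % n_loop]
            a2, b2 = idx[i], idx[(i + 1) % n_loop]
            tube_faces.append([a, a2, b])
            tube_faces.append([b, a2, b2])
        ring_prev = idx
    vertices = np.vstack(all_verts)
    tube_faces = np.asarray(tube_faces, dtype=np.int64)

    # orient tube faces outward (radial in xy)
    f0 = tube_faces[0]
    nrm = np.cross(
        vertices[f0[1]] - vertices[f0[0]], vertices[f0[2]] - vertices[f0[0]]
    )
    centroid = vertices[f0].mean(axis=0)
    if np.dot(nrm[:2], centroid[:2]) < 0:
        tube_faces = tube_faces[:, [0, 2, 1]]
    faces_all = np.vstack([faces, tube_faces])

    # analytic outward unit normals
    on_dome = vertices[:, 2] >= z0 - 1e-9
    normals = np.empty_like(vertices)
    rad3 = np.linalg.norm(vertices, axis=1)
    normals[on_dome] = vertices[on_dome] / rad3[on_dome, None]
    rad2 = np.linalg.norm(vertices[:, :2], axis=1)
    normals[~on_dome, 0] = vertices[~on_dome, 0] / rad2[~on_dome]
    normals[~on_dome, 1] = vertices[~on_dome, 1] / rad2[~on_dome]
    normals[~on_dome, 2] = 0.0

    # labels: dome split into bleb / nonbleb, everything else vessel
    bleb_dir = np.asarray(spec.bleb_direction, dtype=float)
    bleb_dir = bleb_dir / np.linalg.norm(bleb_dir)
    labels = np.full(len(vertices), VESSEL, dtype="U16")
    dome_mask = vertices[:, 2] > z0 + 1e-9
    unit = vertices[dome_mask] / rad3[dome_mask, None]
    geo = r_d * np.arccos(np.clip(unit @ bleb_dir, -1.0, 1.0))
    sub = np.where(geo <= spec.bleb_geodesic_radius_mm, BLEB, NONBLEB)
    labels[dome_mask] = sub
    bleb_mask = np.zeros(len(vertices), dtype=bool)
    bleb_mask[np.flatnonzero(dome_mask)[sub == BLEB]] = True

    mesh = SurfaceMesh(vertices, faces_all, vertex_normals=normals, region_label=labels)

    # planted sources at the dome vertices nearest the requested directions
    src_dirs = [bleb_dir, np.asarray(spec.nonbleb_source_direction, dtype=float)]
    src_pts = []
    for d in src_dirs:
        d = d / np.linalg.norm(d)
        target = r_d * d
        if target[2] <= z0:
            raise PlacementError("planted source direction falls off the dome")
        i = int(np.argmin(((vertices - target) ** 2).sum(axis=1)))
        src_pts.append(vertices[i])
    truth = GroundTruth(
        spec=spec,
        bleb_mask=bleb_mask,
        dome_mask=dome_mask,
        source_points=np.asarray(src_pts),
        inlet_origin=np.array([0.0, 0.0, z0 - spec.inlet_offset_mm]),
        inlet_normal=np.array([0.0, 0.0, 1.0]),
        inlet_thickness=max(spec.inlet_thickness_mm, 1.2 * dz),
    )
    return mesh, truth


# -- field construction ---------------------------------------------------


def _wss_spatial_field(
    spec: SyntheticSpec, xyz: np.ndarray, normals: np.ndarray
) -> np.ndarray:
    """Noise-free peak-systole WSS: attenuated base flow + planted sources."""
    # base: tangential projection of a fixed swirl+axial analytic field
    swirl = np.column_stack([-xyz[:, 1], xyz[:, 0], np.zeros(len(xyz))])
    v = np.tile([0.3, 0.0, 1.0], (len(xyz), 1)) + 0.5 * swirl / spec.dome_radius_mm
    v_t = v - np.einsum("ij,ij->i", v, normals)[:, None] * normals
    base = spec.wss_base_pa * v_t

    # low-WSS patch: flat attenuation over the bleb patch with a smooth rim,
    # so the whole bleb area (not just its center) sees depressed WSS
    bleb_dir = np.asarray(spec.bleb_direction, dtype=float)
    bleb_dir = bleb_dir / np.linalg.norm(bleb_dir)
    unit = xyz / np.maximum(np.linalg.norm(xyz, axis=1, keepdims=True), 1e-12)
    geo = spec.dome_radius_mm * np.arccos(np.clip(unit @ bleb_dir, -1.0, 1.0))
    rim = 0.6  # mm transition width
    t = np.clip((geo - spec.bleb_geodesic_radius_mm) / rim, 0.0, 1.0)
    att = spec.low_wss_factor + (1.0 - spec.low_wss_factor) * (3 * t**2 - 2 * t**3)

    # each planted source is a stagnation point of the background flow:
    # the base field is suppressed in the source core and replaced by a
    # linear-core radial source F = s * (r/sigma) * exp(-r^2/2sigma^2) * rhat,
    # whose magnitude vanishes at the center and whose surface divergence
    # at the center is 2 s / sigma > 0
    sources = []
    for d in (spec.bleb_direction, spec.nonbleb_source_direction):
        d = np.asarray(d, dtype=float)
        center = spec.dome_radius_mm * d / np.linalg.norm(d)
        dvec = xyz - center
        dvec_t = dvec - np.einsum("ij,ij->i", dvec, normals)[:, None] * normals
        norm = np.linalg.norm(dvec_t, axis=1, keepdims=True)
        radial = np.divide(dvec_t, norm, out=np.zeros_like(dvec_t), where=norm > 1e-9)
        r2 = (dvec**2).sum(axis=1)
        ramp = np.sqrt(r2) / spec.source_sigma_mm
        decay = np.exp(-r2 / (2 * spec.source_sigma_mm**2))
        sources.append(spec.source_strength_pa * (ramp * decay)[:, None] * radial)
        stag_sigma = 1.5 * spec.source_sigma_mm
        att *= 1.0 - 0.85 * np.exp(-r2 / (2 * stag_sigma**2))

    out = att[:, None] * base
    for src in sources:
        out += src
    return out


def _osc_component(
    spec: SyntheticSpec, xyz: np.ndarray, normals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unit oscillation direction and spatial weight of the OSI patch."""
    e = np.cross(normals, np.tile([0.3, 0.0, 1.0], (len(xyz), 1)))
    norm = np.linalg.norm(e, axis=1, keepdims=True)
    e = np.divide(e, norm, out=np.zeros_like(e), where=norm > 1e-9)
    bleb_center = spec.dome_radius_mm * np.asarray(spec.bleb_direction)
    bleb_center = bleb_center / np.linalg.norm(bleb_center) * spec.dome_radius_mm
    sigma = 0.7 * spec.bleb_geodesic_radius_mm
    w = np.exp(-(((xyz - bleb_center) ** 2).sum(axis=1)) / (2 * sigma**2))
    return e, w


def make_fields(
    mesh: SurfaceMesh,
    truth: GroundTruth,
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
) -> tuple[FieldSeries, GroundTruth]:
    """Generate the pressure/WSS time series with planted structure.

    The pressure bump amplitude is solved so that the maximum vertex
    pressure on the dome divided by the area-weighted inlet average equals
    ``target_max_normalized_pressure`` exactly (before noise).
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    inlet = define_inlet_plane(
        mesh, truth.inlet_origin, truth.inlet_normal, truth.inlet_thickness
    )

    # pressure bump amplitude from the target max normalized pressure
    g = truth._bump(mesh.vertices)
    g_max = float(g[truth.dome_mask].max())
    w_area = mesh.vertex_areas[inlet.member_vertices]
    g_in = float((g[inlet.member_vertices] * w_area).sum() / w_area.sum())
    t_target = spec.target_max_normalized_pressure
    denom = g_max - t_target * g_in
    if denom <= 0:
        raise ConfigError("pressure bump overlaps the inlet too strongly")
    amp = spec.pressure_base_pa * (t_target - 1.0) / denom
    p_spatial = spec.pressure_base_pa + amp * g

    times = np.linspace(0.0, spec.period_T, spec.n_steps)
    s = spec.waveform_value(times) / spec.waveform_value(spec.peak_time)

    wss_spatial = _wss_spatial_field(spec, mesh.vertices, mesh.vertex_normals)
    e_osc, w_osc = _osc_component(spec, mesh.vertices, mesh.vertex_normals)
    osc_t = spec.oscillatory_amplitude_pa * np.cos(2 * np.pi * times / spec.period_T)

    pressure = s[:, None] * p_spatial[None, :] + rng.normal(
        0.0, spec.noise_sd_pressure, (spec.n_steps, mesh.n_vertices)
    )
    wss = (
        s[:, None, None] * wss_spatial[None, :, :]
        + osc_t[:, None, None] * (w_osc[:, None] * e_osc)[None, :, :]
        + rng.normal(0.0, spec.noise_sd_wss, (spec.n_steps, mesh.n_vertices, 3))
    )
    # keep WSS numerically tangential after adding isotropic noise
    wss = np.stack([tangential_projection(mesh, wss[k]) for k in range(len(times))])

    series = FieldSeries(times, pressure, wss, spec.period_T)
    truth = replace(
        truth,
        bump_amplitude_pa=float(amp),
        inlet_pressure_ave_pa=float(spec.pressure_base_pa + amp * g_in),
    )
    return series, truth


def make_null_fields(
    mesh: SurfaceMesh,
    truth: GroundTruth,
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
) -> FieldSeries:
    """Fields with no region-dependent structure (type-I-error testing).

    Pressure is spatially constant plus iid noise; WSS has constant
    magnitude along the azimuthal (swirl) unit direction plus iid noise,
    so every per-point statistic has the same distribution in both
    regions. The azimuthal field is direction-coherent everywhere on the
    dome except the single apex vertex, keeping interpolated magnitudes
    region-exchangeable.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    times = np.linspace(0.0, spec.period_T, spec.n_steps)
    s = spec.waveform_value(times) / spec.waveform_value(spec.peak_time)

    normals = mesh.vertex_normals
    e = np.cross(np.tile([0.0, 0.0, 1.0], (len(normals), 1)), normals)
    norm = np.linalg.norm(e, axis=1, keepdims=True)
    u = np.divide(e, norm, out=np.zeros_like(e), where=norm > 1e-9)

    pressure = spec.pressure_base_pa * s[:, None] + rng.normal(
        0.0, spec.noise_sd_pressure, (spec.n_steps, mesh.n_vertices)
    )
    wss = spec.wss_base_pa * s[:, None, None] * u[None, :, :] + rng.normal(
        0.0, spec.noise_sd_wss, (spec.n_steps, mesh.n_vertices, 3)
    )
    wss = np.stack([tangential_projection(mesh, wss[k]) for k in range(len(times))])
    return FieldSeries(times, pressure, wss, spec.period_T)


def make_waveform(
    spec: SyntheticSpec, n_cycles: int = 2, n_per_cycle: int = 360
) -> tuple[np.ndarray, np.ndarray]:
    """Inlet flow-rate waveform over ``n_cycles`` cardiac cycles.

    Flow units are arbitrary (only the peak location matters downstream);
    the pulse peaks once per cycle at ``peak_time`` past the cycle start.
    """
    times = np.linspace(0.0, n_cycles * spec.period_T, n_cycles * n_per_cycle + 1)
    return times, spec.waveform_value(times)


# -- published contingency counts (fixture) -------------------------------

#: Divergence-center counts per case: (centers_bleb, n_bleb,
#: centers_nonbleb, n_nonbleb) from the published comparison table.
TABLE1_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "case1": (1, 11, 1, 135),
    "case2": (1, 8, 1, 144),
}


def write_table1_counts(path) -> None:
    """Write the published center-count fixture as CSV."""
    lines = ["case,centers_bleb,n_bleb,centers_nonbleb,n_nonbleb"]
    for case, (cb, nb, cn, nn) in TABLE1_COUNTS.items():
        lines.append(f"{case},{cb},{nb},{cn},{nn}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_csv(path) -> dict[str, tuple[int, int, int, int]]:
    """Read a center-count CSV (as written by :func:`write_table1_counts`)."""
    import csv

    from .exceptions import FormatError

    counts: dict[str, tuple[int, int, int, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"case", "centers_bleb", "n_bleb", "centers_nonbleb", "n_nonbleb"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            try:
                counts[row["case"]] = (
                    int(row["centers_bleb"]),
                    int(row["n_bleb"]),
                    int(row["centers_nonbleb"]),
                    int(row["n_nonbleb"]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer count in row {row}") from exc
    if not counts:
        raise FormatError(f"{path}: no count rows")
    return counts
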