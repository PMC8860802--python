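"""Hemodynamic indices: normalized pressure/WSS, TAWSS, OSI, peak systole.

Pressure and WSS magnitude are normalized by their area-weighted averages
over the inlet cross-section (1 mm proximal to the aneurysm in the
reference protocol), removing dependence on inflow boundary conditions:

    normalized pressure = P / P_ave(inlet)
    normalized WSS      = |tau| / WSS_ave(inlet)

Instantaneous quantities are evaluated at the peak systole of the second
simulated cardiac cycle; cycle-integrated quantities use the standard
definitions

    TAWSS = (1/T) * int_0^T |tau(t)| dt
    OSI   = 1/2 * (1 - |int_0^T tau(t) dt| / int_0^T |tau(t)| dt)

with trapezoidal integration on the supplied (possibly non-uniform) time
grid. OSI lies in [0, 1/2]: 0 for unidirectional shear, 1/2 for perfect
reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateInletError,
    InsufficientDataError,
    NormalizationError,
    RangeError,
    UndefinedOSIError,
)
from .mesh_io import FieldSeries, InletPlane, SurfaceMesh
from .sampling import SamplePointSet, measure_at_points


@dataclass
class InletReference:
    """Inlet-plane averages used as normalization denominators."""

    pressure_ave_inlet: float
    wss_ave_inlet: float
    snapshot_time: float


def select_peak_systole(times, flow, cycle_index: int, period_T: float) -> float:
    """Time of maximum flow rate within the requested cardiac cycle.

    ``cycle_index`` is 1-based (the reference protocol uses the second
    cycle). Ties break to the earliest time.
    """
    times = np.asarray(times, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if cycle_index < 1:
        raise RangeError("cycle_index is 1-based and must be >= 1")
    t0 = (cycle_index - 1) * period_T
    t1 = cycle_index * period_T
    eps = 1e-9 * period_T
    mask = (times >= t0 - eps) & (times <= t1 + eps)
    if not mask.any() or times.min() > t0 + eps or times.max() < t1 - eps:
        raise RangeError(
            f"waveform does not cover cycle {cycle_index} "
            f"([{t0:g}, {t1:g}] s)"
        )
    tw = times[mask]
    fw = flow[mask]
    return float(tw[np.argmax(fw)])  # argmax returns the first maximum


def inlet_average(
    mesh: SurfaceMesh,
    inlet: InletPlane,
    vertex_field: np.ndarray,
    weighted: bool = True,
) -> float:
    """Area-weighted mean of a field over the inlet member vertices.

    Scalar fields are averaged directly; vector fields (n, 3) are averaged
    by magnitude. ``weighted=False`` gives the plain vertex-count mean.
    """
    vertex_field = np.asarray(vertex_field, dtype=float)
    values = vertex_field[inlet.member_vertices]
    if values.ndim == 2:
        values = np.linalg.norm(values, axis=1)
    if weighted:
        w = mesh.vertex_areas[inlet.member_vertices]
    else:
        w = np.ones(len(values))
    total = w.sum()
    if total <= 0:
        raise DegenerateInletError("inlet averaging weights sum to zero")
    return float((values * w).sum() / total)


def normalize(value, reference: float):
    """Divide a value (or array) by a positive inlet reference."""
    if reference <= 0:
        raise NormalizationError(f"normalization reference {reference} is not > 0")
    return np.asarray(value, dtype=float) / reference


def tawss(tau: np.ndarray, times: np.ndarray) -> float:
    """Time-averaged WSS magnitude over the supplied cycle samples (Pa)."""
    tau = np.asarray(tau, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise InsufficientDataError("TAWSS needs at least 2 time samples")
    mag = np.linalg.norm(tau, axis=-1) if tau.ndim > 1 else np.abs(tau)
    span = times[-1] - times[0]
    return float(np.trapezoid(mag, times) / span)


def osi(tau: np.ndarray, times: np.ndarray) -> float:
    """Oscillatory shear index in [0, 0.5] for one WSS vector time series."""
    tau = np.asarray(tau, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise InsufficientDataError("OSI needs at least 2 time samples")
    mag_int = np.trapezoid(np.linalg.norm(tau, axis=1), times)
    if mag_int <= 0:
        raise UndefinedOSIError("WSS is identically zero over the cycle")
    vec_int = np.trapezoid(tau, times, axis=0)
    val = 0.5 * (1.0 - np.linalg.norm(vec_int) / mag_int)
    if abs(val) < 1e-12:  # unidirectional fields are exactly 0
        return 0.0
    return float(np.clip(val, 0.0, 0.5))


def inlet_reference(
    mesh: SurfaceMesh,
    inlet: InletPlane,
    fields: FieldSeries,
    snapshot_time: float,
    weighted: bool = True,
) -> InletReference:
    """Build the normalization reference at the chosen snapshot."""
    k = fields.index_at_time(snapshot_time)
    return InletReference(
        pressure_ave_inlet=inlet_average(mesh, inlet, fields.pressure[k], weighted),
        wss_ave_inlet=inlet_average(mesh, inlet, fields.wss[k], weighted),
        snapshot_time=snapshot_time,
    )


def compute_point_records(
    points: SamplePointSet,
    mesh: SurfaceMesh,
    fields: FieldSeries,
    reference: InletReference,
) -> SamplePointSet:
    """Fill per-point hemodynamic records.

    Normalized pressure and WSS are instantaneous at the snapshot; TAWSS
    and OSI integrate the full supplied cycle. Points where WSS vanishes
    identically over the cycle get OSI = NaN (excluded from statistics).
    """
    fields.check_alignment(mesh)
    k = fields.index_at_time(reference.snapshot_time)
    p_snap = measure_at_points(points, mesh, fields.pressure[k])
    wss_snap = measure_at_points(points, mesh, fields.wss[k])
    np_snap = normalize(p_snap, reference.pressure_ave_inlet)
    nw_snap = normalize(
        np.linalg.norm(wss_snap, axis=1), reference.wss_ave_inlet
    )
    # (n_t, n_p, 3) WSS time series at the sample points
    tau_pts = np.stack(
        [measure_at_points(points, mesh, fields.wss[t]) for t in range(fields.n_times)]
    )
    for i, rec in enumerate(points.records):
        rec.normalized_pressure = float(np_snap[i])
        rec.normalized_wss = float(nw_snap[i])
        rec.tawss = tawss(tau_pts[:, i, :], fields.times)
        try:
            rec.osi = osi(tau_pts[:, i, :], fields.times)
        except UndefinedOSIError:
            rec.osi = float("nan")
    return points
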