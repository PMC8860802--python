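"""Tangential WSS vector-field analysis: divergence and source detection.

A "center of divergent WSS vectors" is a surface location where the
tangential WSS field points radially outward in every direction — a source
of the surface vector field. Detection proceeds in three steps:

1. project the WSS vectors into the local tangent plane (WSS is tangential
   by definition; projection removes numerical normal components),
2. compute a discrete surface divergence: per-face constant divergence from
   the linear-shape-function gradient, area-averaged to vertices,
3. flag vertices that are local maxima of divergence above a percentile
   threshold, whose one-ring field points outward on a sufficient fraction
   of edges, and that are mutually separated by a minimum distance.

The detection thresholds are explicit, reproducible surrogates for the
visual identification used in the clinical workflow; boundary (neck-ring)
vertices are excluded to avoid spurious boundary maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AssignmentError
from .mesh_io import SurfaceMesh
from .sampling import SamplePointSet

#: Default detection parameters.
MIN_DIVERGENCE_PERCENTILE = 95.0
MIN_SEPARATION_MM = 1.0
OUTFLOW_FRACTION_THRESHOLD = 0.8


@dataclass
class DivergenceCenter:
    """A detected source of the tangential WSS field."""

    location: np.ndarray  # mm, on the surface
    vertex_id: int
    divergence_value: float  # Pa/mm
    region: str | None = None
    assigned_point_id: int | None = None


def tangential_projection(mesh: SurfaceMesh, vectors: np.ndarray) -> np.ndarray:
    """Remove the vertex-normal component from a per-vertex vector field."""
    vectors = np.asarray(vectors, dtype=float)
    n = mesh.vertex_normals
    return vectors - (np.einsum("ij,ij->i", vectors, n))[:, None] * n


def surface_divergence(mesh: SurfaceMesh, tangential: np.ndarray) -> np.ndarray:
    """Discrete surface divergence of a tangential field (Pa/mm).

    Per face, the field is interpolated linearly from the vertices; its
    divergence is the constant sum_i grad(phi_i) . F_i with hat-function
    gradients grad(phi_i) = (N x e_i) / (2A), where e_i is the edge
    opposite vertex i and N the unit face normal. Face values are averaged
    to vertices with area weights. Degenerate (zero-area) faces are
    excluded with a warning.
    """
    tangential = np.asarray(tangential, dtype=float)
    v = mesh.vertices
    f = mesh.faces
    e0 = v[f[:, 2]] - v[f[:, 1]]  # opposite vertex 0
    e1 = v[f[:, 0]] - v[f[:, 2]]
    e2 = v[f[:, 1]] - v[f[:, 0]]
    normal = np.cross(e2, -e1)  # (b-a) x (c-a), length 2A
    twoA = np.linalg.norm(normal, axis=1)
    good = twoA > 1e-12
    if not good.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~good)} degenerate faces "
            "from surface divergence",
            stacklevel=2,
        )
    nhat = np.zeros_like(normal)
    nhat[good] = normal[good] / twoA[good, None]
    div_face = np.zeros(len(f))
    for k, e in enumerate((e0, e1, e2)):
        grad = np.cross(nhat, e) / np.where(twoA > 1e-12, twoA, 1.0)[:, None]
        div_face += np.einsum("ij,ij->i", grad, tangential[f[:, k]])
    div_face[~good] = 0.0

    # area-weighted average of incident-face divergence at each vertex
    w = (0.5 * twoA) * good
    num = np.zeros(mesh.n_vertices)
    den = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(num, f[:, k], w * div_face)
        np.add.at(den, f[:, k], w)
    den[den == 0] = 1.0
    return num / den


def find_divergence_centers(
    mesh: SurfaceMesh,
    tangential: np.ndarray,
    divergence: np.ndarray,
    min_divergence_percentile: float = MIN_DIVERGENCE_PERCENTILE,
    min_separation_mm: float = MIN_SEPARATION_MM,
    outflow_fraction_threshold: float = OUTFLOW_FRACTION_THRESHOLD,
    candidate_mask: np.ndarray | None = None,
    local_max_slack: float = 0.1,
) -> list[DivergenceCenter]:
    """Detect sources of the tangential WSS field.

    A vertex is a center when it (a) is a local maximum of divergence
    (up to a plateau slack of ``local_max_slack`` times its own value,
    which makes localization robust to vertex noise on flat peaks) above
    the ``min_divergence_percentile`` of the candidate region, (b) has
    outward-pointing field (positive component along the
    outgoing edge) on at least ``outflow_fraction_threshold`` of its
    one-ring edges, and (c) lies at least ``min_separation_mm`` from any
    stronger accepted center. Boundary vertices are always excluded.
    Returns centers sorted by descending divergence; empty list is valid.
    """
    tangential = np.asarray(tangential, dtype=float)
    divergence = np.asarray(divergence, dtype=float)
    mask = np.ones(mesh.n_vertices, dtype=bool)
    if candidate_mask is not None:
        mask &= np.asarray(candidate_mask, dtype=bool)
    mask[mesh.boundary_vertices()] = False
    if not mask.any():
        return []
    thresh = np.percentile(divergence[mask], min_divergence_percentile)
    adjacency = mesh.vertex_adjacency()

    candidates = []
    for i in np.flatnonzero(mask & (divergence >= thresh) & (divergence > 0)):
        nbrs = adjacency[i]
        slack = local_max_slack * abs(divergence[i])
        if len(nbrs) == 0 or np.any(divergence[nbrs] > divergence[i] + slack):
            continue
        edge_dir = mesh.vertices[nbrs] - mesh.vertices[i]
        outflow = np.einsum("ij,ij->i", tangential[nbrs], edge_dir) > 0
        if outflow.mean() < outflow_fraction_threshold:
            continue
        candidates.append(i)

    candidates.sort(key=lambda i: -divergence[i])
    centers: list[DivergenceCenter] = []
    for i in candidates:
        if any(
            np.linalg.norm(mesh.vertices[i] - c.location) < min_separation_mm
            for c in centers
        ):
            continue
        region = None
        if mesh.region_label is not None:
            region = str(mesh.region_label[i])
        centers.append(
            DivergenceCenter(
                location=mesh.vertices[i].copy(),
                vertex_id=int(i),
                divergence_value=float(divergence[i]),
                region=region,
            )
        )
    return centers


def flag_center_points(
    points: SamplePointSet, centers: list[DivergenceCenter]
) -> SamplePointSet:
    """Mark, for each center, the nearest sample point as ``is_center``.

    Each sample point may represent at most one center; a collision means
    the sampling is too coarse relative to the center separation. Ties in
    distance resolve to the lower point id.
    """
    for rec in points.records:
        rec.is_center = False
    taken: dict[int, DivergenceCenter] = {}
    for center in centers:
        d = np.linalg.norm(points.points - center.location, axis=1)
        pid = int(np.argmin(d))  # first minimum = lowest point id on ties
        if pid in taken:
            raise AssignmentError(
                f"centers at vertices {taken[pid].vertex_id} and "
                f"{center.vertex_id} both map to sample point {pid}; "
                "increase sampling density"
            )
        taken[pid] = center
        center.assigned_point_id = pid
        points.records[pid].is_center = True
    return points


def centers_to_dataframe(centers: list[DivergenceCenter]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center_id": np.arange(len(centers)),
            "x": [c.location[0] for c in centers],
            "y": [c.location[1] for c in centers],
            "z": [c.location[2] for c in centers],
            "vertex_id": [c.vertex_id for c in centers],
            "divergence": [c.divergence_value for c in centers],
            "region": [c.region for c in centers],
            "assigned_point_id": [c.assigned_point_id for c in centers],
        }
    )
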