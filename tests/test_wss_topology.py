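import numpy as np
import pytest

from blebpoint import (
    distribute_points,
    find_divergence_centers,
    flag_center_points,
    label_points,
    make_fields,
    surface_divergence,
    tangential_projection,
)
from blebpoint.exceptions import AssignmentError
from blebpoint.mesh_io import BLEB, NONBLEB
from blebpoint.wss_topology import DivergenceCenter


class TestTangentialProjection:
    def test_pure_normal_field_vanishes(self, dome_case):
        mesh, _ = dome_case
        out = tangential_projection(mesh, mesh.vertex_normals.copy())
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_idempotent_on_tangential_field(self, dome_case):
        mesh, _ = dome_case
        rng = np.random.default_rng(1)
        field = tangential_projection(mesh, rng.normal(size=(mesh.n_vertices, 3)))
        again = tangential_projection(mesh, field)
        np.testing.assert_allclose(again, field, atol=1e-9)

    def test_result_orthogonal_to_normals(self, dome_case):
        mesh, _ = dome_case
        rng = np.random.default_rng(2)
        out = tangential_projection(mesh, rng.normal(size=(mesh.n_vertices, 3)))
        dots = np.einsum("ij,ij->i", out, mesh.vertex_normals)
        np.testing.assert_allclose(dots, 0.0, atol=1e-9)


class TestSurfaceDivergence:
    def test_uniform_field_zero_at_interior(self, planar_grid):
        field = np.tile([1.3, -0.7, 0.0], (planar_grid.n_vertices, 1))
        div = surface_divergence(planar_grid, field)
        interior = np.setdiff1d(
            np.arange(planar_grid.n_vertices), planar_grid.boundary_vertices()
        )
        np.testing.assert_allclose(div[interior], 0.0, atol=1e-9)

    def test_planar_radial_field_divergence_two(self, planar_grid):
        """F(x, y) = (x, y) has divergence exactly 2."""
        field = planar_grid.vertices.copy()
        field[:, 2] = 0.0
        div = surface_divergence(planar_grid, field)
        interior = np.setdiff1d(
            np.arange(planar_grid.n_vertices), planar_grid.boundary_vertices()
        )
        np.testing.assert_allclose(div[interior], 2.0, rtol=0.05)

    def test_divergence_theorem_on_closed_surface(self):
        """Integral of the discrete divergence over a closed surface ~ 0."""
        import trimesh

        from blebpoint.mesh_io import SurfaceMesh

        tm = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        field = tangential_projection(
            mesh, np.column_stack([-mesh.vertices[:, 1], mesh.vertices[:, 0],
                                   np.full(mesh.n_vertices, 0.4)])
        )
        div = surface_divergence(mesh, field)
        total = (div * mesh.vertex_areas).sum()
        scale = (np.abs(div) * mesh.vertex_areas).sum() + 1e-12
        assert abs(total) / scale < 0.05

    def test_planted_source_peaks_at_source_vertex(
        self, dome_case, dome_fields, default_spec
    ):
        mesh, _ = dome_case
        fields, truth = dome_fields
        k = fields.index_at_time(default_spec.peak_time)
        tang = tangential_projection(mesh, fields.wss[k])
        div = surface_divergence(mesh, tang)
        dome = np.isin(mesh.region_label, [BLEB, NONBLEB])
        top = mesh.vertices[np.argmax(np.where(dome, div, -np.inf))]
        d = np.linalg.norm(truth.source_points - top, axis=1).min()
        assert d <= 2 * default_spec.mesh_edge_length_mm


class TestFindCenters:
    def test_uniform_field_gives_no_centers(self, planar_grid):
        field = np.tile([1.0, 0.5, 0.0], (planar_grid.n_vertices, 1))
        div = surface_divergence(planar_grid, field)
        assert find_divergence_centers(planar_grid, field, div) == []

    def test_two_planted_sources_detected(
        self, dome_case, dome_fields, default_spec
    ):
        mesh, _ = dome_case
        fields, truth = dome_fields
        k = fields.index_at_time(default_spec.peak_time)
        tang = tangential_projection(mesh, fields.wss[k])
        div = surface_divergence(mesh, tang)
        dome = np.isin(mesh.region_label, [BLEB, NONBLEB])
        centers = find_divergence_centers(mesh, tang, div, candidate_mask=dome)
        assert len(centers) == 2
        for src in truth.source_points:
            d = min(np.linalg.norm(c.location - src) for c in centers)
            assert d <= 2 * 0.5  # within twice the sampling spacing
        regions = sorted(c.region for c in centers)
        assert regions == [BLEB, NONBLEB]

    def test_detection_invariant_under_field_scaling(
        self, dome_case, dome_fields, default_spec
    ):
        mesh, _ = dome_case
        fields, _ = dome_fields
        k = fields.index_at_time(default_spec.peak_time)
        tang = tangential_projection(mesh, fields.wss[k])
        dome = np.isin(mesh.region_label, [BLEB, NONBLEB])
        ids = [
            c.vertex_id
            for c in find_divergence_centers(
                mesh, tang, surface_divergence(mesh, tang), candidate_mask=dome
            )
        ]
        scaled = 7.3 * tang
        ids2 = [
            c.vertex_id
            for c in find_divergence_centers(
                mesh, scaled, surface_divergence(mesh, scaled), candidate_mask=dome
            )
        ]
        assert ids == ids2

    def test_recovery_across_seeds(self, dome_case, default_spec):
        """Detected center within 2x spacing of the planted source for
        every tested noise realization."""
        mesh, truth0 = dome_case
        hits = 0
        seeds = range(5)
        for seed in seeds:
            fields, truth = make_fields(mesh, truth0, default_spec, seed=seed)
            k = fields.index_at_time(default_spec.peak_time)
            tang = tangential_projection(mesh, fields.wss[k])
            div = surface_divergence(mesh, tang)
            dome = np.isin(mesh.region_label, [BLEB, NONBLEB])
            centers = find_divergence_centers(mesh, tang, div, candidate_mask=dome)
            d = max(
                min(np.linalg.norm(c.location - s) for c in centers)
                for s in truth.source_points
            )
            hits += d <= 2 * 0.5
        assert hits == len(seeds)


class TestFlagCenterPoints:
    def _points(self, dome_case):
        mesh, _ = dome_case
        pts = distribute_points(mesh, {BLEB, NONBLEB}, 0.5, seed=0)
        return label_points(pts, mesh)

    def test_no_centers_all_false(self, dome_case):
        pts = flag_center_points(self._points(dome_case), [])
        assert not pts.is_center.any()

    def test_one_center_per_region_counts(
        self, dome_case, dome_fields, default_spec
    ):
        mesh, _ = dome_case
        fields, _ = dome_fields
        k = fields.index_at_time(default_spec.peak_time)
        tang = tangential_projection(mesh, fields.wss[k])
        div = surface_divergence(mesh, tang)
        dome = np.isin(mesh.region_label, [BLEB, NONBLEB])
        centers = find_divergence_centers(mesh, tang, div, candidate_mask=dome)
        pts = flag_center_points(self._points(dome_case), centers)
        flagged_regions = sorted(pts.region[pts.is_center])
        assert flagged_regions == [BLEB, NONBLEB]
        assert all(c.assigned_point_id is not None for c in centers)

    def test_tie_goes_to_lower_point_id(self):
        from blebpoint.sampling import SamplePointSet

        pts = SamplePointSet(
            points=np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            anchor_faces=np.array([0, 0]),
            anchor_bary=np.array([[1.0, 0, 0], [1.0, 0, 0]]),
            spacing_d=1.0,
        )
        center = DivergenceCenter(np.array([1.0, 0, 0]), 0, 1.0)
        flag_center_points(pts, [center])
        assert pts.records[0].is_center and not pts.records[1].is_center

    def test_colliding_centers_rejected(self, dome_case):
        pts = self._points(dome_case)
        target = pts.points[3]
        c1 = DivergenceCenter(target + 1e-4, 0, 1.0)
        c2 = DivergenceCenter(target - 1e-4, 1, 0.9)
        with pytest.raises(AssignmentError):
            flag_center_points(pts, [c1, c2])
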