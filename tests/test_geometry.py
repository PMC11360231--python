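"""Contour averaging/interpolation, polar meshing, and IDW transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumorperf.geometry import (average_contours, idw_interpolate,
                                interpolate_contours, mesh_polygon,
                                mesh_rectangle, polygon_area, resample_star,
                                star_radii, transfer_fields)
from conftest import circle


class TestAverageContours:
    def test_identical_contours(self):
        c = resample_star(circle(50.0), 64)
        avg = average_contours([c, c, c], n_angles=64)
        assert np.allclose(avg, c, atol=1e-9)

    def test_mean_of_circle_radii(self):
        avg = average_contours([circle(40.0), circle(60.0)], n_angles=128)
        r = np.linalg.norm(avg, axis=1)
        assert np.allclose(r, 50.0, atol=0.1)

    def test_translation_invariance(self):
        # shift-and-compare oracle: centroid alignment removes translation
        c1 = circle(40.0)
        c2 = circle(60.0)
        a = average_contours([c1, c2])
        b = average_contours([c1 + [123.0, -45.0], c2 + [-7.0, 89.0]])
        assert np.allclose(a, b, atol=1e-6)

    def test_scale_normalization(self):
        avg = average_contours([circle(30.0), circle(60.0)],
                               normalize_scale=True)
        # with normalization the mean shape has the mean area
        target = np.mean([np.pi * 30.0**2, np.pi * 60.0**2])
        assert abs(polygon_area(avg)) == pytest.approx(target, rel=0.01)

    def test_non_star_rejected(self):
        L = np.array([[0, 0], [4, 0], [4, 1], [1, 1], [1, 4], [0, 4]], float)
        with pytest.raises(ValueError):
            average_contours([L])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_contours([])


class TestInterpolateContours:
    def test_endpoints_exact(self):
        cA = resample_star(circle(40.0), 64)
        cB = resample_star(circle(60.0), 64)
        assert np.array_equal(interpolate_contours(cA, cB, 0.0), cA)
        assert np.array_equal(interpolate_contours(cA, cB, 1.0), cB)

    def test_circle_midpoint(self):
        cA = resample_star(circle(40.0), 64)
        cB = resample_star(circle(60.0), 64)
        mid = interpolate_contours(cA, cB, 0.5)
        rA = np.linalg.norm(cA, axis=1)
        rB = np.linalg.norm(cB, axis=1)
        assert np.allclose(np.linalg.norm(mid, axis=1), (rA + rB) / 2,
                           rtol=1e-12)
        assert np.allclose(np.linalg.norm(mid, axis=1), 50.0, rtol=1e-3)

    def test_alpha_out_of_range(self):
        c = resample_star(circle(40.0), 64)
        with pytest.raises(ValueError):
            interpolate_contours(c, c, 1.5)

    def test_mismatched_nodes(self):
        with pytest.raises(ValueError):
            interpolate_contours(resample_star(circle(40.0), 64),
                                 resample_star(circle(60.0), 32), 0.5)


class TestMeshPolygon:
    def test_circle_area(self):
        # unit-area circle meshed at 16x32
        R = 1.0 / np.sqrt(np.pi)
        mesh = mesh_polygon(circle(R), 16, 32)
        assert mesh.area == pytest.approx(1.0, rel=0.005)

    def test_jacobians_positive(self):
        s_mesh = mesh_polygon(circle(100.0), 8, 16)
        s_mesh.check_jacobians()  # raises on failure

    def test_refinement_reduces_area_error(self):
        c = circle(100.0)
        true = np.pi * 100.0**2
        errs = [abs(mesh_polygon(c, n, 2 * n,
                                 preserve_area=False).area - true) / true
                for n in (8, 16, 32)]
        assert errs[0] > errs[1] > errs[2]

    def test_boundary_nodes_on_contour(self):
        mesh = mesh_polygon(circle(100.0), 8, 16, preserve_area=False)
        r = np.linalg.norm(mesh.nodes[mesh.boundary_nodes], axis=1)
        assert np.allclose(r, 100.0, rtol=1e-9)

    def test_tributary_volumes_partition(self):
        mesh = mesh_polygon(circle(80.0), 6, 12, h_z=2.0)
        V = mesh.node_tributary_volumes()
        assert np.all(V > 0)
        assert V.sum() == pytest.approx(mesh.area * 2.0)

    def test_degenerate_contour(self):
        bad = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            mesh_polygon(bad, 4, 8)

    def test_min_resolution(self):
        with pytest.raises(ValueError):
            mesh_polygon(circle(10.0), 1, 8)
        with pytest.raises(ValueError):
            mesh_polygon(circle(10.0), 4, 4)


class TestMeshRectangle:
    def test_area_and_counts(self):
        mesh = mesh_rectangle(10.0, 2.0, 5, 2)
        assert mesh.area == pytest.approx(20.0)
        assert mesh.n_elements == 10
        assert len(mesh.boundary_nodes) == 14


class TestIDW:
    def test_exact_at_samples(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        vals = np.array([1.0, 2.0, 3.0])
        out = idw_interpolate(pts, vals, pts)
        assert np.array_equal(out, vals)

    def test_midpoint_symmetry(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        out = idw_interpolate(pts, np.array([0.0, 10.0]),
                              np.array([[1.0, 0.0]]))
        assert out[0] == pytest.approx(5.0)

    def test_constant_preserved(self):
        rng = np.random.default_rng(0)
        pts = rng.random((20, 2))
        out = idw_interpolate(pts, np.full(20, 7.5), rng.random((50, 2)))
        assert np.allclose(out, 7.5)

    def test_duplicate_conflict(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            idw_interpolate(pts, np.array([1.0, 2.0]),
                            np.array([[0.5, 0.5]]))

    def test_bad_power(self):
        with pytest.raises(ValueError):
            idw_interpolate(np.zeros((1, 2)), np.zeros(1),
                            np.ones((1, 2)), power=0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_bounded_by_extrema(self, seed):
        # no-overshoot property of Shepard interpolation
        rng = np.random.default_rng(seed)
        pts = rng.random((10, 2))
        vals = rng.normal(size=10)
        q = rng.random((30, 2)) * 2 - 0.5
        out = idw_interpolate(pts, vals, q)
        assert np.all(out >= vals.min() - 1e-12)
        assert np.all(out <= vals.max() + 1e-12)

    def test_knearest_matches_full_when_k_large(self):
        rng = np.random.default_rng(3)
        pts = rng.random((15, 2))
        vals = rng.normal(size=15)
        q = rng.random((8, 2))
        full = idw_interpolate(pts, vals, q)
        k = idw_interpolate(pts, vals, q, k=15)
        assert np.allclose(full, k)


class TestTransferFields:
    def test_identity_on_same_mesh(self):
        mesh = mesh_polygon(circle(100.0), 6, 12)
        f = np.sin(mesh.nodes[:, 0] / 30.0)
        out = transfer_fields(mesh, f, mesh)
        assert np.allclose(out, f)

    def test_constant_preserved(self):
        m1 = mesh_polygon(circle(100.0), 6, 12)
        m2 = mesh_polygon(circle(110.0), 8, 16)
        out = transfer_fields(m1, np.full(m1.n_nodes, 3.3), m2)
        assert np.allclose(out, 3.3)

    def test_linear_field_refinement(self):
        # transferring p = x: error shrinks as the source mesh refines
        target = mesh_polygon(circle(95.0), 10, 20)
        errs = []
        for n in (6, 12, 24):
            src = mesh_polygon(circle(100.0), n, 2 * n)
            out = transfer_fields(src, src.nodes[:, 0], target)
            errs.append(np.abs(out - target.nodes[:, 0]).max())
        assert errs[0] > errs[1] > errs[2]

    def test_empty_source(self):
        mesh = mesh_polygon(circle(100.0), 6, 12)
        from tumorperf.geometry import Mesh
        empty = Mesh(nodes=np.empty((0, 2)), quads=np.empty((0, 4), int),
                     tris=np.empty((0, 3), int),
                     boundary_nodes=np.empty(0, int))
        with pytest.raises(ValueError):
            transfer_fields(empty, np.empty(0), mesh)


class TestRemeshingAreaPreservation:
    def test_irregular_contour_area_kept(self):
        from tumorperf.synth import gen_contour_series
        s = gen_contour_series(seed=5, irregularity=0.2, eccentricity=1.5)
        for c in s.contours:
            mesh = mesh_polygon(c, 12, 24)
            assert mesh.area == pytest.approx(abs(polygon_area(c)), rel=0.005)
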