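"""Smeared-parameter mapping: fractions, conductances, Darcy tensors."""

import numpy as np
import pytest

from tumorperf.geometry import mesh_polygon
from tumorperf.params import (connectivity_matrix, darcy_tensor_capillary,
                              darcy_tensor_tissue, nodal_params_from_heatmaps,
                              rex_from_fractions, rvcap_from_coverage,
                              uniform_nodal_params)
from tumorperf.synth import FieldSpec, gen_heatmaps
from conftest import circle


class TestRvcap:
    def test_reference_value(self):
        assert rvcap_from_coverage(4.0, 5.0, 1.0) == pytest.approx(0.05)

    def test_zero_coverage(self):
        assert rvcap_from_coverage(0.0, 5.0) == 0.0

    def test_unphysical_combination(self):
        with pytest.raises(ValueError):
            rvcap_from_coverage(50.0, 10.0, 1.0)  # 1.25 > 1

    def test_thickness_scaling(self):
        assert rvcap_from_coverage(4.0, 5.0, 2.0) == pytest.approx(0.025)

    def test_missing_diameter_with_coverage(self):
        with pytest.raises(ValueError):
            rvcap_from_coverage(4.0, 0.0)


class TestRex:
    def test_closure(self):
        assert rex_from_fractions(0.05, 0.75) == pytest.approx(0.20)

    def test_empty(self):
        assert rex_from_fractions(0.0, 0.0) == 1.0

    def test_overfull(self):
        with pytest.raises(ValueError):
            rex_from_fractions(0.6, 0.5)

    def test_machine_precision_closure(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.2, 100)
        b = rng.uniform(0, 0.7, 100)
        r = rex_from_fractions(a, b)
        # closure holds to a couple of ulp of 1.0
        assert np.abs(a + b + r - 1.0).max() <= 4 * np.finfo(float).eps


class TestConnectivity:
    def test_reference_conductance(self):
        # wall area (4 r V / d) times h: 4*0.05*1e4/10 * 1.57e-3 = 0.314
        K = connectivity_matrix(10.0, 0.05, 1.0e4, 1.57e-3)
        assert K[0, 0] == pytest.approx(0.314)
        assert np.allclose(K, K[0, 0] * np.array([[1, -1], [-1, 1]]))

    def test_impermeable_wall(self):
        assert np.all(connectivity_matrix(10.0, 0.05, 1e4, 0.0) == 0.0)

    def test_row_sums_zero(self):
        K = connectivity_matrix(7.0, 0.02, 5e3, 2e-3)
        assert np.allclose(K.sum(axis=1), 0.0)

    def test_scalings(self):
        base = connectivity_matrix(10.0, 0.05, 1e4, 1.57e-3)[0, 0]
        assert connectivity_matrix(10.0, 0.10, 1e4, 1.57e-3)[0, 0] == \
            pytest.approx(2 * base)
        assert connectivity_matrix(10.0, 0.05, 2e4, 1.57e-3)[0, 0] == \
            pytest.approx(2 * base)
        assert connectivity_matrix(10.0, 0.05, 1e4, 3.14e-3)[0, 0] == \
            pytest.approx(2 * base)
        assert connectivity_matrix(20.0, 0.05, 1e4, 1.57e-3)[0, 0] == \
            pytest.approx(base / 2)

    def test_zero_diameter_with_fraction(self):
        with pytest.raises(ValueError):
            connectivity_matrix(0.0, 0.05, 1e4)


class TestDarcyTensors:
    def test_tissue_identity(self):
        assert np.array_equal(darcy_tensor_tissue(1.0), np.eye(2))
        assert np.all(darcy_tensor_tissue(0.0) == 0.0)

    def test_tissue_negative(self):
        with pytest.raises(ValueError):
            darcy_tensor_tissue(-1.0)

    def test_capillary_zero_diameter(self):
        assert np.all(darcy_tensor_capillary(0.0) == 0.0)

    def test_aligned_with_x(self):
        T = darcy_tensor_capillary(10.0, orientation=(1.0, 0.0), mu=3e-3)
        assert T[0, 1] == 0.0 and T[1, 1] == 0.0
        assert T[0, 0] == pytest.approx(100.0 / (32 * 3e-3))

    def test_isotropic_trace_is_orientation_average(self):
        # orientation-average oracle: mean of aligned tensors over uniform
        # directions equals the isotropic tensor
        d, mu = 8.0, 3e-3
        angles = np.linspace(0, np.pi, 720, endpoint=False)
        avg = np.mean([darcy_tensor_capillary(d, (np.cos(a), np.sin(a)), mu)
                       for a in angles], axis=0)
        iso = darcy_tensor_capillary(d, None, mu)
        assert np.allclose(avg, iso, atol=1e-12 + 1e-6 * iso[0, 0])
        assert np.trace(iso) == pytest.approx(d * d / (32 * mu))

    def test_psd(self):
        for d in (0.0, 5.0, 20.0):
            for ori in (None, (1, 1), (0.3, -2.0)):
                T = darcy_tensor_capillary(d, ori)
                assert np.all(np.linalg.eigvalsh(T) >= -1e-12)


class TestNodalParams:
    def test_uniform_heatmap_constants(self):
        contour = circle(200.0)
        mesh = mesh_polygon(contour, 8, 16)
        hm = gen_heatmaps(contour, (9, 9),
                          FieldSpec(vasculature=4.0, diameter=5.0,
                                    perfusion=75.0), seed=0)
        p = nodal_params_from_heatmaps(hm, mesh)
        assert np.allclose(p.r_vcap, 0.05)
        assert np.allclose(p.r_vcell, 0.75)
        assert np.allclose(p.r_ex, 0.20)

    def test_tributary_volume_partition(self):
        contour = circle(200.0)
        mesh = mesh_polygon(contour, 8, 16)
        hm = gen_heatmaps(contour, (9, 9), FieldSpec(), seed=0)
        p = nodal_params_from_heatmaps(hm, mesh)
        assert p.V.sum() == pytest.approx(mesh.area * mesh.h_z)

    def test_fraction_closure_everywhere(self):
        contour = circle(200.0)
        mesh = mesh_polygon(contour, 8, 16)
        hm = gen_heatmaps(
            contour, (9, 9),
            FieldSpec(vasculature=lambda x, y: 3 + 2 * x,
                      vasculature_sd=0.5, diameter=5.0, diameter_sd=0.4,
                      perfusion=lambda x, y: 70 + 5 * y, perfusion_sd=2.0),
            seed=4)
        p = nodal_params_from_heatmaps(hm, mesh)
        assert np.allclose(p.r_vcap + p.r_vcell + p.r_ex, 1.0, atol=1e-15)

    def test_missing_diameter_filled_by_idw(self):
        # held-out-cell recovery: blank one cell's diameter, the nodal
        # field still lands within the range of the informed cells
        contour = circle(200.0)
        mesh = mesh_polygon(contour, 8, 16)
        hm = gen_heatmaps(contour, (9, 9),
                          FieldSpec(diameter=lambda x, y: 5.0 + 2.0 * x),
                          seed=0)
        hm.diameter_um[4, 4] = np.nan
        p = nodal_params_from_heatmaps(hm, mesh)
        informed = hm.diameter_um[hm.mask & np.isfinite(hm.diameter_um)]
        assert np.all(p.d_cap >= informed.min() - 1e-9)
        assert np.all(p.d_cap <= informed.max() + 1e-9)

    def test_overfull_node_named(self):
        contour = circle(200.0)
        mesh = mesh_polygon(contour, 8, 16)
        hm = gen_heatmaps(contour, (9, 9),
                          FieldSpec(vasculature=20.0, diameter=10.0,
                                    perfusion=90.0), seed=0)
        with pytest.raises(ValueError, match="node"):
            nodal_params_from_heatmaps(hm, mesh)

    def test_min_r_ex_caps_cell_fraction(self):
        # saturated perfusion stain: with a guaranteed extracellular
        # fraction the cell fraction is capped instead of erroring
        contour = circle(200.0)
        mesh = mesh_polygon(contour, 8, 16)
        hm = gen_heatmaps(contour, (9, 9),
                          FieldSpec(vasculature=20.0, diameter=10.0,
                                    perfusion=90.0), seed=0)
        p = nodal_params_from_heatmaps(hm, mesh, min_r_ex=0.05)
        assert np.allclose(p.r_vcap + p.r_vcell + p.r_ex, 1.0)
        assert np.all(p.r_ex >= 0.05 - 1e-12)
        assert np.allclose(p.r_vcell, 1.0 - 0.5 - 0.05)  # capped, r_vcap=0.5

    def test_uniform_helper_matches(self):
        mesh = mesh_polygon(circle(150.0), 6, 12)
        p = uniform_nodal_params(mesh)
        assert np.allclose(p.r_vcap + p.r_vcell + p.r_ex, 1.0)
        assert p.V.sum() == pytest.approx(mesh.area * mesh.h_z)

    def test_csv_export(self, tmp_path):
        mesh = mesh_polygon(circle(150.0), 4, 8)
        p = uniform_nodal_params(mesh)
        path = tmp_path / "params.csv"
        p.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert len(df) == mesh.n_nodes
        assert np.allclose(df["r_vcap"] + df["r_vcell"] + df["r_ex"], 1.0)
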