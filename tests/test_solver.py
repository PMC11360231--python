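"""Two-domain FE solver: element matrices, assembly, solutions, conservation."""

import numpy as np
import pytest
from scipy.special import ive

from tumorperf.geometry import mesh_polygon, mesh_rectangle
from tumorperf.params import bessel_length, uniform_nodal_params
from tumorperf.solver import (assemble_system, darcy_velocity,
                              element_conductivity, mass_balance,
                              solve_pressure)
from tumorperf.units import P_CAP_PA
from conftest import circle

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
# classical bilinear Laplace element on the unit square
K_LAPLACE_Q4 = np.array([
    [2 / 3, -1 / 6, -1 / 3, -1 / 6],
    [-1 / 6, 2 / 3, -1 / 6, -1 / 3],
    [-1 / 3, -1 / 6, 2 / 3, -1 / 6],
    [-1 / 6, -1 / 3, -1 / 6, 2 / 3],
])


def analytic_disc_pressure(r, R, lam, p_c=P_CAP_PA):
    """Krogh-type disc: p(r) = p_c [1 - I0(r/lam)/I0(R/lam)].

    Scaled Bessel functions keep the ratio finite for R >> lam.
    """
    return p_c * (1.0 - ive(0, r / lam) * np.exp((r - R) / lam)
                  / ive(0, R / lam))


def analytic_disc_speed(r, R, lam, k_t=1.0, p_c=P_CAP_PA):
    """|v|(r) = k_t p_c I1(r/lam) / (lam I0(R/lam)) on a disc of radius R."""
    return (k_t * p_c * ive(1, r / lam) * np.exp((r - R) / lam)
            / (lam * ive(0, R / lam)))


class TestElementConductivity:
    def test_unit_square_laplace(self):
        K = element_conductivity(UNIT_SQUARE, np.ones(4),
                                 np.broadcast_to(np.eye(2), (4, 2, 2)))
        assert np.allclose(K, K_LAPLACE_Q4)
        assert np.allclose(K.sum(axis=1), 0.0, atol=1e-14)

    def test_zero_fraction(self):
        K = element_conductivity(UNIT_SQUARE, np.zeros(4),
                                 np.broadcast_to(np.eye(2), (4, 2, 2)))
        assert np.all(K == 0.0)

    def test_linearity_in_kd(self):
        kD = np.broadcast_to(np.eye(2), (4, 2, 2))
        K1 = element_conductivity(UNIT_SQUARE, np.ones(4), kD)
        K3 = element_conductivity(UNIT_SQUARE, np.ones(4), 3.0 * kD)
        assert np.allclose(K3, 3.0 * K1)

    def test_triangle_row_sums(self):
        tri = np.array([[0.0, 0.0], [2.0, 0.0], [0.5, 1.5]])
        K = element_conductivity(tri, np.full(3, 0.4),
                                 np.broadcast_to(2.0 * np.eye(2), (3, 2, 2)))
        assert np.allclose(K.sum(axis=1), 0.0, atol=1e-14)
        assert np.allclose(K, K.T)

    def test_inverted_element_rejected(self):
        with pytest.raises(ValueError):
            element_conductivity(UNIT_SQUARE[::-1], np.ones(4),
                                 np.broadcast_to(np.eye(2), (4, 2, 2)))


class TestAssembly:
    def test_decoupled_when_impermeable(self):
        mesh = mesh_polygon(circle(100.0), 6, 12)
        params = uniform_nodal_params(mesh, h_cap=0.0)
        system = assemble_system(mesh, params)
        assert np.all(system.coupling == 0.0)
        K = system.global_matrix()
        n = mesh.n_nodes
        assert abs(K[:n, n:]).sum() == 0.0

    def test_symmetry_and_zero_row_sums(self):
        mesh = mesh_polygon(circle(100.0), 6, 12)
        params = uniform_nodal_params(mesh)
        K = assemble_system(mesh, params).global_matrix()
        assert abs(K - K.T).max() < 1e-12
        assert np.abs(K @ np.ones(K.shape[0])).max() < 1e-9


class TestSolve:
    def test_strip_laplace_profile(self):
        # decoupled 1D strip with fixed ends -> linear pressure
        mesh = mesh_rectangle(100.0, 5.0, 50, 1)
        params = uniform_nodal_params(mesh, h_cap=0.0)
        system = assemble_system(mesh, params)
        left = np.nonzero(mesh.nodes[:, 0] == 0.0)[0]
        right = np.nonzero(mesh.nodes[:, 0] == 100.0)[0]
        bcs = [(int(j), 2, 0.0) for j in left] + \
              [(int(j), 2, P_CAP_PA) for j in right]
        res = solve_pressure(system, extra_bcs=bcs,
                             ex_boundary_nodes=np.concatenate([left, right]))
        expected = mesh.nodes[:, 0] / 100.0 * P_CAP_PA
        assert np.allclose(res.p_ex, expected, atol=1e-8 * P_CAP_PA)

    def test_disc_matches_bessel(self, disc_solution):
        mesh, params, system, res = disc_solution
        lam = bessel_length(0.2, 1.0, 5.0, 0.05)
        r = np.linalg.norm(mesh.nodes, axis=1)
        pa = analytic_disc_pressure(r, 250.0, lam)
        err = np.sqrt(np.sum((res.p_ex - pa) ** 2) / np.sum(pa ** 2))
        assert err < 0.01

    def test_wall_dominated_limit(self):
        mesh = mesh_polygon(circle(250.0), 16, 32)
        params = uniform_nodal_params(mesh, h_cap=1.57)  # 1000x default
        res = solve_pressure(assemble_system(mesh, params))
        interior = np.linalg.norm(mesh.nodes, axis=1) < 150.0
        assert np.all(res.p_ex[interior] > 0.99 * P_CAP_PA)

    def test_impermeable_limit(self):
        mesh = mesh_polygon(circle(250.0), 8, 16)
        params = uniform_nodal_params(mesh, h_cap=0.0)
        res = solve_pressure(assemble_system(mesh, params))
        assert np.allclose(res.p_ex, 0.0, atol=1e-9)

    def test_no_dirichlet_is_singular(self):
        mesh = mesh_rectangle(10.0, 10.0, 3, 3)
        params = uniform_nodal_params(mesh, h_cap=0.0)
        system = assemble_system(mesh, params)
        with pytest.raises(ValueError):
            solve_pressure(system, fix_capillary_everywhere=False,
                           ex_boundary_nodes=np.empty(0, int))

    def test_maximum_principle(self, disc_solution):
        _, _, _, res = disc_solution
        assert np.all(res.p_ex >= -1e-9)
        assert np.all(res.p_ex <= P_CAP_PA + 1e-9)

    def test_monotone_in_coupling(self):
        mesh = mesh_polygon(circle(250.0), 12, 24)
        p_lo = solve_pressure(assemble_system(
            mesh, uniform_nodal_params(mesh, h_cap=1.57e-3))).p_ex
        p_hi = solve_pressure(assemble_system(
            mesh, uniform_nodal_params(mesh, h_cap=3.14e-3))).p_ex
        assert np.all(p_hi >= p_lo - 1e-9)

    def test_halfplane_anisotropy_raises_pressure(self):
        # doubling r_Vcap for x > 0 shifts the pressure field toward +x
        mesh = mesh_polygon(circle(250.0), 12, 24)
        params = uniform_nodal_params(mesh)
        right = mesh.nodes[:, 0] > 0
        params.r_vcap[right] *= 2
        params.r_ex[right] -= params.r_vcap[right] / 2  # keep closure
        res = solve_pressure(assemble_system(mesh, params))
        assert res.p_ex[right].mean() > res.p_ex[~right].mean()

    def test_residual_small(self, disc_solution):
        _, _, _, res = disc_solution
        assert res.residual < 1e-10


class TestDarcyVelocity:
    def test_uniform_pressure_zero_velocity(self):
        mesh = mesh_polygon(circle(100.0), 6, 12)
        kD = np.broadcast_to(np.eye(2), (mesh.n_nodes, 2, 2))
        v = darcy_velocity(mesh, np.full(mesh.n_nodes, 500.0), kD)
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_linear_pressure_constant_velocity(self):
        mesh = mesh_rectangle(10.0, 10.0, 5, 5)
        k = 2.5
        kD = np.broadcast_to(k * np.eye(2), (mesh.n_nodes, 2, 2))
        g = 3.0
        v = darcy_velocity(mesh, g * mesh.nodes[:, 0], kD)
        assert np.allclose(v[:, 0], -k * g)
        assert np.allclose(v[:, 1], 0.0, atol=1e-12)

    def test_disc_boundary_speed(self, disc_solution):
        mesh, params, system, res = disc_solution
        lam = bessel_length(0.2, 1.0, 5.0, 0.05)
        centers = mesh.element_centers()
        rc = np.linalg.norm(centers, axis=1)
        outer = rc > rc.max() - 4.0  # outermost ring of elements
        speed = np.linalg.norm(res.v_ex[outer], axis=1)
        expected = analytic_disc_speed(rc[outer].mean(), 250.0, lam)
        assert speed.mean() == pytest.approx(expected, rel=0.02)


class TestMassBalance:
    def test_conservation(self, disc_solution):
        _, _, system, res = disc_solution
        mb = mass_balance(res, system)
        assert mb.relative_imbalance < 1e-8

    def test_impermeable_zero_fluxes(self):
        mesh = mesh_polygon(circle(100.0), 6, 12)
        system = assemble_system(mesh, uniform_nodal_params(mesh, h_cap=0.0))
        mb = mass_balance(solve_pressure(system), system)
        assert mb.wall_influx == 0.0
        assert mb.boundary_outflux == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_p_cap(self):
        mesh = mesh_polygon(circle(100.0), 8, 16)
        system = assemble_system(mesh, uniform_nodal_params(mesh))
        mb1 = mass_balance(solve_pressure(system, p_cap_value=P_CAP_PA),
                           system)
        mb2 = mass_balance(solve_pressure(system, p_cap_value=2 * P_CAP_PA),
                           system)
        assert mb2.wall_influx == pytest.approx(2 * mb1.wall_influx)
        assert mb2.boundary_outflux == pytest.approx(2 * mb1.boundary_outflux)
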