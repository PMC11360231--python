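"""Composite smeared two-domain Darcy finite-element solver.

Two pressure fields share every mesh node: domain 1 is the capillary
network, domain 2 the extracellular space.  Each domain contributes a
standard Darcy stiffness

    K_IJ = integral_V  r_V  kD_ij  N_I,i N_J,j  dV

(2x2 Gauss on bilinear quads, one point on linear triangles, thickness
h_z), and at every node a fictitious zero-length "connectivity element"
couples the two domains with conductance k = (4 r_Vcap V / d) h_cap —
capillary wall area times wall hydraulic coefficient.  The global system

    [[K_cap + C, -C], [-C, K_ex + C]] [p_cap, p_ex] = Q

is symmetric with zero row sums before constraints (pure-Neumann
singular), so at least one Dirichlet condition is required.  In the
default configuration the capillary pressure is prescribed everywhere
(10 mmHg) and the tumor contour is held at zero extracellular pressure;
the solve is a single linear step (no storage term, steady state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh, QUAD_GAUSS, quad_shape, polygon_area
from .params import NodalParams
from .units import P_CAP_PA

__all__ = [
    "FESystem",
    "FieldResult",
    "MassBalance",
    "element_conductivity",
    "assemble_system",
    "solve_pressure",
    "darcy_velocity",
    "mass_balance",
]

CAPILLARY, EXTRACELLULAR = 1, 2


def element_conductivity(coords: np.ndarray, r_nodal: np.ndarray,
                         kD_nodal: np.ndarray, h_z: float = 1.0) -> np.ndarray:
    """Element Darcy stiffness for one domain.

    ``coords`` is (4, 2) for a quad or (3, 2) for a triangle; ``r_nodal``
    the nodal volumetric fractions and ``kD_nodal`` the nodal (2, 2)
    Darcy tensors, both interpolated to the quadrature points.  Returns
    the symmetric (n, n) matrix with zero row sums.
    """
    coords = np.asarray(coords, dtype=float)
    r_nodal = np.asarray(r_nodal, dtype=float)
    kD_nodal = np.asarray(kD_nodal, dtype=float)
    n = len(coords)
    K = np.zeros((n, n))
    if n == 4:
        for xi, eta in QUAD_GAUSS:
            N, dN = quad_shape(xi, eta)
            J = dN.T @ coords
            detJ = np.linalg.det(J)
            if detJ <= 0:
                raise ValueError("non-positive Jacobian")
            B = np.linalg.solve(J, dN.T)          # (2, 4) physical gradients
            kD = np.einsum("a,aij->ij", N, kD_nodal)
            r = float(N @ r_nodal)
            K += (B.T @ kD @ B) * r * detJ * h_z  # unit Gauss weights
    elif n == 3:
        area = polygon_area(coords)
        if area <= 0:
            raise ValueError("non-positive Jacobian (inverted triangle)")
        # constant P1 gradients
        x, y = coords[:, 0], coords[:, 1]
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
        B = np.vstack([b, c]) / (2.0 * area)
        kD = kD_nodal.mean(axis=0)                # 1-point rule at centroid
        r = float(r_nodal.mean())
        K = (B.T @ kD @ B) * r * area * h_z
    else:
        raise ValueError("element must have 3 or 4 nodes")
    return K


@dataclass
class FESystem:
    """Assembled two-domain system on a mesh.

    ``K_cap``/``K_ex`` are the per-domain stiffness blocks, ``coupling``
    the nodal connectivity conductances k_J; DOF ordering of the global
    matrix is [p_cap (n), p_ex (n)].
    """

    mesh: Mesh
    params: NodalParams
    K_cap: sp.csr_matrix
    K_ex: sp.csr_matrix
    coupling: np.ndarray
    source: np.ndarray = None  # optional Q_Vp, length 2n

    def __post_init__(self) -> None:
        if self.source is None:
            self.source = np.zeros(2 * self.mesh.n_nodes)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    def global_matrix(self) -> sp.csr_matrix:
        C = sp.diags(self.coupling)
        return sp.bmat([[self.K_cap + C, -C], [-C, self.K_ex + C]],
                       format="csr")


def _assemble_domain(mesh: Mesh, r: np.ndarray, kD: np.ndarray) -> sp.csr_matrix:
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    for conn in mesh.element_nodes():
        Ke = element_conductivity(mesh.nodes[conn], r[conn], kD[conn],
                                  h_z=mesh.h_z)
        for a, ia in enumerate(conn):
            for b, ib in enumerate(conn):
                rows.append(ia)
                cols.append(ib)
                vals.append(Ke[a, b])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def assemble_system(mesh: Mesh, params: NodalParams,
                    source: np.ndarray | None = None) -> FESystem:
    """Assemble per-domain stiffness and nodal connectivity coupling.

    With h_cap = 0 everywhere the domains decouple (block-diagonal
    system); the global matrix is symmetric with zero row sums.
    """
    if params.n_nodes != mesh.n_nodes:
        raise ValueError("params defined on a different number of nodes "
                         f"({params.n_nodes} vs mesh {mesh.n_nodes})")
    K_cap = _assemble_domain(mesh, params.r_vcap, params.kD_cap)
    K_ex = _assemble_domain(mesh, params.r_ex, params.kD_tissue)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(params.r_vcap > 0,
                     4.0 * params.r_vcap * params.V / params.d_cap
                     * params.h_cap, 0.0)
    if np.any(~np.isfinite(k)):
        raise ValueError("connectivity conductance not finite "
                         "(zero diameter with positive r_Vcap?)")
    return FESystem(mesh=mesh, params=params, K_cap=K_cap, K_ex=K_ex,
                    coupling=k, source=source)


@dataclass
class FieldResult:
    """Solved pressures, Darcy velocities, and wall fluxes.

    Pressures (Pa) live at nodes, superficial Darcy velocities (um/s) at
    element centers, wall flux (um^3/s, capillary -> extracellular) at
    nodes.
    """

    p_cap: np.ndarray
    p_ex: np.ndarray
    v_cap: np.ndarray
    v_ex: np.ndarray
    wall_flux: np.ndarray
    dirichlet_dofs: np.ndarray
    residual: float


def _dirichlet_dofs(system: FESystem, p_cap_value: float,
                    boundary_value: float, fix_capillary_everywhere: bool,
                    extra_bcs, ex_boundary_nodes=None):
    n = system.n_nodes
    dofs, vals = [], []
    if fix_capillary_everywhere:
        dofs.extend(range(n))
        vals.extend([p_cap_value] * n)
    # general two-field mode: capillary conditions come via extra_bcs
    if ex_boundary_nodes is None:
        ex_boundary_nodes = system.mesh.boundary_nodes
    for j in ex_boundary_nodes:
        dofs.append(n + int(j))
        vals.append(boundary_value)
    if extra_bcs:
        for node, domain, value in extra_bcs:
            dof = int(node) + (0 if domain == CAPILLARY else n)
            dofs.append(dof)
            vals.append(float(value))
    # later entries win on duplicates
    seen = {}
    for d, v in zip(dofs, vals):
        seen[d] = v
    dofs = np.fromiter(seen.keys(), dtype=int)
    vals = np.fromiter(seen.values(), dtype=float)
    return dofs, vals


def solve_pressure(
    system: FESystem,
    p_cap_value: float = P_CAP_PA,
    boundary_value: float = 0.0,
    fix_capillary_everywhere: bool = True,
    extra_bcs=None,
    p_initial: np.ndarray | None = None,
    ex_boundary_nodes=None,
) -> FieldResult:
    """Solve the coupled pressure system with Dirichlet conditions.

    Defaults fix the capillary pressure at every node (10 mmHg =
    1333.22 Pa) and the extracellular pressure to zero on the contour;
    ``ex_boundary_nodes`` restricts the zero-pressure condition to a
    subset of nodes (e.g. only the ends of a strip, the sides then being
    natural no-flux boundaries).
    The solve is incremental, K dP = Q - K P0, from ``p_initial`` (zero
    if not given); the problem is linear, so one step reaches steady
    state regardless of the initial field.  Raises on a system with no
    Dirichlet constraint (pure-Neumann, singular).
    """
    n = system.n_nodes
    K = system.global_matrix()
    Q = system.source
    dofs, vals = _dirichlet_dofs(system, p_cap_value, boundary_value,
                                 fix_capillary_everywhere, extra_bcs,
                                 ex_boundary_nodes)
    if len(dofs) == 0:
        raise ValueError("no Dirichlet condition anywhere: singular system")

    P0 = np.zeros(2 * n) if p_initial is None else np.asarray(p_initial,
                                                              float).copy()
    P0[dofs] = vals
    free = np.setdiff1d(np.arange(2 * n), dofs)
    if len(free):
        rhs = (Q - K @ P0)[free]
        K_ff = K[np.ix_(free, free)].tocsc()
        dP = spla.spsolve(K_ff, rhs)
        P = P0.copy()
        P[free] += dP
        denom = max(np.linalg.norm((Q - K @ P0)[free]), 1e-300)
        residual = float(
            np.linalg.norm(K_ff @ (P[free] - P0[free]) - rhs) / denom)
    else:
        P = P0
        residual = 0.0

    p_cap, p_ex = P[:n], P[n:]
    v_cap = darcy_velocity(system.mesh, p_cap, system.params.kD_cap)
    v_ex = darcy_velocity(system.mesh, p_ex, system.params.kD_tissue)
    wall_flux = system.coupling * (p_cap - p_ex)
    return FieldResult(p_cap=p_cap, p_ex=p_ex, v_cap=v_cap, v_ex=v_ex,
                       wall_flux=wall_flux, dirichlet_dofs=dofs,
                       residual=residual)


def darcy_velocity(mesh: Mesh, pressure: np.ndarray,
                   kD_nodal: np.ndarray) -> np.ndarray:
    """Superficial Darcy velocity v = -kD grad(p) at element centers."""
    pressure = np.asarray(pressure, dtype=float)
    out = np.empty((mesh.n_elements, 2))
    for e, conn in enumerate(mesh.element_nodes()):
        coords = mesh.nodes[conn]
        p = pressure[conn]
        if len(conn) == 4:
            N, dN = quad_shape(0.0, 0.0)
            J = dN.T @ coords
            grad = np.linalg.solve(J, dN.T @ p)
            kD = np.einsum("a,aij->ij", N, kD_nodal[conn])
        else:
            area = polygon_area(coords)
            x, y = coords[:, 0], coords[:, 1]
            b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
            c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
            grad = np.vstack([b, c]) @ p / (2.0 * area)
            kD = kD_nodal[conn].mean(axis=0)
        out[e] = -kD @ grad
    return out


@dataclass
class MassBalance:
    """Conservation report: capillary-wall influx vs boundary outflux."""

    wall_influx: float
    boundary_outflux: float

    @property
    def relative_imbalance(self) -> float:
        scale = max(abs(self.wall_influx), abs(self.boundary_outflux))
        if scale == 0:
            return 0.0
        return abs(self.wall_influx - self.boundary_outflux) / scale


def mass_balance(result: FieldResult, system: FESystem) -> MassBalance:
    """Check that what crosses the capillary walls leaves the boundary.

    The boundary outflux is recovered from the reactions of the
    extracellular equation at its Dirichlet nodes; in a conservative
    discretization it matches the total wall influx to solver precision.
    """
    n = system.n_nodes
    influx = float(result.wall_flux.sum())
    C = sp.diags(system.coupling)
    residual_ex = (system.K_ex + C) @ result.p_ex - C @ result.p_cap \
        - system.source[n:]
    ex_fixed = result.dirichlet_dofs[result.dirichlet_dofs >= n] - n
    outflux = -float(residual_ex[ex_fixed].sum())
    return MassBalance(wall_influx=influx, boundary_outflux=outflux)
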