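"""Mapping of heatmap fields to per-node smeared-model parameters.

The smeared (homogenized) description replaces the resolved capillary
network by nodal volumetric fractions and effective transport properties:
``r_Vcap`` (capillary), ``r_Vcell`` (cells), ``r_ex`` (extracellular
space, the remainder), a capillary diameter ``d_cap``, a wall hydraulic
coefficient ``h_cap``, and 2x2 Darcy tensors for the capillary and tissue
domains.  The capillary fraction follows from the stained areal coverage:
with coverage Acap% read as capillary *surface* per section area
(A_cap = d*pi*L per unit cell) and the cylinder volume V = d^2*pi*L/4,

    r_Vcap = d * Acap% / (400 * h_z)

for model thickness h_z.  The perfusion coverage is taken as the
cell-occupied areal fraction, r_Vcell = perfusion% / 100, and closure
gives r_ex = 1 - r_Vcap - r_Vcell.

The capillary-to-tissue exchange at a node is a fictitious two-node
"connectivity element" whose conductance is the capillary wall area in
the nodal tributary volume times the wall hydraulic coefficient: a
cylinder's surface-to-volume ratio is 4/d, so

    k = (4 * r_Vcap * V / d) * h_cap      [um^3/(Pa s)]

(the literal product 4*d*r*V*h would carry units um^5/(Pa s); the
surface-area reading is the dimensionally consistent one and is what is
implemented — see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Mesh, idw_interpolate
from .heatmaps import HeatmapGrid
from .units import H_CAP_DEFAULT, H_Z_DEFAULT, K_TISSUE_DEFAULT, MU_BLOOD_DEFAULT

__all__ = [
    "NodalParams",
    "rvcap_from_coverage",
    "rex_from_fractions",
    "connectivity_matrix",
    "darcy_tensor_tissue",
    "darcy_tensor_capillary",
    "nodal_params_from_heatmaps",
    "bessel_length",
]


def rvcap_from_coverage(Acap_pct: float, d: float, h_z: float = H_Z_DEFAULT):
    """Capillary volumetric fraction from stained coverage percent.

    r_Vcap = d * Acap% / (400 * h_z).  Scalar or array arguments.
    """
    Acap_pct = np.asarray(Acap_pct, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(Acap_pct < 0) or np.any(Acap_pct > 100):
        raise ValueError("coverage percent must lie in [0, 100]")
    if h_z <= 0:
        raise ValueError("h_z must be positive")
    if np.any((Acap_pct > 0) & (d <= 0)):
        raise ValueError("capillary diameter must be positive where "
                         "coverage is positive")
    r = np.where(Acap_pct > 0, d * Acap_pct / (400.0 * h_z), 0.0)
    if np.any(r > 1.0):
        raise ValueError("r_Vcap > 1: unphysical coverage/diameter "
                         "combination")
    return float(r) if r.ndim == 0 else r


def rex_from_fractions(r_Vcap, r_Vcell):
    """Extracellular fraction by closure: r_ex = 1 - r_Vcap - r_Vcell."""
    r_Vcap = np.asarray(r_Vcap, dtype=float)
    r_Vcell = np.asarray(r_Vcell, dtype=float)
    for name, r in (("r_Vcap", r_Vcap), ("r_Vcell", r_Vcell)):
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    r_ex = 1.0 - r_Vcap - r_Vcell
    if np.any(r_ex < 0):
        raise ValueError("volume over-full: r_Vcap + r_Vcell > 1")
    return float(r_ex) if r_ex.ndim == 0 else r_ex


def connectivity_matrix(d: float, r_Vcap: float, V: float,
                        h_cap: float = H_CAP_DEFAULT) -> np.ndarray:
    """Nodal capillary-wall conductance matrix k * [[1, -1], [-1, 1]].

    k = (4 * r_Vcap * V / d) * h_cap in um^3/(Pa s): wall area times wall
    hydraulic coefficient.  Rows sum to zero (whatever leaves the
    capillary domain enters the extracellular one).
    """
    if min(r_Vcap, V, h_cap) < 0 or d < 0:
        raise ValueError("all connectivity inputs must be non-negative")
    if r_Vcap > 0 and d <= 0:
        raise ValueError("capillary diameter must be positive when "
                         "r_Vcap > 0")
    k = (4.0 * r_Vcap * V / d) * h_cap if r_Vcap > 0 else 0.0
    return k * np.array([[1.0, -1.0], [-1.0, 1.0]])


def darcy_tensor_tissue(k_iso: float) -> np.ndarray:
    """Isotropic tissue Darcy tensor diag(k, k), um^2/(Pa s)."""
    if k_iso < 0:
        raise ValueError("Darcy coefficient must be non-negative")
    return k_iso * np.eye(2)


def darcy_tensor_capillary(d: float, orientation=None,
                           mu: float = MU_BLOOD_DEFAULT) -> np.ndarray:
    """Effective capillary Darcy tensor from Poiseuille conductivity.

    A tube of diameter d has hydraulic conductivity d^2/(32 mu).  Aligned
    with unit vector t the tensor is (d^2/(32 mu)) t (x) t; for an
    isotropic in-plane orientation distribution the average of t (x) t is
    I/2, giving (d^2/(64 mu)) I.  ``orientation=None`` means isotropic.
    """
    if d < 0:
        raise ValueError("diameter must be non-negative")
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    k = d * d / (32.0 * mu)
    if orientation is None:
        return 0.5 * k * np.eye(2)
    t = np.asarray(orientation, dtype=float)
    n = np.linalg.norm(t)
    if n == 0:
        raise ValueError("orientation vector must be non-zero")
    t = t / n
    return k * np.outer(t, t)


def bessel_length(r_ex: float, k_tissue: float, d: float, r_Vcap: float,
                  h_cap: float = H_CAP_DEFAULT) -> float:
    """Pressure screening length lambda = sqrt(r_ex k_t d / (4 r_Vcap h_cap)).

    The distance over which the extracellular pressure relaxes from the
    capillary source level toward a boundary value; reported so the effect
    of the (configurable) tissue Darcy coefficient is visible.
    """
    if r_Vcap <= 0 or h_cap <= 0:
        return float("inf")
    return float(np.sqrt(r_ex * k_tissue * d / (4.0 * r_Vcap * h_cap)))


@dataclass
class NodalParams:
    """Per-node smeared parameters on a mesh.

    Arrays are indexed by mesh node: fractions ``r_vcap``/``r_vcell``/
    ``r_ex`` (closing to 1), diameter ``d_cap`` (um), wall coefficient
    ``h_cap`` (um/(Pa s)), Darcy tensors ``kD_cap``/``kD_tissue``
    ((n, 2, 2), um^2/(Pa s)), and tributary volumes ``V`` (um^3) that
    partition the mesh volume.
    """

    r_vcap: np.ndarray
    r_vcell: np.ndarray
    r_ex: np.ndarray
    d_cap: np.ndarray
    h_cap: np.ndarray
    kD_cap: np.ndarray
    kD_tissue: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.r_vcap)
        for name in ("r_vcell", "r_ex", "d_cap", "h_cap", "V"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        for name in ("kD_cap", "kD_tissue"):
            t = getattr(self, name)
            if t.shape != (n, 2, 2):
                raise ValueError(f"{name} must have shape (n, 2, 2)")
            if not np.allclose(t, np.swapaxes(t, 1, 2)):
                raise ValueError(f"{name} tensors must be symmetric")
            if np.any(np.linalg.eigvalsh(t) < -1e-12):
                raise ValueError(f"{name} tensors must be PSD")
        closure = self.r_vcap + self.r_vcell + self.r_ex
        if not np.allclose(closure, 1.0, rtol=0, atol=1e-12):
            raise ValueError("volumetric fractions do not close to 1")
        for name in ("r_vcap", "r_vcell", "r_ex"):
            r = getattr(self, name)
            if np.any(r < -1e-15) or np.any(r > 1 + 1e-15):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.V <= 0):
            raise ValueError("tributary volumes must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.r_vcap)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": np.arange(self.n_nodes),
            "r_vcap": self.r_vcap,
            "r_vcell": self.r_vcell,
            "r_ex": self.r_ex,
            "d_cap_um": self.d_cap,
            "h_cap": self.h_cap,
            "V_um3": self.V,
            "kD_tissue_xx": self.kD_tissue[:, 0, 0],
            "kD_tissue_xy": self.kD_tissue[:, 0, 1],
            "kD_tissue_yy": self.kD_tissue[:, 1, 1],
            "kD_cap_xx": self.kD_cap[:, 0, 0],
            "kD_cap_xy": self.kD_cap[:, 0, 1],
            "kD_cap_yy": self.kD_cap[:, 1, 1],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def uniform_nodal_params(
    mesh: Mesh,
    r_vcap: float = 0.05,
    r_vcell: float = 0.75,
    d_cap: float = 5.0,
    h_cap: float = H_CAP_DEFAULT,
    k_tissue: float = K_TISSUE_DEFAULT,
    mu: float = MU_BLOOD_DEFAULT,
) -> NodalParams:
    """Spatially constant smeared parameters on a mesh (benchmark helper)."""
    n = mesh.n_nodes
    r_ex = rex_from_fractions(r_vcap, r_vcell)
    return NodalParams(
        r_vcap=np.full(n, r_vcap),
        r_vcell=np.full(n, r_vcell),
        r_ex=np.full(n, r_ex),
        d_cap=np.full(n, d_cap),
        h_cap=np.full(n, h_cap),
        kD_cap=np.broadcast_to(darcy_tensor_capillary(d_cap, None, mu),
                               (n, 2, 2)).copy(),
        kD_tissue=np.broadcast_to(darcy_tensor_tissue(k_tissue),
                                  (n, 2, 2)).copy(),
        V=mesh.node_tributary_volumes(),
    )


def nodal_params_from_heatmaps(
    heatmap: HeatmapGrid,
    mesh: Mesh,
    h_cap: float = H_CAP_DEFAULT,
    k_tissue: float = K_TISSUE_DEFAULT,
    mu: float = MU_BLOOD_DEFAULT,
    h_z: float | None = None,
    idw_power: float = 2.0,
    min_r_ex: float | None = None,
) -> NodalParams:
    """Interpolate heatmap fields to mesh nodes and build smeared parameters.

    Coverage, diameter, and perfusion are carried from unmasked cell
    centers to the nodes by inverse-distance weighting (cells without a
    diameter reading contribute nothing to the diameter field, so holes
    are filled from cells that have data), then converted per node.
    Raises if any node ends up volumetrically over-full, naming the node.

    The perfusion stain is a proxy for the cell-occupied fraction and can
    saturate near dense vasculature, over-filling the volume budget.
    ``min_r_ex`` (e.g. 0.05), when given, guarantees that much
    extracellular space by capping r_Vcell at 1 - r_Vcap - min_r_ex
    instead of raising.
    """
    if h_z is None:
        h_z = mesh.h_z
    centers = heatmap.cell_centers.reshape(-1, 2)
    mask = heatmap.mask.ravel()
    if not mask.any():
        raise ValueError("heatmap has no unmasked cells")
    vasc = heatmap.vasculature_pct.ravel()
    perf = heatmap.perfusion_pct.ravel()
    diam = heatmap.diameter_um.ravel()

    nodes = mesh.nodes
    vasc_n = idw_interpolate(centers[mask], vasc[mask], nodes, power=idw_power)
    perf_n = idw_interpolate(centers[mask], perf[mask], nodes, power=idw_power)
    has_d = mask & np.isfinite(diam)
    if not has_d.any():
        raise ValueError("no cell provides a capillary diameter")
    diam_n = idw_interpolate(centers[has_d], diam[has_d], nodes,
                             power=idw_power)

    r_vcap = rvcap_from_coverage(vasc_n, diam_n, h_z)
    r_vcell = perf_n / 100.0
    if min_r_ex is not None:
        if not 0.0 <= min_r_ex < 1.0:
            raise ValueError("min_r_ex must lie in [0, 1)")
        r_vcell = np.minimum(r_vcell, 1.0 - r_vcap - min_r_ex)
        if np.any(r_vcell < 0):
            j = int(np.nonzero(r_vcell < 0)[0][0])
            raise ValueError(
                f"node {j}: r_Vcap={r_vcap[j]:.3f} leaves no room for "
                f"cells at min_r_ex={min_r_ex}")
    over = r_vcap + r_vcell > 1.0
    if np.any(over):
        j = int(np.nonzero(over)[0][0])
        raise ValueError(
            f"node {j} volumetrically over-full: r_Vcap={r_vcap[j]:.3f} + "
            f"r_Vcell={r_vcell[j]:.3f} > 1")
    r_ex = rex_from_fractions(r_vcap, r_vcell)

    n = mesh.n_nodes
    kD_tissue = np.broadcast_to(darcy_tensor_tissue(k_tissue), (n, 2, 2)).copy()
    kD_cap = np.stack([darcy_tensor_capillary(d, None, mu) for d in diam_n])
    return NodalParams(
        r_vcap=r_vcap,
        r_vcell=r_vcell,
        r_ex=r_ex,
        d_cap=diam_n,
        h_cap=np.full(n, h_cap),
        kD_cap=kD_cap,
        kD_tissue=kD_tissue,
        V=mesh.node_tributary_volumes(),
    )
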