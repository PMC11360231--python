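"""Verification benchmarks against closed-form solutions.

With spatially uniform parameters and the capillary pressure fixed, the
coupled model reduces to a screened Poisson problem whose disc and strip
solutions are modified-Bessel and hyperbolic-cosine profiles.  This
driver measures the solver's error against both and the discrete mass
balance, and writes the table the README quotes.

Writes results/benchmarks.csv.
"""

import pathlib
import sys

import numpy as np
import pandas as pd
from scipy.special import ive

import tumorperf as tp
from tumorperf.params import uniform_nodal_params
from tumorperf.solver import assemble_system, mass_balance, solve_pressure

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

LAM = tp.bessel_length(0.2, tp.K_TISSUE_DEFAULT, 5.0, 0.05)
R_DISC = 250.0
L_STRIP = 200.0


def circle(radius, n=512):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


def disc_case(n_rings, n_sectors):
    mesh = tp.mesh_polygon(circle(R_DISC), n_rings, n_sectors,
                           preserve_area=False)
    system = assemble_system(mesh, uniform_nodal_params(mesh))
    res = solve_pressure(system)
    r = np.linalg.norm(mesh.nodes, axis=1)
    exact = tp.P_CAP_PA * (1 - ive(0, r / LAM) * np.exp((r - R_DISC) / LAM)
                           / ive(0, R_DISC / LAM))
    err = np.sqrt(np.sum((res.p_ex - exact) ** 2) / np.sum(exact ** 2))
    return err, mass_balance(res, system).relative_imbalance


def strip_case(nx):
    mesh = tp.mesh_rectangle(2 * L_STRIP, 10.0, nx=nx, ny=1,
                             origin=(-L_STRIP, -5.0))
    system = assemble_system(mesh, uniform_nodal_params(mesh))
    ends = np.nonzero(np.isclose(np.abs(mesh.nodes[:, 0]), L_STRIP))[0]
    res = solve_pressure(system, ex_boundary_nodes=ends)
    x = mesh.nodes[:, 0]
    exact = tp.P_CAP_PA * (1 - np.cosh(x / LAM) / np.cosh(L_STRIP / LAM))
    err = np.sqrt(np.sum((res.p_ex - exact) ** 2) / np.sum(exact ** 2))
    return err, mass_balance(res, system).relative_imbalance


def main(seed: int = 0) -> None:
    del seed  # benchmarks are deterministic
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for n in (8, 16, 32, 64):
        err, imb = disc_case(n, 2 * n)
        rows.append({"case": "disc_bessel", "resolution": f"{n}x{2*n}",
                     "rel_l2_error": err, "mass_imbalance": imb})
    for nx in (50, 200):
        err, imb = strip_case(nx)
        rows.append({"case": "strip_cosh", "resolution": f"{nx}x1",
                     "rel_l2_error": err, "mass_imbalance": imb})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "benchmarks.csv", index=False)
    print(df.to_string(index=False))

    disc = df[df["case"] == "disc_bessel"]["rel_l2_error"].to_numpy()
    orders = np.log2(disc[:-1] / disc[1:])
    print(f"observed convergence order on the disc: "
          f"{', '.join(f'{o:.2f}' for o in orders)}")
    print(f"(screening length lambda = {LAM:.1f} um, "
          f"disc radius {R_DISC:.0f} um)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
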