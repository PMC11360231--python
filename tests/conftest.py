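import numpy as np
import pytest

from tumorperf.geometry import mesh_polygon
from tumorperf.params import uniform_nodal_params


def circle(radius: float, n: int = 512) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


@pytest.fixture(scope="session")
def disc_contour():
    """Circle of radius 250 um, finely sampled."""
    return circle(250.0)


@pytest.fixture(scope="session")
def disc_solution(disc_contour):
    """Solved uniform disc at 32x64: the workhorse verification case.

    Uniform defaults: r_Vcap = 0.05, r_Vcell = 0.75, d = 5 um, so the
    screening length is lambda = sqrt(0.2 * 1.0 * 5 / (4*0.05*1.57e-3))
    ~ 56.4 um.
    """
    from tumorperf.solver import assemble_system, solve_pressure

    mesh = mesh_polygon(disc_contour, 32, 64, preserve_area=False)
    params = uniform_nodal_params(mesh)
    system = assemble_system(mesh, params)
    result = solve_pressure(system)
    return mesh, params, system, result
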