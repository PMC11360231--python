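"""Orchestration of the growing-tumor perfusion simulation.

Tumor outlines and heatmap fields are known at a few experimental knots
(days 7, 10, 13, 16 after inoculation, roughly 15/25/60/80% of final
growth).  Between knots both geometry and fields are interpolated
linearly in time; at every substep the domain is remeshed (elements are
not fixed in space as the geometry evolves), the previous pressures are
carried to the new mesh by IDW as the starting field of the incremental
solve, smeared parameters are rebuilt, and the steady pressure/velocity
fields recorded.  No extrapolation outside the first/last knot.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .geometry import (Mesh, idw_interpolate, interpolate_contours,
                       mesh_polygon, resample_star, star_radii,
                       polygon_centroid, transfer_fields)
from .heatmaps import HeatmapGrid
from .params import NodalParams, nodal_params_from_heatmaps
from .solver import (FieldResult, MassBalance, assemble_system, mass_balance,
                     solve_pressure)
from .units import (H_CAP_DEFAULT, K_TISSUE_DEFAULT, MU_BLOOD_DEFAULT,
                    PA_PER_MMHG, P_CAP_MMHG)

__all__ = [
    "TimeCourseConfig",
    "TimeStepResult",
    "TimeCourseResult",
    "run_timecourse",
    "centerline_profile",
    "summarize_groups",
]

DEFAULT_KNOT_DAYS = (7.0, 10.0, 13.0, 16.0)


@dataclass
class TimeCourseConfig:
    """Inputs of one simulation run.

    ``contours``/``heatmaps`` are the per-knot tumor outlines (um) and
    heatmap grids; all heatmaps must share one grid shape.  ``substeps``
    is the number of new steps per knot interval (3 by default, so four
    knots give 10 solved configurations).
    """

    times: tuple = DEFAULT_KNOT_DAYS
    contours: list = dc_field(default_factory=list)
    heatmaps: list = dc_field(default_factory=list)
    substeps: int = 3
    n_rings: int = 16
    n_sectors: int = 32
    p_cap_mmhg: float = P_CAP_MMHG
    h_cap: float = H_CAP_DEFAULT
    k_tissue: float = K_TISSUE_DEFAULT
    mu: float = MU_BLOOD_DEFAULT
    idw_power: float = 2.0
    transfer_k: int = 4
    min_r_ex: float | None = None
    seed: int = 0


@dataclass
class TimeStepResult:
    """State and summaries of one solved substep."""

    day: float
    mesh: Mesh
    params: NodalParams
    fields: FieldResult
    balance: MassBalance
    mean_pressure: float        # area-weighted, Pa
    mean_velocity: float        # area-weighted |v_ex|, um/s
    area: float                 # domain area, um^2


@dataclass
class TimeCourseResult:
    steps: list

    @property
    def days(self) -> np.ndarray:
        return np.array([s.day for s in self.steps])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.days,
            "area_um2": [s.area for s in self.steps],
            "mean_pressure_Pa": [s.mean_pressure for s in self.steps],
            "mean_velocity_um_s": [s.mean_velocity for s in self.steps],
            "max_pressure_Pa": [float(s.fields.p_ex.max()) for s in self.steps],
            "residual": [s.fields.residual for s in self.steps],
            "mass_imbalance": [s.balance.relative_imbalance for s in self.steps],
        })


def _interp_heatmap(hA: HeatmapGrid, hB: HeatmapGrid, alpha: float,
                    contour: np.ndarray) -> HeatmapGrid:
    """Cell-wise linear blend of two aligned heatmaps onto a new contour.

    Values interpolate linearly where both knots have data; cells with
    data on only one side keep that side's value.  The blended grid is
    laid over the bounding box of the current contour and re-masked
    against it.
    """
    from shapely.geometry import Point, Polygon

    if hA.grid_shape != hB.grid_shape:
        raise ValueError("heatmap grids must share one shape")

    def blend(a, b):
        out = (1.0 - alpha) * a + alpha * b
        only_a = np.isfinite(a) & ~np.isfinite(b)
        only_b = np.isfinite(b) & ~np.isfinite(a)
        out[only_a] = a[only_a]
        out[only_b] = b[only_b]
        return out

    xmin, ymin = contour.min(axis=0)
    xmax, ymax = contour.max(axis=0)
    rows, cols = hA.grid_shape
    x_edges = np.linspace(xmin, xmax, cols + 1)
    y_edges = np.linspace(ymin, ymax, rows + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    poly = Polygon(contour)
    mask = np.array([[poly.contains(Point(x, y)) for x in xc] for y in yc])
    # values from masked knots still blend: the union of in-tumor cells
    vA = np.where(hA.mask, hA.vasculature_pct, np.nan)
    vB = np.where(hB.mask, hB.vasculature_pct, np.nan)
    pA = np.where(hA.mask, hA.perfusion_pct, np.nan)
    pB = np.where(hB.mask, hB.perfusion_pct, np.nan)
    dA = np.where(hA.mask, hA.diameter_um, np.nan)
    dB = np.where(hB.mask, hB.diameter_um, np.nan)
    vasc = blend(vA, vB)
    perf = blend(pA, pB)
    diam = blend(dA, dB)
    # a cell inside the new contour but without data at either knot keeps
    # NaN coverage; mask it out so IDW fills from informed cells
    informed = np.isfinite(vasc) & np.isfinite(perf)
    vasc = np.where(informed, vasc, 0.0)
    perf = np.where(informed, perf, 0.0)
    return HeatmapGrid(
        vasculature_pct=np.clip(vasc, 0, 100),
        perfusion_pct=np.clip(perf, 0, 100),
        diameter_um=diam,
        mask=mask & informed,
        x_edges=x_edges,
        y_edges=y_edges,
    )


def run_timecourse(config: TimeCourseConfig) -> TimeCourseResult:
    """Run the full interpolate-remesh-transfer-solve loop.

    Deterministic for a given config; returns one
    :class:`TimeStepResult` per substep, knots included.
    """
    times = np.asarray(config.times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("knot times must be strictly increasing")
    if len(config.contours) != len(times):
        raise ValueError("one contour per knot time required")
    if len(config.heatmaps) != len(times):
        raise ValueError("one heatmap per knot time required")

    n_angles = max(128, 2 * config.n_sectors)
    knots = [resample_star(np.asarray(c, float), n_angles)
             for c in config.contours]

    steps: list[TimeStepResult] = []
    prev_mesh: Mesh | None = None
    prev_P: np.ndarray | None = None
    p_cap_pa = config.p_cap_mmhg * PA_PER_MMHG

    for i in range(len(times) - 1):
        local = np.linspace(0.0, 1.0, config.substeps + 1)
        if i > 0:
            local = local[1:]  # knot already solved in the previous interval
        for alpha in local:
            day = (1 - alpha) * times[i] + alpha * times[i + 1]
            contour = interpolate_contours(knots[i], knots[i + 1], alpha)
            heatmap = _interp_heatmap(config.heatmaps[i],
                                      config.heatmaps[i + 1], alpha, contour)
            mesh = mesh_polygon(contour, config.n_rings, config.n_sectors)
            params = nodal_params_from_heatmaps(
                heatmap, mesh, h_cap=config.h_cap, k_tissue=config.k_tissue,
                mu=config.mu, idw_power=config.idw_power,
                min_r_ex=config.min_r_ex)
            system = assemble_system(mesh, params)
            if prev_mesh is not None:
                P0 = np.concatenate([
                    transfer_fields(prev_mesh, prev_P[:prev_mesh.n_nodes],
                                    mesh, k=config.transfer_k),
                    transfer_fields(prev_mesh, prev_P[prev_mesh.n_nodes:],
                                    mesh, k=config.transfer_k),
                ])
            else:
                P0 = None
            fields = solve_pressure(system, p_cap_value=p_cap_pa,
                                    p_initial=P0)
            balance = mass_balance(fields, system)

            areas = mesh.element_areas()
            total = areas.sum()
            # element mean pressure from nodal values
            p_elem = np.array([fields.p_ex[conn].mean()
                               for conn in mesh.element_nodes()])
            v_mod = np.linalg.norm(fields.v_ex, axis=1)
            steps.append(TimeStepResult(
                day=float(day),
                mesh=mesh,
                params=params,
                fields=fields,
                balance=balance,
                mean_pressure=float((areas * p_elem).sum() / total),
                mean_velocity=float((areas * v_mod).sum() / total),
                area=float(total),
            ))
            prev_mesh = mesh
            prev_P = np.concatenate([fields.p_cap, fields.p_ex])
    return TimeCourseResult(steps=steps)


def centerline_profile(step: TimeStepResult, axis: str = "x",
                       n_points: int = 101, field: str = "pressure",
                       k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Field profile along the axis-parallel line through the tumor center.

    ``field`` is "pressure" (nodal p_ex) or "velocity" (element |v_ex|);
    values are sampled by IDW at ``n_points`` between the two boundary
    crossings of the line.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    mesh = step.mesh
    boundary = mesh.nodes[mesh.boundary_nodes]
    center = polygon_centroid(boundary)
    ang = 0.0 if axis == "x" else np.pi / 2.0
    r_pos = star_radii(boundary, np.array([ang]), center)[0]
    r_neg = star_radii(boundary, np.array([ang + np.pi]), center)[0]
    s = np.linspace(-r_neg, r_pos, n_points)
    direction = np.array([np.cos(ang), np.sin(ang)])
    pts = center + s[:, None] * direction

    if field == "pressure":
        values = idw_interpolate(mesh.nodes, step.fields.p_ex, pts, k=k)
    elif field == "velocity":
        v_mod = np.linalg.norm(step.fields.v_ex, axis=1)
        values = idw_interpolate(mesh.element_centers(), v_mod, pts, k=k)
    else:
        raise ValueError("field must be 'pressure' or 'velocity'")
    return s, values


def summarize_groups(groups: dict) -> pd.DataFrame:
    """Mean and standard error of the mean per named group.

    s.e.m. = sd(ddof=1)/sqrt(n); reported as NaN for a single value.
    Empty groups are an error.
    """
    rows = []
    for name, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append({"group": name, "n": v.size, "mean": float(v.mean()),
                     "sem": sem})
    return pd.DataFrame(rows)
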