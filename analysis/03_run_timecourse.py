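"""Simulate intratumoral pressure and fluid velocity over the growth window.

Per time point the replicate outlines are averaged (centroid-aligned,
per-angle mean radius) into one geometry, paired with the averaged
heatmaps from step 02, and fed into the moving-mesh two-domain Darcy
model: capillaries held at 10 mmHg everywhere, zero extracellular
pressure on the contour, geometry and parameters interpolated linearly
between knots with remeshing at every substep.

Reads  results/contours.csv, results/heatmap_day{7,10,13,16}.csv.
Writes results/timecourse_summary.csv    per-step means and diagnostics
       results/profiles.csv              centerline pressure/velocity
       scratch/fields/step_*.vtk         full fields for visualization
"""

import pathlib
import sys

import numpy as np
import pandas as pd

import tumorperf as tp
from tumorperf.io import write_vtk

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIELDS = ROOT / "scratch" / "fields"

KNOT_DAYS = (7.0, 10.0, 13.0, 16.0)


def main(seed: int = 0) -> None:
    FIELDS.mkdir(parents=True, exist_ok=True)
    contours_df = pd.read_csv(RESULTS / "contours.csv")

    avg_contours = []
    heatmaps = []
    for day in KNOT_DAYS:
        sel = contours_df[contours_df["time_day"] == day]
        reps = [g[["x_um", "y_um"]].to_numpy()
                for _, g in sel.groupby("replicate")]
        avg_contours.append(tp.average_contours(reps, n_angles=128))
        heatmaps.append(
            tp.HeatmapGrid.read_csv(RESULTS / f"heatmap_day{int(day)}.csv"))

    lam = tp.bessel_length(0.2, tp.K_TISSUE_DEFAULT, 5.0, 0.05)
    print(f"pressure screening length at nominal parameters: {lam:.1f} um")

    cfg = tp.TimeCourseConfig(times=KNOT_DAYS, contours=avg_contours,
                              heatmaps=heatmaps, substeps=3,
                              n_rings=24, n_sectors=48, min_r_ex=0.05,
                              seed=seed)
    res = tp.run_timecourse(cfg)

    summary = res.summary_frame()
    summary.to_csv(RESULTS / "timecourse_summary.csv", index=False)
    print(summary.to_string(index=False))

    prof_rows = []
    for step in res.steps:
        for axis in ("x", "y"):
            s, p = tp.centerline_profile(step, axis, n_points=51)
            _, v = tp.centerline_profile(step, axis, n_points=51,
                                         field="velocity")
            prof_rows.append(pd.DataFrame({
                "day": step.day, "axis": axis, "s_um": s,
                "pressure_Pa": p, "velocity_um_s": v}))
    pd.concat(prof_rows, ignore_index=True).to_csv(
        RESULTS / "profiles.csv", index=False, float_format="%.5g")

    for i, step in enumerate(res.steps):
        write_vtk(FIELDS / f"step_{i:02d}_day{step.day:04.1f}.vtk",
                  step.mesh,
                  point_data={"p_ex_Pa": step.fields.p_ex,
                              "wall_flux_um3_s": step.fields.wall_flux},
                  cell_data={"v_ex_um_s": step.fields.v_ex})

    mp = summary["mean_pressure_Pa"]
    mv = summary["mean_velocity_um_s"]
    print(f"mean pressure rose {mp.iloc[0]:.0f} -> {mp.iloc[-1]:.0f} Pa "
          f"while mean velocity fell {mv.iloc[0]:.2f} -> "
          f"{mv.iloc[-1]:.2f} um/s as the tumor grew")
    imb = summary["mass_imbalance"].max()
    print(f"worst wall-influx/boundary-outflux imbalance: {imb:.2e}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
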