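"""Synthesize the study cohort: growth curve, tumor outlines, section images.

The experimental design is a flank-tumor cohort imaged at four knots
along the growth curve (days 7, 10, 13, 16 after inoculation, about
15/25/60/80% of final volume).  The raw section images are not deposited,
so this driver generates a synthetic stand-in cohort with known ground
truth: per time point, a few replicate "tumors" (star-shaped outlines
whose areas track the exponential volume fit y = 59.98 exp(0.1874 t)
as volume^(2/3)) and two-channel pseudo-immunofluorescence images
(channel 0 vessel lumens, channel 1 perfusion halos).

Writes:
  results/growth_curve.csv      volume fit sampled daily
  results/contours.csv          all replicate outlines (x_um, y_um, day)
  results/image_truth.csv       exact per-cell truth coverage per image
  scratch/images/*.tif          rendered two-channel images (binary, large)

The replicate count is scaled down from the experimental six to three per
time point to keep the full pipeline fast; the downstream averaging is
unchanged.
"""

import pathlib
import sys

import numpy as np
import pandas as pd
import tifffile

import tumorperf as tp

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "images"

KNOT_DAYS = (7.0, 10.0, 13.0, 16.0)
N_REPLICATES = 3
IMAGE_PX = 900          # image frame, px (1 um/px)
BASE_RADIUS = 300.0     # nominal day-7 section radius, um
SEED = 20240


def main(seed: int = SEED) -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    days = np.arange(0, 20)
    pd.DataFrame({
        "day": days,
        "volume_mm3": [tp.growth_volume(t) for t in days],
    }).to_csv(RESULTS / "growth_curve.csv", index=False)

    contour_rows = []
    truth_rows = []
    for rep in range(N_REPLICATES):
        series = tp.gen_contour_series(
            seed=int(rng.integers(2**31)), times=KNOT_DAYS,
            base_radius=BASE_RADIUS * rng.uniform(0.9, 1.1),
            eccentricity=rng.uniform(1.0, 1.5),
            irregularity=rng.uniform(0.05, 0.2), n_vertices=128)
        for day, contour in zip(series.times, series.contours):
            contour_rows.append(pd.DataFrame({
                "x_um": contour[:, 0], "y_um": contour[:, 1],
                "time_day": day, "replicate": rep}))

            # vascular density declines at late time points (necrosis-like
            # trend); vessel count drives the drawn lumen coverage, tuned
            # to a few percent at 3-7 um lumen widths so the smeared
            # capillary fraction stays in a physiologic range
            n_vessels = int(55 * (1.0 - 0.04 * (day - 7.0)))
            spec = tp.random_image_spec(
                seed=int(rng.integers(2**31)),
                shape_px=(IMAGE_PX, IMAGE_PX), n_vessels=n_vessels,
                width_range_um=(3.5, 7.0), halo_um=25.0,
                density_gradient=0.4)
            truth = tp.gen_fluorescence_image(spec)
            name = f"tumor_d{int(day)}_r{rep}"
            tifffile.imwrite(SCRATCH / f"{name}.tif",
                             np.moveaxis(truth.image, -1, 0))
            df = pd.DataFrame({
                "image": name,
                "day": day,
                "replicate": rep,
                "row": np.repeat(np.arange(9), 9),
                "col": np.tile(np.arange(9), 9),
                "vasculature_truth_pct":
                    truth.vasculature_truth_pct.ravel(),
                "perfusion_truth_pct": truth.perfusion_truth_pct.ravel(),
            })
            truth_rows.append(df)

    pd.concat(contour_rows, ignore_index=True).to_csv(
        RESULTS / "contours.csv", index=False, float_format="%.2f")
    pd.concat(truth_rows, ignore_index=True).to_csv(
        RESULTS / "image_truth.csv", index=False)

    n_img = N_REPLICATES * len(KNOT_DAYS)
    print(f"wrote {n_img} two-channel images to {SCRATCH}")
    print(f"wrote contours for {N_REPLICATES} replicates x "
          f"{len(KNOT_DAYS)} time points to {RESULTS/'contours.csv'}")
    v7 = tp.growth_volume(7.0)
    v16 = tp.growth_volume(16.0)
    print(f"volume fit: day 7 = {v7:.1f} mm^3, day 16 = {v16:.1f} mm^3 "
          f"({v16/v7:.1f}x growth over the simulated window)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
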