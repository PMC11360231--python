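"""Gridded quantification of two-channel tumor-section images.

A coarse grid (9 x 9 by default) is laid over the section; in every cell
we record the areal coverage of the vascular stain (CD31-like, channel 0),
the areal coverage of the perfusion stain (Hoechst-like, channel 1), and
the mean diameter of a random sample of stained capillaries.  The three
per-cell fields form a :class:`HeatmapGrid`, the interchange object that
feeds the smeared-parameter mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.morphology import skeletonize

__all__ = [
    "HeatmapGrid",
    "threshold_channel",
    "grid_coverage",
    "measure_capillary_diameters",
    "build_heatmaps",
]


@dataclass
class HeatmapGrid:
    """Per-cell stain coverage and capillary diameter on a rectangular grid.

    Attributes
    ----------
    vasculature_pct : (rows, cols) float array
        Vascular-stain coverage per cell, percent of cell area.
    perfusion_pct : (rows, cols) float array
        Perfusion-stain coverage per cell, percent; used downstream as a
        proxy for the cell-occupied areal fraction.
    diameter_um : (rows, cols) float array
        Mean capillary diameter per cell in micrometres; NaN where no
        vessel was found.
    mask : (rows, cols) bool array
        True for cells whose center lies inside the tumor contour.
    x_edges, y_edges : 1D float arrays
        Cell edge coordinates in micrometres (cols + 1 and rows + 1 long).
    """

    vasculature_pct: np.ndarray
    perfusion_pct: np.ndarray
    diameter_um: np.ndarray
    mask: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self) -> None:
        self.vasculature_pct = np.asarray(self.vasculature_pct, dtype=float)
        self.perfusion_pct = np.asarray(self.perfusion_pct, dtype=float)
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        r, c = self.vasculature_pct.shape
        for name in ("perfusion_pct", "diameter_um", "mask"):
            if getattr(self, name).shape != (r, c):
                raise ValueError(f"{name} shape mismatch with vasculature_pct")
        if self.x_edges.shape != (c + 1,) or self.y_edges.shape != (r + 1,):
            raise ValueError("edge arrays inconsistent with grid shape")
        for name in ("vasculature_pct", "perfusion_pct"):
            a = getattr(self, name)[self.mask]
            if a.size and (np.nanmin(a) < -1e-9 or np.nanmax(a) > 100 + 1e-9):
                raise ValueError(f"{name} outside [0, 100]")
        d = self.diameter_um[self.mask]
        d = d[np.isfinite(d)]
        if d.size and d.min() <= 0:
            raise ValueError("capillary diameters must be positive where present")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.vasculature_pct.shape

    @property
    def cell_centers(self) -> np.ndarray:
        """(rows, cols, 2) cell-center coordinates in micrometres."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc)
        return np.stack([xx, yy], axis=-1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell table (row, col, x_um, y_um, fields, masked)."""
        r, c = self.grid_shape
        rows, cols = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
        centers = self.cell_centers
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "x_um": centers[..., 0].ravel(),
                "y_um": centers[..., 1].ravel(),
                "vasculature_pct": self.vasculature_pct.ravel(),
                "perfusion_pct": self.perfusion_pct.ravel(),
                "diameter_um": self.diameter_um.ravel(),
                "masked": (~self.mask).ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, x_edges: np.ndarray | None = None,
        y_edges: np.ndarray | None = None,
    ) -> "HeatmapGrid":
        r = int(df["row"].max()) + 1
        c = int(df["col"].max()) + 1
        order = df.sort_values(["row", "col"])

        def grid(col):
            return np.asarray(order[col], dtype=float).reshape(r, c)

        if x_edges is None or y_edges is None:
            # reconstruct uniform edges from cell centers
            xc = np.sort(order["x_um"].unique())
            yc = np.sort(order["y_um"].unique())
            dx = xc[1] - xc[0] if len(xc) > 1 else 1.0
            dy = yc[1] - yc[0] if len(yc) > 1 else 1.0
            x_edges = np.concatenate([xc - dx / 2, [xc[-1] + dx / 2]])
            y_edges = np.concatenate([yc - dy / 2, [yc[-1] + dy / 2]])
        return cls(
            vasculature_pct=grid("vasculature_pct"),
            perfusion_pct=grid("perfusion_pct"),
            diameter_um=grid("diameter_um"),
            mask=~grid("masked").astype(bool),
            x_edges=np.asarray(x_edges, float),
            y_edges=np.asarray(y_edges, float),
        )

    @classmethod
    def read_csv(cls, path) -> "HeatmapGrid":
        return cls.from_frame(pd.read_csv(path))


def _full_scale(channel: np.ndarray) -> float:
    if np.issubdtype(channel.dtype, np.integer):
        return float(np.iinfo(channel.dtype).max)
    return 1.0


def threshold_channel(
    channel: np.ndarray, threshold_fraction: float, mode: str = "fraction"
) -> np.ndarray:
    """Binarize a single stain channel.

    ``mode="fraction"`` marks a pixel positive iff its intensity exceeds
    ``threshold_fraction`` times the full-scale intensity of the dtype
    (255 for 8-bit, 1.0 for float images).  ``mode="percentile"`` instead
    thresholds at the given percentile of the intensity histogram.  The
    fraction reading is the default interpretation of an over/under
    threshold with a fixed "minimum below" setting.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty image")
    if channel.ndim != 2:
        raise ValueError("threshold_channel expects a single 2D channel")
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in [0, 1]")
    if mode == "fraction":
        cut = threshold_fraction * _full_scale(channel)
    elif mode == "percentile":
        cut = float(np.percentile(channel, threshold_fraction * 100.0))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return channel > cut


def _cell_slices(shape: tuple[int, int], grid_shape: tuple[int, int]):
    """Slices of near-equal pixel blocks tiling the image."""
    rows, cols = grid_shape
    h, w = shape
    if rows > h or cols > w:
        raise ValueError("grid cell with zero pixels (grid finer than image)")
    r_edges = np.linspace(0, h, rows + 1).round().astype(int)
    c_edges = np.linspace(0, w, cols + 1).round().astype(int)
    return r_edges, c_edges


def grid_coverage(mask: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Percent of positively stained pixels per grid cell.

    Each cell value is 100 * (positive pixels) / (pixels in cell); cells
    tile the mask exactly, so coverage times cell pixel count sums back to
    the total positive area.
    """
    mask = np.asarray(mask, dtype=bool)
    r_edges, c_edges = _cell_slices(mask.shape, grid_shape)
    rows, cols = grid_shape
    out = np.empty((rows, cols), dtype=float)
    for i in range(rows):
        for j in range(cols):
            cell = mask[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            if cell.size == 0:
                raise ValueError(f"grid cell ({i}, {j}) has zero pixels")
            out[i, j] = 100.0 * cell.sum() / cell.size
    return out


def _component_widths(
    mask: np.ndarray, labels: np.ndarray, skeleton: np.ndarray,
    edt: np.ndarray, which: np.ndarray, pixel_size: float,
) -> np.ndarray:
    widths = np.empty(len(which), dtype=float)
    for i, lab in enumerate(which):
        on_skel = edt[(labels == lab) & skeleton]
        if on_skel.size == 0:
            # component too small to skeletonize; fall back to the thickest
            # inscribed disk
            on_skel = np.array([edt[labels == lab].max()])
        widths[i] = 2.0 * float(np.median(on_skel)) * pixel_size
    return widths


def measure_capillary_diameters(
    vessel_mask: np.ndarray,
    n_samples: int = 6,
    pixel_size: float = 1.0,
    seed: int = 0,
    cell: tuple[slice, slice] | None = None,
    _precomputed: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> float:
    """Mean diameter (um) of up to ``n_samples`` random vessels in a cell.

    Vessels are the connected components of ``vessel_mask`` whose centroid
    falls inside ``cell`` (a pair of slices; whole frame if None).  A
    component's width is twice the median distance-transform value along
    its skeleton, converted by ``pixel_size`` (um/px) — the automated
    analogue of placing a caliper across a stained capillary.  Returns NaN
    when the cell holds no vessel.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if _precomputed is None:
        labels, _ = ndimage.label(vessel_mask)
        skeleton = skeletonize(vessel_mask)
        edt = ndimage.distance_transform_edt(vessel_mask)
    else:
        labels, skeleton, edt = _precomputed
    n_lab = labels.max()
    if n_lab == 0:
        return float("nan")
    centroids = np.asarray(ndimage.center_of_mass(vessel_mask, labels,
                                                  np.arange(1, n_lab + 1)))
    if cell is None:
        inside = np.arange(1, n_lab + 1)
    else:
        rs, cs = cell
        r0 = rs.start or 0
        r1 = rs.stop if rs.stop is not None else vessel_mask.shape[0]
        c0 = cs.start or 0
        c1 = cs.stop if cs.stop is not None else vessel_mask.shape[1]
        sel = ((centroids[:, 0] >= r0) & (centroids[:, 0] < r1)
               & (centroids[:, 1] >= c0) & (centroids[:, 1] < c1))
        inside = np.nonzero(sel)[0] + 1
    if inside.size == 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    if inside.size > n_samples:
        inside = rng.choice(inside, size=n_samples, replace=False)
    widths = _component_widths(vessel_mask, labels, skeleton, edt, inside,
                               pixel_size)
    return float(widths.mean())


def build_heatmaps(
    image: np.ndarray,
    grid_shape: tuple[int, int] = (9, 9),
    thresholds: tuple[float, float] = (0.95, 0.79),
    pixel_size: float = 1.0,
    seed: int = 0,
    contour: np.ndarray | None = None,
    n_diameter_samples: int = 6,
    threshold_mode: str = "fraction",
) -> HeatmapGrid:
    """Quantify a two-channel image into the three per-cell heatmaps.

    Parameters
    ----------
    image : (H, W, 2) array
        Channel 0 = vascular stain, channel 1 = perfusion stain.
    thresholds : (vascular, perfusion) fractions of full scale.
    contour : optional (N, 2) polygon in micrometres; cells whose center
        falls outside it are masked out.  Without a contour the whole
        frame counts as tumor.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 2:
        raise ValueError("expected a (H, W, 2) two-channel image")
    vessel_mask = threshold_channel(image[..., 0], thresholds[0], threshold_mode)
    perf_mask = threshold_channel(image[..., 1], thresholds[1], threshold_mode)

    vasc_pct = grid_coverage(vessel_mask, grid_shape)
    perf_pct = grid_coverage(perf_mask, grid_shape)

    labels, _ = ndimage.label(vessel_mask)
    skeleton = skeletonize(vessel_mask)
    edt = ndimage.distance_transform_edt(vessel_mask)
    pre = (labels, skeleton, edt)

    rows, cols = grid_shape
    r_edges, c_edges = _cell_slices(vessel_mask.shape, grid_shape)
    diam = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            diam[i, j] = measure_capillary_diameters(
                vessel_mask,
                n_samples=n_diameter_samples,
                pixel_size=pixel_size,
                seed=seed + i * cols + j,
                cell=(slice(r_edges[i], r_edges[i + 1]),
                      slice(c_edges[j], c_edges[j + 1])),
                _precomputed=pre,
            )

    h, w = vessel_mask.shape
    x_edges = c_edges * pixel_size
    y_edges = r_edges * pixel_size
    if contour is None:
        mask = np.ones((rows, cols), dtype=bool)
    else:
        poly = Polygon(np.asarray(contour, float))
        xc = 0.5 * (x_edges[:-1] + x_edges[1:])
        yc = 0.5 * (y_edges[:-1] + y_edges[1:])
        mask = np.array([[poly.contains(Point(x, y)) for x in xc] for y in yc])
    return HeatmapGrid(
        vasculature_pct=vasc_pct,
        perfusion_pct=perf_pct,
        diameter_um=diam,
        mask=mask,
        x_edges=np.asarray(x_edges, float),
        y_edges=np.asarray(y_edges, float),
    )
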