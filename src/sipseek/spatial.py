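"""Spatial interpolation of the biotic index and anomaly delineation.

Site BI values are gridded with inverse-distance weighting (IDW), an exact
and deterministic interpolator: the surface equals a site's BI at the site's
own location and stays inside the range of the input values everywhere else.
Anomaly zones are the 4-connected components of the cells at or above a
threshold, by default the background-site mean plus two standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class SurveySite:
    """A survey sampling site with its biotic index."""

    site_id: str
    easting_m: float
    northing_m: float
    bi_percent: float
    zone: str = "unknown"             # gas_field | background | unknown

    def __post_init__(self) -> None:
        if not (np.isfinite(self.easting_m) and np.isfinite(self.northing_m)):
            raise ValueError("coordinates must be finite")
        if not 0 <= self.bi_percent <= 100:
            raise ValueError("BI must lie in [0, 100]")


def sites_from_frame(df: pd.DataFrame) -> list[SurveySite]:
    """Build sites from a table with site_id/easting_m/northing_m/bi_percent."""
    zone = df["zone"] if "zone" in df else ["unknown"] * len(df)
    return [
        SurveySite(str(r.site_id), float(r.easting_m), float(r.northing_m),
                   float(r.bi_percent), str(z))
        for r, z in zip(df.itertuples(index=False), zone)
    ]


@dataclass
class AnomalyGrid:
    """A regular grid with an interpolated BI surface and anomaly mask."""

    origin: tuple[float, float]       # (easting, northing) of the lower-left cell centre
    cell_size: float                  # metres
    surface: np.ndarray               # (n_rows, n_cols), NaN where no site in radius
    mask: np.ndarray | None = None    # surface >= threshold
    threshold: float | None = None
    zone_labels: np.ndarray | None = None  # connected-component id per cell, 0 = none

    @property
    def shape(self) -> tuple[int, int]:
        return self.surface.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        x = self.origin[0] + self.cell_size * np.arange(cols)
        y = self.origin[1] + self.cell_size * np.arange(rows)
        return np.meshgrid(x, y)

    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """Write the surface in ESRI ASCII grid format (row 0 at the top)."""
        rows, cols = self.shape
        half = self.cell_size / 2.0
        data = np.where(np.isnan(self.surface), nodata, self.surface)
        with open(path, "w") as fh:
            fh.write(f"ncols {cols}\n")
            fh.write(f"nrows {rows}\n")
            fh.write(f"xllcorner {self.origin[0] - half}\n")
            fh.write(f"yllcorner {self.origin[1] - half}\n")
            fh.write(f"cellsize {self.cell_size}\n")
            fh.write(f"NODATA_value {nodata}\n")
            for row in data[::-1]:
                fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def idw_interpolate(
    sites: list[SurveySite],
    origin: tuple[float, float] | None = None,
    cell_size: float | None = None,
    shape: tuple[int, int] | None = None,
    power: float = 2.0,
    max_radius: float = np.inf,
    margin: float = 500.0,
) -> AnomalyGrid:
    """Inverse-distance-weighted interpolation of site BI onto a grid.

    value(x) = sum(w_i BI_i) / sum(w_i) with w_i = ||x - x_i||**(-power) over
    the sites within ``max_radius``.  A grid node coinciding with a site
    takes that site's BI exactly; nodes with no site in radius are NaN.

    When the grid is not given, it spans the sites' bounding box plus
    ``margin`` with a cell size of 1/200 of the longest extent.
    """
    if not sites:
        raise ValueError("need at least one site")
    if power <= 0:
        raise ValueError("power must be positive")
    xs = np.array([s.easting_m for s in sites])
    ys = np.array([s.northing_m for s in sites])
    bis = np.array([s.bi_percent for s in sites])
    # collapse co-located sites (mean BI) so duplicates do not double-weight
    coords, inverse = np.unique(np.column_stack([xs, ys]), axis=0, return_inverse=True)
    merged = np.zeros(len(coords))
    np.add.at(merged, inverse, bis)
    bis = merged / np.bincount(inverse)
    xs, ys = coords[:, 0], coords[:, 1]

    if origin is None or cell_size is None or shape is None:
        x0, x1 = xs.min() - margin, xs.max() + margin
        y0, y1 = ys.min() - margin, ys.max() + margin
        extent = max(x1 - x0, y1 - y0)
        if cell_size is None:
            cell_size = extent / 200.0 if extent > 0 else 1.0
        if origin is None:
            origin = (x0, y0)
        if shape is None:
            shape = (max(int(np.ceil((y1 - y0) / cell_size)) + 1, 1),
                     max(int(np.ceil((x1 - x0) / cell_size)) + 1, 1))
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one cell")

    gx = origin[0] + cell_size * np.arange(cols)
    gy = origin[1] + cell_size * np.arange(rows)
    xx, yy = np.meshgrid(gx, gy)
    # distances: (rows*cols, n_sites)
    dx = xx.ravel()[:, None] - xs[None, :]
    dy = yy.ravel()[:, None] - ys[None, :]
    dist = np.hypot(dx, dy)

    surface = np.full(rows * cols, np.nan)
    exact = dist < 1e-9
    has_exact = exact.any(axis=1)
    if has_exact.any():
        first = np.argmax(exact[has_exact], axis=1)
        surface[has_exact] = bis[first]

    in_range = dist <= max_radius
    todo = ~has_exact & in_range.any(axis=1)
    if todo.any():
        with np.errstate(divide="ignore"):
            w = np.where(in_range[todo], dist[todo] ** (-power), 0.0)
        surface[todo] = (w @ bis) / w.sum(axis=1)
    return AnomalyGrid(origin=tuple(origin), cell_size=float(cell_size),
                       surface=surface.reshape(rows, cols))


def delineate_anomaly(
    grid: AnomalyGrid,
    sites: list[SurveySite] | None = None,
    threshold: float | None = None,
    fallback_threshold: float = 10.0,
) -> AnomalyGrid:
    """Mark anomaly cells and label contiguous zones on an IDW surface.

    With no fixed ``threshold``, the adaptive rule uses the mean plus two
    standard deviations of the BI of the sites labelled ``background``; if no
    background sites exist the fixed ``fallback_threshold`` applies, with a
    warning.  Zones are 4-connected components of the mask; missing cells
    (NaN) are never part of the mask.
    """
    if threshold is None:
        bg = [s.bi_percent for s in (sites or []) if s.zone == "background"]
        if bg:
            threshold = float(np.mean(bg) + 2.0 * np.std(bg))
        else:
            warnings.warn("no background sites; using the fixed fallback threshold",
                          stacklevel=2)
            threshold = fallback_threshold
    mask = np.where(np.isnan(grid.surface), False, grid.surface >= threshold)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, _ = ndimage.label(mask, structure=structure)
    grid.mask = mask
    grid.threshold = float(threshold)
    grid.zone_labels = labels
    return grid


def mask_jaccard(grid: AnomalyGrid, polygon) -> float:
    """Jaccard overlap between the anomaly mask and a reference polygon.

    Computed over the grid's non-missing cells, comparing mask membership
    with polygon containment of each cell centre.
    """
    if grid.mask is None:
        raise ValueError("delineate_anomaly must run first")
    from shapely import contains_xy

    xx, yy = grid.cell_centers()
    valid = ~np.isnan(grid.surface)
    inside = contains_xy(polygon, xx[valid], yy[valid])
    mask = grid.mask[valid]
    union = np.logical_or(mask, inside).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(mask, inside).sum() / union)
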