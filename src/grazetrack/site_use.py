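"""Zone occupancy, Landscape Preference Index, and kernel-density heatmaps.

Occupancy is the fraction of GPS fixes falling inside each zone of interest
(shade, water, forage strips), a valid proxy for time at a constant fix rate;
a dt-weighted variant handles resampled data.  The Landscape Preference
Index (LPI) is the ratio of the proportion of time spent in a zone to the
proportion of the total area that zone occupies: LPI = 1 means use in
proportion to availability, > 1 preference, < 1 avoidance.

Kernel density maps are computed by binning fixes to the grid and convolving
with a discretized kernel (quartic by default, the common GIS heatmap
choice), which is exact up to cell discretization and fast at millions of
fixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from grazetrack.geometry import Zone, points_in_polygon
from grazetrack.gps_io import Trajectory


@dataclass(frozen=True)
class LpiResult:
    zone: str
    time_fraction: float
    area_fraction: float
    lpi: float


def lpi(time_fraction: float, area_fraction: float, zone: str = "") -> LpiResult:
    """Landscape Preference Index: time share over area share."""
    if not (0 < area_fraction <= 1):
        raise ValueError("area_fraction must be in (0, 1]")
    if not (0 <= time_fraction <= 1):
        raise ValueError("time_fraction must be in [0, 1]")
    return LpiResult(zone=zone, time_fraction=time_fraction, area_fraction=area_fraction,
                     lpi=time_fraction / area_fraction)


def zone_occupancy(traj: Trajectory, zones: list[Zone], weights=None) -> pd.DataFrame:
    """Percent of fixes inside each zone (closed convention).

    ``weights`` (optional, e.g. per-fix dt) switches from fix counts to a
    time-weighted tally.  Overlapping zones are tallied independently, so
    percentages may sum above 100.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    x, y = traj.xy
    if weights is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    rows = []
    for z in zones:
        inside = points_in_polygon(x, y, z.geometry)
        frac = float(w[inside].sum() / total)
        rows.append(
            {
                "zone": z.name,
                "n_inside": int(inside.sum()),
                "pct_of_day": 100.0 * frac,
                "hours": frac * 24.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DensityGrid:
    """Raster of kernel density values (points per m^2) over a paddock.

    ``values[i, j]`` is the density at the center of the cell in row ``i``
    (counted from the top, as in ESRI grids) and column ``j``; ``origin`` is
    the lower-left corner of the grid.
    """

    origin: tuple[float, float]
    cell_size_m: float
    values: np.ndarray  # shape (n_rows, n_cols)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def total_mass(self) -> float:
        """Integral of the density surface (should be ~ number of points)."""
        return float(self.values.sum() * self.cell_size_m**2)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size_m
        return xs, ys

    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        """Write the grid in ESRI ASCII raster format."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.origin[0]}\n")
            fh.write(f"yllcorner {self.origin[1]}\n")
            fh.write(f"cellsize {self.cell_size_m}\n")
            fh.write(f"NODATA_value {nodata}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def _kernel_profile(kernel: str, r2: np.ndarray, h: float) -> np.ndarray:
    """2-D kernel density profiles, each integrating to 1 over the plane."""
    u2 = r2 / h**2
    if kernel == "quartic":
        k = np.where(u2 <= 1.0, 3.0 / (np.pi * h**2) * (1.0 - u2) ** 2, 0.0)
    elif kernel == "epanechnikov":
        k = np.where(u2 <= 1.0, 2.0 / (np.pi * h**2) * (1.0 - u2), 0.0)
    elif kernel == "gaussian":
        k = 1.0 / (2.0 * np.pi * h**2) * np.exp(-0.5 * u2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return k


def kernel_density(
    points,
    bandwidth_m: float = 10.0,
    cell_size_m: float = 1.0,
    kernel: str = "quartic",
    bounds=None,
) -> DensityGrid:
    """Kernel density surface of fix locations.

    ``points`` is an (N, 2) array or a planar Trajectory.  The grid covers
    the point (or ``bounds``) bounding box plus a bandwidth margin so the
    kernel mass is conserved:  sum(values) * cell_area ~= N.
    """
    if isinstance(points, Trajectory):
        x, y = points.xy
    else:
        pts = np.asarray(points, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    if len(x) == 0:
        raise ValueError("no points")
    if bandwidth_m <= 0:
        raise ValueError("bandwidth must be > 0")
    if cell_size_m >= 2 * bandwidth_m:
        import warnings

        warnings.warn("cell size >= 2x bandwidth: kernel is undersampled", stacklevel=2)

    margin = bandwidth_m if kernel != "gaussian" else 5.0 * bandwidth_m
    if bounds is None:
        xmin, xmax = x.min(), x.max()
        ymin, ymax = y.min(), y.max()
    else:
        xmin, ymin, xmax, ymax = bounds
    x0 = xmin - margin
    y0 = ymin - margin
    n_cols = int(np.ceil((xmax + margin - x0) / cell_size_m)) + 1
    n_rows = int(np.ceil((ymax + margin - y0) / cell_size_m)) + 1

    # bin points to cells, then convolve with the discretized kernel
    ci = np.clip(((x - x0) / cell_size_m).astype(int), 0, n_cols - 1)
    ri = np.clip(((y - y0) / cell_size_m).astype(int), 0, n_rows - 1)
    counts = np.zeros((n_rows, n_cols))
    np.add.at(counts, (ri, ci), 1.0)

    half = int(np.ceil(margin / cell_size_m))
    offs = (np.arange(-half, half + 1) * cell_size_m)
    r2 = offs[:, None] ** 2 + offs[None, :] ** 2
    kern = _kernel_profile(kernel, r2, bandwidth_m)
    # normalize the discrete kernel so binning does not lose mass
    kern = kern / (kern.sum() * cell_size_m**2)

    dens = fftconvolve(counts, kern, mode="same")
    dens = np.maximum(dens, 0.0)  # clip fft ringing
    # rows are stored top-down (ESRI convention)
    return DensityGrid(origin=(x0, y0), cell_size_m=cell_size_m, values=dens[::-1, :])


def hotspot_summary(grid: DensityGrid, quantile: float = 0.95) -> pd.DataFrame:
    """Cells with density strictly above the given quantile of cell values.

    Returns a table of flagged cell centers and their densities — the
    "dark red" high-use areas of a heatmap.
    """
    thresh = float(np.quantile(grid.values, quantile))
    rows_idx, cols_idx = np.nonzero(grid.values > thresh)
    xs, ys = grid.cell_centers()
    return pd.DataFrame(
        {
            "x": xs[cols_idx],
            "y": ys[rows_idx],
            "density": grid.values[rows_idx, cols_idx],
        }
    )
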