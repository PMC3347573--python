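"""Gene-geographic interpolation of a population statistic onto a raster.

A scalar statistic known at reference points (the sampled populations, with
lat/lon coordinates — e.g. their multilocus average heterozygosity) is
spread over a uniform longitude/latitude grid by generalized Shepard
inverse-distance weighting: each node value is

    z(node) = sum_i w_i z_i / sum_i w_i,   w_i = 1 / d_i^power,

over the reference points within a cutoff radius (defaults: cube weighting,
``power=3``, and a 3,000 km radius).  Distances are great-circle
(haversine, Earth radius 6371 km) — over continental extents planar
distance would be badly distorted.  A node coinciding with a reference
point takes its value exactly; a node with no point in radius is no-data.
Because the weights form a convex combination, every interpolated value
lies within the range of the reference values.

The grid carries an optional boolean land mask (user-supplied; nothing is
bundled) and a legend-statistics block: number of reference points K,
number of grid nodes N, and min/max/mean/std of the interpolated surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoGrid",
    "ReferencePoint",
    "greatcircle_km",
    "build_grid",
    "shepard_interpolate",
    "grid_stats",
    "write_esri_ascii",
    "render_png",
]


@dataclass(frozen=True)
class ReferencePoint:
    """A population anchoring the interpolation: location plus statistic."""

    population_id: str
    lat: float
    lon: float
    z: float

    def __post_init__(self) -> None:
        if not (-90 <= self.lat <= 90) or not (-180 < self.lon <= 180):
            raise ValueError(f"invalid coordinates for {self.population_id}")
        if not np.isfinite(self.z):
            raise ValueError(f"non-finite value for {self.population_id}")


@dataclass
class GeoGrid:
    """Uniform lon/lat raster with values, optional mask, legend stats."""

    lon: np.ndarray  # (n_cols,)
    lat: np.ndarray  # (n_rows,)
    values: np.ndarray  # (n_rows, n_cols), NaN = no-data
    mask: np.ndarray | None = None  # True = usable (land); same shape
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values shape must be (n_rows, n_cols)")
        if self.mask is not None and self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")

    @property
    def n_nodes(self) -> int:
        return int(self.values.size)

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum()) if self.mask is not None else self.n_nodes

    def to_frame(self) -> pd.DataFrame:
        lon2, lat2 = np.meshgrid(self.lon, self.lat)
        return pd.DataFrame(
            {"lon": lon2.ravel(), "lat": lat2.ravel(), "value": self.values.ravel()}
        )


def greatcircle_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine great-circle distance in km; broadcasts over arrays."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def build_grid(
    bounds: tuple[float, float, float, float] = (10.0, 180.0, 35.0, 75.0),
    n_cols: int = 881,
    n_rows: int = 381,
    mask: np.ndarray | None = None,
) -> GeoGrid:
    """Uniform grid over ``(lon_min, lon_max, lat_min, lat_max)``.

    Nodes are evenly spaced inclusive of the bounds; the node count is
    ``n_cols x n_rows`` (the study-scale default, 881 x 381 = 335,661
    nodes over North Eurasia).
    """
    lon_min, lon_max, lat_min, lat_max = bounds
    if n_cols < 2 or n_rows < 2:
        raise ValueError("grid needs at least 2 columns and rows")
    if lon_min >= lon_max or lat_min >= lat_max:
        raise ValueError("degenerate bounds")
    lon = np.linspace(lon_min, lon_max, n_cols)
    lat = np.linspace(lat_min, lat_max, n_rows)
    values = np.full((n_rows, n_cols), np.nan)
    return GeoGrid(lon=lon, lat=lat, values=values, mask=mask)


def shepard_interpolate(
    points: Sequence[ReferencePoint],
    grid: GeoGrid,
    power: float = 3.0,
    radius_km: float = 3000.0,
) -> GeoGrid:
    """Inverse-distance-power interpolation with a hard cutoff radius.

    Returns a new grid; masked nodes stay NaN, as do nodes with no
    reference point within ``radius_km``.  Duplicate reference coordinates
    with different values are ambiguous and rejected.
    """
    if not points:
        raise ValueError("need at least one reference point")
    seen: dict[tuple[float, float], float] = {}
    for p in points:
        key = (round(p.lat, 9), round(p.lon, 9))
        if key in seen and seen[key] != p.z:
            raise ValueError(f"duplicate reference coordinates at {key} with different values")
        seen[key] = p.z

    plat = np.array([p.lat for p in points])
    plon = np.array([p.lon for p in points])
    pz = np.array([p.z for p in points])

    values = np.full_like(grid.values, np.nan)
    lon2, lat2 = np.meshgrid(grid.lon, grid.lat)
    # distance cube blows up near zero; treat < 1e-9 km as coincident
    for r in range(values.shape[0]):
        d = greatcircle_km(lat2[r][:, None], lon2[r][:, None], plat[None, :], plon[None, :])
        within = d <= radius_km
        w = np.where(within, 1.0 / np.maximum(d, 1e-9) ** power, 0.0)
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row_vals = (w @ pz) / wsum
        row_vals[wsum == 0.0] = np.nan
        exact = d < 1e-9
        hit = exact.any(axis=1)
        if hit.any():
            row_vals[hit] = pz[exact.argmax(axis=1)[hit]]
        values[r] = row_vals
    if grid.mask is not None:
        values[~grid.mask] = np.nan
    out = GeoGrid(lon=grid.lon.copy(), lat=grid.lat.copy(), values=values, mask=grid.mask)
    out.stats = grid_stats(out, points)
    return out


def grid_stats(grid: GeoGrid, points: Sequence[ReferencePoint]) -> dict:
    """Legend block: K reference points, N usable nodes, min/max/aver/std."""
    vals = grid.values[np.isfinite(grid.values)]
    if vals.size == 0:
        raise ValueError("grid has no interpolated values")
    return {
        "K": len(points),
        "N": grid.n_usable,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "aver": float(vals.mean()),
        "std": float(vals.std(ddof=0)),
    }


def write_esri_ascii(grid: GeoGrid, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII raster export (row order north to south)."""
    dlon = float(grid.lon[1] - grid.lon[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {len(grid.lon)}\n")
        fh.write(f"nrows {len(grid.lat)}\n")
        fh.write(f"xllcorner {grid.lon[0]:.6f}\n")
        fh.write(f"yllcorner {grid.lat[0]:.6f}\n")
        fh.write(f"cellsize {dlon:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        vals = np.where(np.isfinite(grid.values), grid.values, nodata)
        for row in vals[::-1]:
            fh.write(" ".join(f"{x:.6g}" for x in row) + "\n")


def render_png(
    grid: GeoGrid,
    path,
    points: Sequence[ReferencePoint] = (),
    n_classes: int = 8,
    cmap: str = "YlOrBr",
) -> None:
    """Optional raster rendering with class breaks (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm

    vals = grid.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("grid has no interpolated values to render")
    breaks = np.linspace(finite.min(), finite.max(), n_classes + 1)
    norm = BoundaryNorm(breaks, ncolors=256)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    im = ax.imshow(
        vals,
        origin="lower",
        extent=(grid.lon[0], grid.lon[-1], grid.lat[0], grid.lat[-1]),
        aspect="auto",
        cmap=cmap,
        norm=norm,
    )
    if points:
        ax.scatter([p.lon for p in points], [p.lat for p in points], s=12, c="red")
    fig.colorbar(im, ax=ax, ticks=breaks, format="%.3f")
    stats = grid.stats or (grid_stats(grid, points) if points else {})
    if stats:
        label = "  ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}" for k, v in stats.items())
        ax.set_title(label, fontsize=8)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
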