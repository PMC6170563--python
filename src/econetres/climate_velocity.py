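"""Historical climate-change velocity from paired current / past climate grids.

Velocity at a site is the temporal climate gradient (absolute difference
between current and Last-Glacial-Maximum conditions at the site's cell)
divided by the local spatial gradient of the current climate surface
(units per km), giving the km of displacement needed to track the climatic
shift.  Time normalization (dividing by the ~21 kyr span) is optional and
off by default.

Grids are ESRI ASCII rasters on a geographic (lon/lat) lattice.  The spatial
gradient uses Horn's 8-neighbour third-order finite difference, with
horizontal distances from great-circle (haversine) cell spacing evaluated at
each cell's latitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "VelocityResult",
    "read_ascii_grid",
    "write_ascii_grid",
    "temporal_gradient",
    "spatial_slope",
    "climate_velocity",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088
#: km per degree of latitude along a meridian (great-circle)
KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0
#: spatial-gradient floor (units/km) applied before division; flat climate
#: surfaces would otherwise give infinite velocity
DEFAULT_SLOPE_FLOOR = 1e-6
LGM_YEARS = 21_000.0


@dataclass(frozen=True)
class RasterGrid:
    """Row-major raster; row 0 is the NORTHERN edge (ESRI ASCII convention)."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]  # (lon, lat) of the lower-left corner
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 3:
            raise ValueError("raster must be at least 3x3 for slope computation")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; row 0 at the top."""
        lon0, lat0 = self.origin
        col = int(np.floor((lon - lon0) / self.cell_size))
        row_from_bottom = int(np.floor((lat - lat0) / self.cell_size))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"site ({lat}, {lon}) outside raster extent")
        return row, col

    def cell_latitude(self, row: int) -> float:
        """Latitude of the cell-centre for a given row."""
        lon0, lat0 = self.origin
        return lat0 + (self.nrows - 1 - row + 0.5) * self.cell_size

    def is_nodata(self, value: float) -> bool:
        return value == self.nodata or np.isnan(value)

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class VelocityResult:
    site_id: str
    temporal_gradient: float
    spatial_gradient: float
    velocity: float
    slope_floored: bool = False


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII (.asc) raster."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} values, found {values.size}")
    return RasterGrid(
        values.reshape(nrows, ncols),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return path


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def temporal_gradient(current: RasterGrid, past: RasterGrid, lat: float, lon: float) -> float:
    """|current - past| at the cell containing the site."""
    if not current.same_geometry(past):
        raise ValueError("current and past grids must share geometry")
    r, c = current.cell_index(lat, lon)
    cur, pst = current.values[r, c], past.values[r, c]
    if current.is_nodata(cur) or past.is_nodata(pst):
        raise ValueError(f"site ({lat}, {lon}) falls on a nodata cell")
    return abs(float(cur) - float(pst))


def spatial_slope(
    current: RasterGrid, lat: float, lon: float, edge_policy: str = "error"
) -> float:
    """Gradient magnitude (units per km) of the climate surface at the site.

    Horn's method: third-order finite difference over the 3x3 window with the
    4-neighbours double-weighted.  East-west spacing is the haversine distance
    between adjacent cell centres on the cell's own row; north-south spacing
    is the (constant) meridian arc per cell.
    """
    r, c = current.cell_index(lat, lon)
    on_edge = r in (0, current.nrows - 1) or c in (0, current.ncols - 1)
    if on_edge and edge_policy == "error":
        raise ValueError(f"site ({lat}, {lon}) lies on the raster edge")
    if on_edge and edge_policy != "reflect":
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    idx_r = np.clip(np.arange(r - 1, r + 2), 0, current.nrows - 1)
    idx_c = np.clip(np.arange(c - 1, c + 2), 0, current.ncols - 1)
    win = current.values[np.ix_(idx_r, idx_c)]
    if any(current.is_nodata(v) for v in win.ravel()):
        raise ValueError(f"nodata in the 3x3 neighbourhood of site ({lat}, {lon})")
    cell_lat = current.cell_latitude(r)
    dx_km = _haversine_km(cell_lat, 0.0, cell_lat, current.cell_size)
    dy_km = KM_PER_DEG_LAT * current.cell_size
    # Horn weights; win[0] is the northern row
    a, b, bb = win[0]
    d, _, f = win[1]
    g, h, i = win[2]
    dz_dx = ((bb + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_km)
    dz_dy = ((a + 2 * b + bb) - (g + 2 * h + i)) / (8.0 * dy_km)
    return float(np.hypot(dz_dx, dz_dy))


def climate_velocity(
    current: RasterGrid,
    past: RasterGrid,
    lat: float,
    lon: float,
    site_id: str = "",
    slope_floor: float = DEFAULT_SLOPE_FLOOR,
    normalize_time: bool = False,
    edge_policy: str = "error",
) -> VelocityResult:
    """Climate-change velocity = temporal gradient / max(spatial slope, floor).

    Units: km of displacement over the glacial-interglacial span, or km/yr if
    ``normalize_time`` divides by the 21 000-yr span.
    """
    tg = temporal_gradient(current, past, lat, lon)
    slope = spatial_slope(current, lat, lon, edge_policy=edge_policy)
    floored = slope < slope_floor
    v = tg / max(slope, slope_floor)
    if normalize_time:
        v /= LGM_YEARS
    return VelocityResult(site_id, tg, slope, v, slope_floored=floored)
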