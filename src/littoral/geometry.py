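"""Core spatial containers: lake geometry, depth rasters and survey transects.

All coordinates are planar metric (metres); no CRS handling is attempted.
Vector data round-trips through GeoJSON, rasters through ESRI ASCII grid —
both plain-text formats.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Point, Polygon, mapping, shape

NODATA = -9999.0

__all__ = [
    "LakeGeometry",
    "DepthGrid",
    "Transect",
    "read_lake_geojson",
    "write_lake_geojson",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class Transect:
    """A 30 m wide survey strip running from the shoreline into the lake.

    ``onshore_normal_deg`` is the compass bearing (0° = north, clockwise)
    of the inward perpendicular, i.e. the direction from the shore anchor
    towards open water.
    """

    transect_id: str
    anchor: Point
    onshore_normal_deg: float
    width_m: float = 30.0
    c_max_tr: float | None = None
    lake_id: str | None = None

    def __post_init__(self) -> None:
        self.onshore_normal_deg = float(self.onshore_normal_deg) % 360.0
        if self.width_m <= 0:
            raise ValueError("transect width must be positive")


@dataclass
class LakeGeometry:
    """Shoreline polygon plus depth-labelled isobath polylines.

    ``isobaths`` maps are (depth_m, polyline) pairs; depths must be positive
    and no deeper than ``z_max``.  ``lake_area_P_ha`` is the polygon area in
    hectares (the P of the status index).
    """

    shoreline: Polygon
    isobaths: list[tuple[float, LineString]] = field(default_factory=list)
    islands: list[Polygon] = field(default_factory=list)
    z_max: float | None = None
    lake_id: str | None = None
    uniform_depth: float | None = None  # flat-lake depth tag when no isobaths

    def __post_init__(self) -> None:
        if not self.shoreline.is_valid or not self.shoreline.is_simple:
            raise ValueError("shoreline polygon is degenerate (self-intersecting)")
        if self.shoreline.area <= 0:
            raise ValueError("shoreline polygon has zero area")
        for depth, _ in self.isobaths:
            if depth <= 0:
                raise ValueError(f"isobath depth must be positive, got {depth}")
            if self.z_max is not None and depth > self.z_max:
                raise ValueError(f"isobath at {depth} m deeper than z_max={self.z_max} m")

    @property
    def lake_area_P_ha(self) -> float:
        area = self.shoreline.area - sum(i.area for i in self.islands)
        return area / 1e4

    @property
    def basin(self) -> Polygon:
        """Water surface: shoreline minus islands."""
        poly = self.shoreline
        for isl in self.islands:
            poly = poly.difference(isl)
        return poly


@dataclass
class DepthGrid:
    """Regular raster of water depth (m), NaN outside the lake.

    Registered to cell centers: cell (row, col) has center
    ``x = x0 + (col + 0.5) * cell_size``, ``y = y0 + (row + 0.5) * cell_size``
    with row 0 at the southern edge (rows increase northward).
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.values.shape
        xs = self.x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((y - self.y0) / self.cell_size))
        return row, col

    def sample(self, x, y):
        """Nearest-cell depth at planar points; NaN outside the raster."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        nr, nc = self.values.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.full(x.shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out


# ---------------------------------------------------------------------------
# GeoJSON I/O

def write_lake_geojson(geom: LakeGeometry, transects: list[Transect] | None, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom.shoreline),
            "properties": {"kind": "shoreline", "lake_id": geom.lake_id, "z_max": geom.z_max},
        }
    ]
    for isl in geom.islands:
        features.append({"type": "Feature", "geometry": mapping(isl), "properties": {"kind": "island"}})
    for depth, line in geom.isobaths:
        features.append(
            {"type": "Feature", "geometry": mapping(line), "properties": {"kind": "isobath", "depth_m": depth}}
        )
    for tr in transects or []:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(tr.anchor),
                "properties": {
                    "kind": "transect",
                    "transect_id": tr.transect_id,
                    "onshore_normal_deg": tr.onshore_normal_deg,
                    "width_m": tr.width_m,
                    "c_max_tr": tr.c_max_tr,
                    "lake_id": tr.lake_id,
                },
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_lake_geojson(path: str | Path) -> tuple[LakeGeometry, list[Transect]]:
    data = json.loads(Path(path).read_text())
    shoreline = None
    islands: list[Polygon] = []
    isobaths: list[tuple[float, LineString]] = []
    transects: list[Transect] = []
    lake_id = z_max = None
    for feat in data["features"]:
        props = feat.get("properties") or {}
        kind = props.get("kind")
        geo = shape(feat["geometry"])
        if kind == "shoreline":
            shoreline, lake_id, z_max = geo, props.get("lake_id"), props.get("z_max")
        elif kind == "island":
            islands.append(geo)
        elif kind == "isobath":
            isobaths.append((float(props["depth_m"]), geo))
        elif kind == "transect":
            transects.append(
                Transect(
                    transect_id=props["transect_id"],
                    anchor=geo,
                    onshore_normal_deg=props["onshore_normal_deg"],
                    width_m=props.get("width_m", 30.0),
                    c_max_tr=props.get("c_max_tr"),
                    lake_id=props.get("lake_id"),
                )
            )
    if shoreline is None:
        raise ValueError(f"{path}: no shoreline feature found")
    geom = LakeGeometry(shoreline=shoreline, isobaths=isobaths, islands=islands, z_max=z_max, lake_id=lake_id)
    return geom, transects


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster)

def write_ascii_grid(grid: DepthGrid, path: str | Path) -> None:
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    nr, nc = vals.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {grid.x0!r}\nyllcorner {grid.y0!r}\n"
        f"cellsize {grid.cell_size!r}\nNODATA_value {NODATA}\n"
    )
    body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in vals[::-1])  # top row first
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> DepthGrid:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    }:
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    vals = np.array([[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    vals = vals[::-1]  # back to south-up row order
    nodata = hdr.get("nodata_value", NODATA)
    vals[vals == nodata] = np.nan
    return DepthGrid(x0=hdr["xllcorner"], y0=hdr["yllcorner"], cell_size=hdr["cellsize"], values=vals)
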