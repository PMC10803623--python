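"""Depth raster from isobaths, slope raster, and per-transect littoral slopes.

The chain mirrors the standard GIS workflow for littoral-slope surveys:
interpolate depth from digitised contours, derive a slope map with Horn's
3x3 operator, then take zonal statistics over each transect strip.  Depth
interpolation is triangulation-based linear interpolation over densified
contour vertices (the shoreline acting as the 0 m contour): inside a lake
basin there is no drainage network to enforce, so a transparent
linear-between-contours surface replaces the hydrologically corrected
ANUDEM-style interpolant used with commercial GIS tooling.

Two slopes are reported per transect: ``Sl_1m``, the mean slope of the
shallow littoral down to the 1 m isobath (the helophyte zone), and
``Sl_Cmax``, the mean slope down to the isobath nearest the lake's maximum
colonisation depth (the hydrophyte zone).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import LineString, Point

from .geometry import DepthGrid, LakeGeometry, Transect

logger = logging.getLogger(__name__)

#: Slope-class thresholds on the deep littoral slope, degrees.
#: Below the first → gentle (2.3% grade); above the second → steep (14.8%).
GENTLE_MAX_DEG = 1.32
STEEP_MIN_DEG = 8.42

__all__ = [
    "interpolate_depth",
    "slope_raster",
    "transect_zone",
    "zonal_slope",
    "deg_to_pct",
    "classify_slope",
    "area_shallower_than",
    "SlopeResult",
]


@dataclass
class SlopeResult:
    transect_id: str
    sl_1m_deg: float
    sl_cmax_deg: float
    slope_class: str

    @property
    def sl_1m_pct(self) -> float:
        return deg_to_pct(self.sl_1m_deg)

    @property
    def sl_cmax_pct(self) -> float:
        return deg_to_pct(self.sl_cmax_deg)


def _densify(line, step: float) -> np.ndarray:
    n = max(int(math.ceil(line.length / step)), 1)
    dists = np.linspace(0.0, line.length, n + 1)
    pts = [line.interpolate(d) for d in dists]
    return np.array([[p.x, p.y] for p in pts])


def _check_isobaths(geometry: LakeGeometry) -> None:
    shore = geometry.shoreline.exterior
    labelled = sorted(geometry.isobaths, key=lambda t: t[0])
    for depth, line in labelled:
        if line.crosses(shore):
            raise ValueError(f"isobath at {depth} m crosses the shoreline")
    for i, (d1, l1) in enumerate(labelled):
        for d2, l2 in labelled[i + 1:]:
            if d1 != d2 and l1.crosses(l2):
                raise ValueError(f"isobaths at {d1} m and {d2} m cross each other")


def interpolate_depth(geometry: LakeGeometry, cell_size: float = 1.0) -> DepthGrid:
    """Build a depth raster from the shoreline (0 m) and labelled isobaths.

    Linear interpolation over the Delaunay triangulation of densified
    contour vertices; cells inside the polygon but outside the point hull
    (or inside the deepest closed contour) are filled by nearest-neighbour
    extrapolation.  Cells whose centre lies outside the lake are NaN.
    With no isobaths the lake must carry a ``uniform_depth`` tag, and the
    raster is that constant inside the basin.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    basin = geometry.basin
    minx, miny, maxx, maxy = basin.bounds
    x0 = minx - cell_size
    y0 = miny - cell_size
    nc = int(math.ceil((maxx - x0) / cell_size)) + 1
    nr = int(math.ceil((maxy - y0) / cell_size)) + 1
    xs = x0 + (np.arange(nc) + 0.5) * cell_size
    ys = y0 + (np.arange(nr) + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys)
    inside = contains_xy(basin, X, Y)

    if not geometry.isobaths:
        if geometry.uniform_depth is None:
            raise ValueError("lake has no isobaths and no uniform_depth tag")
        vals = np.where(inside, float(geometry.uniform_depth), np.nan)
        return DepthGrid(x0=x0, y0=y0, cell_size=cell_size, values=vals)

    _check_isobaths(geometry)
    step = max(cell_size, 1.0)
    pts = [_densify(LineString(geometry.shoreline.exterior.coords), step)]
    depths = [np.zeros(len(pts[0]))]
    for isl in geometry.islands:
        ring = _densify(LineString(isl.exterior.coords), step)
        pts.append(ring)
        depths.append(np.zeros(len(ring)))
    for depth, line in geometry.isobaths:
        ring = _densify(line, step)
        pts.append(ring)
        depths.append(np.full(len(ring), float(depth)))
    P = np.vstack(pts)
    Z = np.concatenate(depths)

    lin = LinearNDInterpolator(P, Z)
    vals = np.full(X.shape, np.nan)
    vals[inside] = lin(np.column_stack([X[inside], Y[inside]]))
    hole = inside & np.isnan(vals)
    if hole.any():
        near = NearestNDInterpolator(P, Z)
        vals[hole] = near(X[hole], Y[hole])
    vals[inside] = np.clip(vals[inside], 0.0, None)
    return DepthGrid(x0=x0, y0=y0, cell_size=cell_size, values=vals)


def _extrapolate_missing(z: np.ndarray, valid: np.ndarray, cs: float) -> np.ndarray:
    """Fill NaN cells with a first-order extension of the valid surface.

    Each missing cell takes depth + gradient x offset from its nearest
    *interior* valid cell (two erosions in, where central differences are
    untainted by the boundary).  Falls back to nearest-valid fill when the
    grid is too small to have such interior cells.
    """
    filled = z.copy()
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    filled[~valid] = z[idx[0][~valid], idx[1][~valid]]
    interior = ndimage.binary_erosion(valid, iterations=2)
    if not interior.any():
        return filled
    gy, gx = np.gradient(filled, cs)
    src = ndimage.distance_transform_edt(~interior, return_distances=False, return_indices=True)
    rr, cc = np.nonzero(~valid)
    sr, sc = src[0][rr, cc], src[1][rr, cc]
    filled[rr, cc] = z[sr, sc] + gy[sr, sc] * (rr - sr) * cs + gx[sr, sc] * (cc - sc) * cs
    return filled


def slope_raster(grid: DepthGrid) -> np.ndarray:
    """Per-cell slope in degrees via Horn's 3x3 finite differences.

    Missing cells are filled by linear extrapolation from the nearest
    interior cell (its depth plus its local gradient times the offset), so
    a planar basin continues as the same plane across the shoreline and the
    stencil sees no artificial flattening there; the raster border uses
    nearest-edge padding and the output is masked back to the valid cells.
    """
    z = grid.values
    valid = ~np.isnan(z)
    if valid.sum() < 9:
        raise ValueError("depth grid has fewer than 3x3 valid cells")
    if (~valid).any():
        z = _extrapolate_missing(z, valid, grid.cell_size)
    zp = np.pad(z, 1, mode="edge")
    cs = grid.cell_size
    a = zp[2:, :-2]; b = zp[2:, 1:-1]; c = zp[2:, 2:]
    d = zp[1:-1, :-2];                  f = zp[1:-1, 2:]
    g = zp[:-2, :-2]; h = zp[:-2, 1:-1]; i = zp[:-2, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    slope[~valid] = np.nan
    return slope


def transect_zone(
    transect: Transect,
    geometry: LakeGeometry,
    grid: DepthGrid,
    max_depth: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cells of the transect strip from the shore to the ``max_depth`` contour.

    The strip is a rectangle ``transect.width_m`` wide along the inward
    normal, truncated where the depth first reaches ``max_depth`` along the
    centerline.  Returns (rows, cols) index arrays of cells whose centers
    fall inside the strip and hold valid depths.
    """
    anchor = transect.anchor
    if anchor.distance(geometry.shoreline.exterior) > grid.cell_size:
        raise ValueError(
            f"transect {transect.transect_id}: anchor is {anchor.distance(geometry.shoreline.exterior):.2f} m "
            "off the shoreline (> one cell)"
        )
    b = math.radians(transect.onshore_normal_deg)
    ux, uy = math.sin(b), math.cos(b)  # compass bearing -> unit vector

    # walk the centerline until depth first reaches max_depth
    minx, miny, maxx, maxy = geometry.shoreline.bounds
    reach = math.hypot(maxx - minx, maxy - miny)
    step = grid.cell_size / 2.0
    s = np.arange(step, reach + step, step)
    px = anchor.x + s * ux
    py = anchor.y + s * uy
    depth = grid.sample(px, py)
    hit = np.nonzero(depth >= max_depth)[0]
    if hit.size:
        length = s[hit[0]]
    else:
        # stop at the centroid side of the basin rather than crossing the lake
        cen = geometry.basin.centroid
        s_cen = (cen.x - anchor.x) * ux + (cen.y - anchor.y) * uy
        inside = contains_xy(geometry.basin, px, py)
        last = np.nonzero(inside)[0]
        s_exit = s[last[-1]] if last.size else step
        length = min(s_exit, max(s_cen, step))
        logger.warning(
            "transect %s: depth %.2f m never reached along centerline; zone truncated at %.1f m",
            transect.transect_id, max_depth, length,
        )
    half = transect.width_m / 2.0
    vx, vy = uy, -ux  # perpendicular
    rect = np.array(
        [
            (anchor.x + half * vx, anchor.y + half * vy),
            (anchor.x - half * vx, anchor.y - half * vy),
            (anchor.x - half * vx + length * ux, anchor.y - half * vy + length * uy),
            (anchor.x + half * vx + length * ux, anchor.y + half * vy + length * uy),
        ]
    )
    from shapely.geometry import Polygon as _Poly

    rect_poly = _Poly(rect)
    # restrict to the rectangle's bounding box before point-in-polygon
    bminx, bminy, bmaxx, bmaxy = rect_poly.bounds
    nr, nc = grid.values.shape
    c0 = max(int((bminx - grid.x0) / grid.cell_size) - 1, 0)
    c1 = min(int((bmaxx - grid.x0) / grid.cell_size) + 2, nc)
    r0 = max(int((bminy - grid.y0) / grid.cell_size) - 1, 0)
    r1 = min(int((bmaxy - grid.y0) / grid.cell_size) + 2, nr)
    xs = grid.x0 + (np.arange(c0, c1) + 0.5) * grid.cell_size
    ys = grid.y0 + (np.arange(r0, r1) + 0.5) * grid.cell_size
    X, Y = np.meshgrid(xs, ys)
    sel = contains_xy(rect_poly, X, Y) & ~np.isnan(grid.values[r0:r1, c0:c1])
    rows, cols = np.nonzero(sel)
    return rows + r0, cols + c0


def zonal_slope(cells: tuple[np.ndarray, np.ndarray], slope: np.ndarray) -> float:
    """Arithmetic mean slope (degrees) over the zone's cells."""
    rows, cols = cells
    if len(rows) == 0:
        raise ValueError("empty zone: no cells to average")
    vals = slope[rows, cols]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("zone contains no valid slope cells")
    return float(vals.mean())


def deg_to_pct(angle_deg: float, ndigits: int | None = 1) -> float:
    """Convert a slope angle in degrees to percent grade, tan(angle)*100.

    Reported values are rounded half-up to one decimal by default; pass
    ``ndigits=None`` for the raw value.
    """
    if not 0 <= angle_deg < 90:
        raise ValueError(f"angle must be in [0, 90), got {angle_deg}")
    pct = math.tan(math.radians(angle_deg)) * 100.0
    if ndigits is None:
        return pct
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(pct)).quantize(q, rounding=ROUND_HALF_UP))


def classify_slope(
    sl_cmax_deg: float,
    gentle_max: float = GENTLE_MAX_DEG,
    steep_min: float = STEEP_MIN_DEG,
) -> str:
    """Classify the deep littoral slope: gentle (<1.32°), steep (>8.42°), else moderate."""
    if not 0 <= sl_cmax_deg < 90:
        raise ValueError(f"slope angle out of range: {sl_cmax_deg}")
    if sl_cmax_deg < gentle_max:
        return "gentle"
    if sl_cmax_deg > steep_min:
        return "steep"
    return "moderate"


def area_shallower_than(grid: DepthGrid, depth: float = 2.5) -> float:
    """Lake area (ha) no deeper than ``depth`` m — the iso-2.5 area of the colonisation index."""
    n = int(np.sum(grid.values[~np.isnan(grid.values)] <= depth))
    return n * grid.cell_size**2 / 1e4


def cmax_isobath_depth(geometry: LakeGeometry, c_max: float) -> float:
    """Depth of the labelled isobath nearest the lake's maximum colonisation depth.

    Ties are broken toward the deeper isobath.
    """
    if not geometry.isobaths:
        raise ValueError("lake has no labelled isobaths")
    depths = sorted({d for d, _ in geometry.isobaths})
    best = min(depths, key=lambda d: (abs(d - c_max), -d))
    return best
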