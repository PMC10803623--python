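"""Synthetic lakes, bathymetry, wind series and macrophyte surveys.

Every downstream stage of the pipeline (slope recovery, fetch and exposure,
status indices, indicator analysis) is exercised against data generated
here with analytically known ground truth: star-shaped basins whose radial
depth profiles give exact slopes at every cell, wind series drawn from a
von Mises directional family with known mean and toward-sector mass, and
community tables whose charophyte covers follow a prescribed trophic
(total-phosphorus) effect.

Default scales emulate a lowland-lake monitoring survey: 8-27 transects
per lake, maximum colonisation depths of 2.0-8.5 m, total phosphorus in
0.015-0.049 mg/l, six years of hourly wind.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from shapely import contains_xy
from shapely.geometry import LineString, Point, Polygon

from .geometry import DepthGrid, LakeGeometry, Transect

__all__ = [
    "SyntheticLakeSpec",
    "SyntheticWindSpec",
    "SyntheticCommunitySpec",
    "make_lake",
    "make_wind",
    "make_survey",
]

_N_THETA = 720  # polygon / isobath vertex count


@dataclass
class SyntheticLakeSpec:
    """Recipe for one star-shaped lake basin.

    ``shape`` is one of ``circle``, ``ellipse`` (uses ``axes_m``) or
    ``irregular-harmonic`` (radius perturbed by low-order Fourier terms so
    the polygon stays simple and star-shaped).  ``profile`` controls depth
    as a function of distance-to-shore s along the radial ray:

    * ``conic``          — depth rises linearly to ``max_depth_m`` at the center;
    * ``planar-shelf``   — depth = ``shore_slope`` * s, capped at ``max_depth_m``
      (flat central shelf); with the default slope the cap sits at half-radius;
    * ``two-slope``      — slope ``shore_slope`` down to ``break_depth_m``,
      then ``deep_slope``, capped at ``max_depth_m``.
    """

    lake_id: str = "L1"
    shape: str = "circle"
    radius_m: float = 500.0
    axes_m: tuple[float, float] = (600.0, 400.0)
    max_depth_m: float = 10.0
    profile: str = "conic"
    shore_slope: float | None = None     # rise (m) per metre from shore
    break_depth_m: float | None = None   # two-slope profile only
    deep_slope: float | None = None
    n_transects: int = 12
    cell_size: float = 1.0
    isobath_interval_m: float = 1.0
    harmonic_amplitude: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in {"circle", "ellipse", "irregular-harmonic"}:
            raise ValueError(f"unknown shape: {self.shape!r}")
        if self.profile not in {"conic", "planar-shelf", "two-slope"}:
            raise ValueError(f"unknown profile: {self.profile!r}")
        if self.radius_m <= 0 or self.max_depth_m <= 0:
            raise ValueError("radius_m and max_depth_m must be positive")
        if not 8 <= self.n_transects <= 27:
            raise ValueError("n_transects must lie in [8, 27]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class SyntheticWindSpec:
    """Recipe for an hourly wind-station record.

    Directions follow a hierarchical von Mises model: each day gets a mean
    direction drawn around ``mean_direction_deg`` with the given
    ``concentration`` (0 = uniform, ``math.inf`` = point mass), emulating
    synoptic day-to-day variability, and hourly directions scatter around
    that day's mean with ``intraday_concentration``.  Speeds come from a
    Rayleigh-shaped Weibull with the requested mean.  The window spans
    ``years`` years, the standard averaging period preceding a macrophyte
    survey.
    """

    mean_direction_deg: float = 270.0
    concentration: float = 1.0
    intraday_concentration: float = 12.0
    mean_speed_ms: float = 3.5
    years: int = 6
    end: str = "2016-01-01"
    station_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mean_direction_deg < 360:
            raise ValueError("mean_direction_deg must be in [0, 360)")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.mean_speed_ms <= 0:
            raise ValueError("mean_speed_ms must be positive")


@dataclass
class SyntheticCommunitySpec:
    """Recipe for per-transect macrophyte community tables.

    The survey scale mirrors a national monitoring pool: 69 syntaxa of
    which two thirds are hydrophytes, with charophytes a subset of those.
    ``trophic_effect`` is a signed log-weight coupling charophyte presence
    and cover to the lake's total phosphorus (negative = charophytes
    decline as TP rises); 0 removes the association.
    """

    n_syntaxa: int = 69
    hydrophyte_fraction: float = 46 / 69
    charophyte_fraction: float = 0.2
    tp_range_mgL: tuple[float, float] = (0.015, 0.049)
    trophic_effect: float = -1.5
    syntaxa_per_transect: tuple[int, int] = (3, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.hydrophyte_fraction, self.charophyte_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.charophyte_fraction > self.hydrophyte_fraction:
            raise ValueError("charophytes are a subset of hydrophytes")
        lo, hi = self.tp_range_mgL
        if not 0 < lo <= hi:
            raise ValueError("tp_range_mgL must be a positive interval")


# ---------------------------------------------------------------------------
# lake geometry

def _radius_function(spec: SyntheticLakeSpec, rng: np.random.Generator):
    """Return R(theta) and its derivative R'(theta) for the star-shaped shoreline."""
    if spec.shape == "circle":
        r0 = spec.radius_m
        return (lambda t: np.full_like(np.asarray(t, float), r0),
                lambda t: np.zeros_like(np.asarray(t, float)))
    if spec.shape == "ellipse":
        a, b = spec.axes_m

        def R(t):
            t = np.asarray(t, float)
            return a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)

        def Rp(t):
            t = np.asarray(t, float)
            num = (b**2 - a**2) * np.sin(t) * np.cos(t)
            den = ((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2) ** 1.5
            return a * b * num / den

        return R, Rp
    # irregular-harmonic: r0 * (1 + sum a_k cos(k t + phi_k)), k = 2..5
    r0 = spec.radius_m
    ks = np.arange(2, 6)
    amps = rng.uniform(-spec.harmonic_amplitude, spec.harmonic_amplitude, size=ks.size) / ks
    phis = rng.uniform(0, 2 * np.pi, size=ks.size)

    def R(t):
        t = np.asarray(t, float)[..., None]
        return r0 * (1.0 + (amps * np.cos(ks * t + phis)).sum(axis=-1))

    def Rp(t):
        t = np.asarray(t, float)[..., None]
        return r0 * (-(amps * ks) * np.sin(ks * t + phis)).sum(axis=-1)

    return R, Rp


def _default_shore_slope(spec: SyntheticLakeSpec, mean_radius: float) -> float:
    if spec.shore_slope is not None:
        return spec.shore_slope
    return 2.0 * spec.max_depth_m / mean_radius


def _depth_from_shore(spec: SyntheticLakeSpec, s, R_local, shore_slope: float):
    """Depth at distance-to-shore s (m) along a ray with local shore radius R_local."""
    s = np.asarray(s, float)
    if spec.profile == "conic":
        return spec.max_depth_m * np.clip(s / R_local, 0.0, 1.0)
    if spec.profile == "planar-shelf":
        return np.minimum(shore_slope * s, spec.max_depth_m)
    brk = spec.break_depth_m if spec.break_depth_m is not None else spec.max_depth_m / 2.0
    deep = spec.deep_slope if spec.deep_slope is not None else 3.0 * shore_slope
    shallow = np.minimum(shore_slope * s, brk)
    extra = np.clip(s - brk / shore_slope, 0.0, None) * deep
    return np.minimum(shallow + extra, spec.max_depth_m)


def _shore_distance_of_depth(spec: SyntheticLakeSpec, level: float, R_local, shore_slope: float):
    """Invert the depth profile: distance from shore at which ``level`` is reached."""
    if spec.profile == "conic":
        return level / spec.max_depth_m * R_local
    if spec.profile == "planar-shelf":
        return level / shore_slope
    brk = spec.break_depth_m if spec.break_depth_m is not None else spec.max_depth_m / 2.0
    deep = spec.deep_slope if spec.deep_slope is not None else 3.0 * shore_slope
    if level <= brk:
        return level / shore_slope
    return brk / shore_slope + (level - brk) / deep


def make_lake(spec: SyntheticLakeSpec) -> tuple[LakeGeometry, DepthGrid, list[Transect]]:
    """Generate shoreline, labelled isobaths, analytic depth raster and transects.

    The returned :class:`DepthGrid` is the ground-truth bathymetry evaluated
    directly from the depth profile (not interpolated from the isobaths), so
    recovery tests can compare the full isobath->raster->slope chain to it.
    Transect anchors are spaced evenly by arc length along the shoreline
    with inward-pointing normals; each carries a maximum colonisation depth
    drawn from the 2.0-8.5 m survey range (truncated below 90% of the
    basin's depth).
    """
    rng = np.random.default_rng(spec.seed)
    R, Rp = _radius_function(spec, rng)

    # equal arc-length anchor angles, found by inverting the arclength integral
    t_dense = np.linspace(0.0, 2 * np.pi, 1 << 14)
    ds = np.sqrt(R(t_dense) ** 2 + Rp(t_dense) ** 2)
    arclen = cumulative_trapezoid(ds, t_dense, initial=0.0)
    targets = arclen[-1] * (np.arange(spec.n_transects) + 0.5) / spec.n_transects
    t_anchor = np.interp(targets, arclen, t_dense)

    # shoreline vertices: uniform fan plus the anchor angles, so every anchor
    # lies exactly on the polygon boundary
    t = np.unique(np.concatenate([np.linspace(0.0, 2 * np.pi, _N_THETA, endpoint=False), t_anchor]))
    rr = R(t)
    if np.any(rr <= 0):
        raise ValueError("degenerate shoreline: radius function is non-positive somewhere")
    ring = np.column_stack([rr * np.cos(t), rr * np.sin(t)])
    shoreline = Polygon(ring)
    if not shoreline.is_valid or not shoreline.is_simple:
        raise ValueError("degenerate shoreline polygon (self-intersection)")

    mean_radius = float(rr.mean())
    shore_slope = _default_shore_slope(spec, mean_radius)

    # labelled isobaths at regular depth intervals, plus the 2.5 m contour
    levels = set(np.arange(spec.isobath_interval_m, spec.max_depth_m, spec.isobath_interval_m).round(6))
    if 2.5 < spec.max_depth_m:
        levels.add(2.5)
    isobaths: list[tuple[float, LineString]] = []
    for level in sorted(levels):
        r_iso = rr - _shore_distance_of_depth(spec, level, rr, shore_slope)
        if np.any(r_iso <= 0):
            continue  # contour would collapse through the center
        pts = np.column_stack([r_iso * np.cos(t), r_iso * np.sin(t)])
        isobaths.append((float(level), LineString(np.vstack([pts, pts[:1]]))))

    geom = LakeGeometry(
        shoreline=shoreline, isobaths=isobaths, z_max=spec.max_depth_m, lake_id=spec.lake_id
    )

    # ground-truth depth raster
    cs = spec.cell_size
    minx, miny, maxx, maxy = shoreline.bounds
    x0, y0 = minx - cs, miny - cs
    nc = int(math.ceil((maxx - x0) / cs)) + 1
    nr = int(math.ceil((maxy - y0) / cs)) + 1
    xs = x0 + (np.arange(nc) + 0.5) * cs
    ys = y0 + (np.arange(nr) + 0.5) * cs
    X, Y = np.meshgrid(xs, ys)
    inside = contains_xy(shoreline, X, Y)
    tt = np.arctan2(Y, X)
    rad = np.hypot(X, Y)
    Rt = R(tt)
    depth = _depth_from_shore(spec, np.clip(Rt - rad, 0.0, None), Rt, shore_slope)
    vals = np.where(inside, depth, np.nan)
    grid = DepthGrid(x0=x0, y0=y0, cell_size=cs, values=vals)

    # transects with inward normals; colonisation depth capped by what the
    # depth profile can reach along each transect's own ray
    transects = []
    for i, ta in enumerate(t_anchor):
        ra, rpa = float(R(ta)), float(Rp(ta))
        x, y = ra * math.cos(ta), ra * math.sin(ta)
        # tangent of the polar curve, then the normal that points at the center
        tx = rpa * math.cos(ta) - ra * math.sin(ta)
        ty = rpa * math.sin(ta) + ra * math.cos(ta)
        nx, ny = ty, -tx
        if nx * (-x) + ny * (-y) < 0:
            nx, ny = -nx, -ny
        norm = math.hypot(nx, ny)
        bearing = math.degrees(math.atan2(nx / norm, ny / norm)) % 360.0
        reachable = float(_depth_from_shore(spec, ra, ra, shore_slope))
        c_hi = min(8.5, 0.9 * reachable)
        c_lo = min(2.0, 0.5 * reachable)
        transects.append(
            Transect(
                transect_id=f"{spec.lake_id}-T{i + 1:02d}",
                anchor=Point(x, y),
                onshore_normal_deg=bearing,
                c_max_tr=float(rng.uniform(c_lo, c_hi)),
                lake_id=spec.lake_id,
            )
        )
    return geom, grid, transects


# ---------------------------------------------------------------------------
# wind

def make_wind(spec: SyntheticWindSpec) -> pd.DataFrame:
    """Hourly wind records (timestamp, direction_deg, speed_ms) over the window."""
    rng = np.random.default_rng(spec.seed)
    n_days = spec.years * 365
    n = n_days * 24
    idx = pd.date_range(end=spec.end, periods=n, freq="h")
    mu = math.radians(spec.mean_direction_deg)
    if math.isinf(spec.concentration):
        day_means = np.full(n_days, mu)
    else:
        day_means = rng.vonmises(mu - math.pi, spec.concentration, size=n_days) + math.pi
    if math.isinf(spec.intraday_concentration):
        hourly = np.repeat(day_means, 24)
    else:
        jitter = rng.vonmises(0.0, spec.intraday_concentration, size=n)
        hourly = np.repeat(day_means, 24) + jitter
    directions = np.degrees(hourly) % 360.0
    # Rayleigh-shaped Weibull speeds scaled to the requested mean
    scale = spec.mean_speed_ms / math.gamma(1.5)
    speeds = scale * rng.weibull(2.0, size=n)
    df = pd.DataFrame({"timestamp": idx, "direction_deg": directions, "speed_ms": speeds})
    df.attrs["station_id"] = spec.station_id
    return df


# ---------------------------------------------------------------------------
# community survey

def make_survey(
    geom: LakeGeometry,
    transects: list[Transect],
    spec: SyntheticCommunitySpec,
    tp_mgL: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-transect community covers for one lake plus lake covariates.

    Returns ``(observations, transect_table, lake_attrs)``:

    * ``observations`` — long table (lake_id, transect_id, syntaxon_code,
      group, rel_cover_pct); relative covers sum to 100 per transect;
    * ``transect_table`` — per-transect total cover (%COV) and C_max_TR;
    * ``lake_attrs`` — lake_id, tp_mgL, z_max, lake_area_P_ha and the total
      vegetated area N (ha).

    Charophyte presence odds and cover weights are multiplied by
    ``exp(trophic_effect * z)`` where z is the lake's TP standardised to
    [-1, 1] over ``tp_range_mgL``, so a negative effect makes stonewort
    communities scarce in the most phosphorus-rich lakes.
    """
    if not transects:
        raise ValueError("no transects supplied")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.tp_range_mgL
    tp = float(rng.uniform(lo, hi)) if tp_mgL is None else float(tp_mgL)
    mid, half = (lo + hi) / 2.0, max((hi - lo) / 2.0, 1e-12)
    tp_z = (tp - mid) / half
    ch_weight = math.exp(spec.trophic_effect * tp_z)

    n = spec.n_syntaxa
    n_ch = int(round(spec.charophyte_fraction * n))
    n_hy = int(round(spec.hydrophyte_fraction * n)) - n_ch
    n_he = n - n_ch - n_hy
    codes = (
        [f"CH{i + 1:02d}" for i in range(n_ch)]
        + [f"HY{i + 1:02d}" for i in range(n_hy)]
        + [f"HE{i + 1:02d}" for i in range(n_he)]
    )
    groups = ["charophyte"] * n_ch + ["hydrophyte"] * n_hy + ["helophyte"] * n_he
    # lake-level commonness of each syntaxon (some communities are rare everywhere)
    commonness = rng.gamma(2.0, 0.5, size=n)

    obs_rows, tr_rows = [], []
    lo_s, hi_s = spec.syntaxa_per_transect
    for tr in transects:
        k = int(rng.integers(lo_s, hi_s + 1))
        w = commonness * np.where(np.array(groups) == "charophyte", ch_weight, 1.0)
        pick = rng.choice(n, size=min(k, n), replace=False, p=w / w.sum())
        alpha = np.where(np.array(groups)[pick] == "charophyte", ch_weight, 1.0)
        covers = rng.dirichlet(alpha) * 100.0
        for j, c in zip(pick, covers):
            obs_rows.append(
                {
                    "lake_id": geom.lake_id,
                    "transect_id": tr.transect_id,
                    "syntaxon_code": codes[j],
                    "group": groups[j],
                    "rel_cover_pct": float(c),
                }
            )
        tr_rows.append(
            {
                "lake_id": geom.lake_id,
                "transect_id": tr.transect_id,
                "total_cover_pct": float(rng.uniform(10.0, 100.0)),
                "c_max_tr": tr.c_max_tr,
            }
        )
    lake_attrs = {
        "lake_id": geom.lake_id,
        "tp_mgL": tp,
        "z_max": geom.z_max,
        "lake_area_P_ha": geom.lake_area_P_ha,
        "total_vegetated_area_N_ha": float(rng.uniform(0.05, 0.4) * geom.lake_area_P_ha),
    }
    return pd.DataFrame(obs_rows), pd.DataFrame(tr_rows), lake_attrs
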