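"""Effective fetch and wind-exposure index for littoral survey sites.

Effective fetch follows the five-ray scheme: from the transect anchor, the
uninterrupted over-water distance is measured along the inward normal and
along rays offset ±22.5° and ±45° from it (the extreme rays subtend 90°),
and the five lengths are averaged with the cosine of the offset as weight.

The exposure index combines fetch f (km), the share w of days with wind
blowing toward the site, the mean wind speed h (m/s) and the site depth d
(m):

    E = log(1 + f * w * h / d**2)

Daily wind directions are averaged with the Linear Directional Mean (LDM),
the circular mean computed as arctan(sum sin / sum cos) with an explicit
four-branch quadrant correction.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .geometry import LakeGeometry, Transect

logger = logging.getLogger(__name__)

#: Ray offsets from the onshore normal (degrees) and their cosine weights.
RAY_OFFSETS_DEG = (-45.0, -22.5, 0.0, 22.5, 45.0)
FETCH_WEIGHTS = (0.70711, 0.92388, 1.0, 0.92388, 0.70711)

_TOL = 1e-9  # metres; transversal-intersection tolerance


class UndefinedMeanError(ValueError):
    """Raised when the resultant vector of a direction set has ~zero length."""


def cast_fetch_rays(transect: Transect, geometry: LakeGeometry) -> list[float]:
    """Lengths (km) of the five fetch rays from the anchor to the first shore hit.

    Each ray runs from the anchor until it first meets the shoreline or an
    island boundary (the origin itself excluded).  A ray that leaves the
    lake immediately (concave anchor) gets length 0 with a warning.
    """
    anchor = transect.anchor
    basin = geometry.basin
    minx, miny, maxx, maxy = geometry.shoreline.bounds
    reach = 2.0 * math.hypot(maxx - minx, maxy - miny)
    # an anchor a hair off the polygon (digitisation noise) must not clip the ray
    start_tol = max(anchor.distance(basin.exterior) * 2.0, 1e-6)
    lengths = []
    for off in RAY_OFFSETS_DEG:
        b = math.radians((transect.onshore_normal_deg + off) % 360.0)
        ux, uy = math.sin(b), math.cos(b)
        ray = LineString([(anchor.x, anchor.y), (anchor.x + reach * ux, anchor.y + reach * uy)])
        inter = ray.intersection(basin)
        # open-water segments of the ray, ordered by where they start
        segs = []
        geoms = getattr(inter, "geoms", [inter]) if not inter.is_empty else []
        for g in geoms:
            if g.is_empty or not hasattr(g, "coords") or len(g.coords) < 2:
                continue
            ds = [math.hypot(x - anchor.x, y - anchor.y) for x, y in g.coords]
            segs.append((min(ds), max(ds)))
        segs.sort()
        first = next(((d0, d1) for d0, d1 in segs if d1 - d0 > _TOL), None)
        if first is None or first[0] > start_tol:
            logger.warning(
                "transect %s: ray %+.1f° leaves the lake immediately (concave anchor); length 0",
                transect.transect_id, off,
            )
            lengths.append(0.0)
        else:
            lengths.append(first[1] / 1000.0)
    return lengths


def effective_fetch(ray_lengths_km) -> float:
    """Cosine-weighted mean of the five ray lengths (km)."""
    rays = np.asarray(ray_lengths_km, dtype=float)
    if rays.shape != (5,):
        raise ValueError(f"expected 5 ray lengths, got {rays.shape}")
    if (rays < 0).any():
        raise ValueError("ray lengths must be non-negative")
    w = np.array(FETCH_WEIGHTS)
    return float((w * rays).sum() / w.sum())


def linear_directional_mean(directions_deg) -> float:
    """Circular mean of compass directions via the quadrant-corrected arctangent.

    Computes arctan(sum sin / sum cos) and resolves the quadrant by the signs
    of the two sums; result in [0°, 360°).  Raises :class:`UndefinedMeanError`
    when the resultant vector has (near-)zero length and no mean direction
    exists.
    """
    theta = np.radians(np.asarray(directions_deg, dtype=float))
    if theta.size == 0:
        raise ValueError("need at least one direction")
    S = float(np.sin(theta).sum())
    C = float(np.cos(theta).sum())
    if math.hypot(S, C) < 1e-9 * theta.size:
        raise UndefinedMeanError("resultant vector has ~zero length; mean direction undefined")
    if C == 0.0:
        return 90.0 if S >= 0 else 270.0
    a = abs(math.degrees(math.atan(S / C)))
    if S >= 0 and C > 0:
        ldm = a
    elif S >= 0 and C < 0:
        ldm = 180.0 - a
    elif S < 0 and C > 0:
        ldm = 360.0 - a
    else:  # S < 0 and C < 0
        ldm = 180.0 + a
    return ldm % 360.0


def daily_wind_summary(wind: pd.DataFrame) -> pd.DataFrame:
    """Collapse hourly records to one (LDM direction, mean speed) row per day.

    ``wind`` columns: ``timestamp`` (datetime-like), ``direction_deg``,
    ``speed_ms``.  Days with no records are simply absent; days whose
    direction resultant vanishes are dropped with a log entry.
    """
    if wind.empty:
        raise ValueError("wind series is empty")
    df = wind.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if not df["timestamp"].is_monotonic_increasing:
        df = df.sort_values("timestamp")
    theta = np.radians(df["direction_deg"].to_numpy())
    df["_sin"], df["_cos"] = np.sin(theta), np.cos(theta)
    agg = df.groupby(df["timestamp"].dt.date).agg(
        S=("_sin", "sum"), C=("_cos", "sum"), speed_ms=("speed_ms", "mean"), n=("_sin", "size")
    )
    S, C = agg["S"].to_numpy(), agg["C"].to_numpy()
    defined = np.hypot(S, C) >= 1e-9 * agg["n"].to_numpy()
    if (~defined).any():
        logger.info("%d day(s) with undefined mean direction skipped", int((~defined).sum()))
    # vectorised quadrant-corrected arctangent (same branches as linear_directional_mean)
    with np.errstate(divide="ignore"):
        a = np.abs(np.degrees(np.arctan(S / np.where(C == 0.0, np.nan, C))))
    ldm = np.where(C > 0, np.where(S >= 0, a, 360.0 - a), np.where(S >= 0, 180.0 - a, 180.0 + a))
    ldm = np.where(C == 0.0, np.where(S >= 0, 90.0, 270.0), ldm) % 360.0
    out = pd.DataFrame(
        {"date": agg.index.to_numpy(), "direction_deg": ldm, "speed_ms": agg["speed_ms"].to_numpy()}
    )
    return out[defined].reset_index(drop=True)


def _circular_diff_deg(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def toward_share(
    daily: pd.DataFrame,
    transect: Transect,
    half_angle_deg: float = 45.0,
    convention: str = "from",
) -> float:
    """Share of days whose wind blows toward the site.

    With the meteorological convention (``"from"``, the default) a record's
    direction is where the wind comes from; it blows toward the shore anchor
    when that origin lies on the open-water side, i.e. within
    ``half_angle_deg`` of the onshore normal.  With ``convention="to"`` the
    record already holds the travel direction and is compared against the
    offshore (normal + 180°) bearing.  The default ±45° sector spans the
    same 90° fan as the fetch rays.
    """
    if daily.empty:
        raise ValueError("no valid daily wind summaries")
    if convention == "from":
        target = transect.onshore_normal_deg
    elif convention == "to":
        target = (transect.onshore_normal_deg + 180.0) % 360.0
    else:
        raise ValueError(f"unknown wind convention: {convention!r}")
    hit = _circular_diff_deg(daily["direction_deg"].to_numpy(), target) <= half_angle_deg
    return float(hit.mean())


def exposure(f_km: float, w: float, h_ms: float, d_m: float, log_base: float | None = None) -> float:
    """Wind-exposure index E = log(1 + f*w*h/d^2); natural log by default."""
    if d_m <= 0:
        raise ValueError("site depth d must be positive")
    if f_km < 0 or w < 0 or h_ms < 0:
        raise ValueError("f, w and h must be non-negative")
    x = 1.0 + f_km * w * h_ms / d_m**2
    return math.log(x) if log_base is None else math.log(x, log_base)
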