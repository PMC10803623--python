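"""Macrophyte diversity, abundance and ecological-status indices.

The lake-level Ecological State Macrophyte Index (ESMI) is a multimetric of
a composition component — Pielou's evenness J' of community relative covers
— and an abundance component, the colonisation index Z = N / iso.2.5 (total
vegetated area over the lake area shallower than 2.5 m):

    ESMI = 1 - exp(-J' * (N / iso2.5) * exp(N / P))

with N and iso.2.5 in ha and P the lake area (ha).  Its transect-level
modification replaces N with the maximum colonisation depth on the transect
C_max_TR (m, normalised by 2.5 m) and P with the lake's maximum depth Z_max:

    ESMI_TR = 1 - exp(-J' * (C_max_TR / 2.5) * exp(C_max_TR / Z_max))

Both indices live in [0, 1); higher values indicate better status.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

GROUPS = ("charophyte", "hydrophyte", "helophyte")

__all__ = [
    "shannon_evenness",
    "esmi_lake",
    "esmi_transect",
    "transect_metrics",
]


def shannon_evenness(covers, monodominant_evenness: float = 0.0) -> tuple[float, float]:
    """Shannon diversity H' (natural log) and Pielou's evenness J' = H'/ln S.

    ``covers`` are non-negative (relative) abundances; zeros are dropped.
    For a monodominant stand (S = 1) ln S = 0 leaves J' undefined; the
    conservative convention J' = 0 is used, overridable via
    ``monodominant_evenness``.
    """
    c = np.asarray(covers, dtype=float)
    if (c < 0).any():
        raise ValueError("covers must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all covers are zero")
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    s = c.size
    j = h / math.log(s) if s >= 2 else float(monodominant_evenness)
    return h, j


def esmi_lake(j_prime: float, n_ha: float, iso25_ha: float, p_ha: float) -> float:
    """Lake-level ESMI from evenness J', vegetated area N, iso-2.5 area and lake area P (ha)."""
    if iso25_ha <= 0:
        raise ValueError("iso2.5 area must be positive")
    if p_ha <= 0:
        raise ValueError("lake area P must be positive")
    if n_ha < 0:
        raise ValueError("vegetated area N must be non-negative")
    esmi = 1.0 - math.exp(-j_prime * (n_ha / iso25_ha) * math.exp(n_ha / p_ha))
    return min(max(esmi, 0.0), math.nextafter(1.0, 0.0))


def esmi_transect(j_prime: float, c_max_tr: float, z_max: float) -> float:
    """Transect-level ESMI_TR from evenness J', colonisation depth C_max_TR and lake Z_max (m)."""
    if z_max <= 0:
        raise ValueError("Z_max must be positive")
    if not 0 <= c_max_tr <= z_max:
        raise ValueError(f"C_max_TR={c_max_tr} must lie in [0, Z_max={z_max}]")
    esmi = 1.0 - math.exp(-j_prime * (c_max_tr / 2.5) * math.exp(c_max_tr / z_max))
    return min(max(esmi, 0.0), math.nextafter(1.0, 0.0))


def transect_metrics(survey: pd.DataFrame, transect_id: str) -> dict[str, float]:
    """Syntaxon counts, group covers and diversity for one transect.

    ``survey`` is long-format with columns ``transect_id``, ``syntaxon_code``,
    ``group`` (charophyte / hydrophyte / helophyte; charophytes count as
    hydrophytes for S_Hy and %N_Hy) and ``rel_cover_pct``.

    Returns S_TOT, S_Hy, S_Ch, S_He, %N_Hy, %N_Ch, H' and J'.
    """
    rows = survey[(survey["transect_id"] == transect_id) & (survey["rel_cover_pct"] > 0)]
    if rows.empty:
        raise ValueError(f"transect {transect_id!r} not present in survey")
    bad = set(rows["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown growth-group labels: {sorted(bad)}")
    is_ch = rows["group"] == "charophyte"
    is_hy = rows["group"].isin(("charophyte", "hydrophyte"))
    is_he = rows["group"] == "helophyte"
    h, j = shannon_evenness(rows["rel_cover_pct"].to_numpy())
    return {
        "S_TOT": int(len(rows)),
        "S_Hy": int(is_hy.sum()),
        "S_Ch": int(is_ch.sum()),
        "S_He": int(is_he.sum()),
        "pct_N_Hy": float(rows.loc[is_hy, "rel_cover_pct"].sum()),
        "pct_N_Ch": float(rows.loc[is_ch, "rel_cover_pct"].sum()),
        "H_prime": h,
        "J_prime": j,
    }
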