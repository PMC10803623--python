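"""End-to-end orchestration: synthetic lakes -> slopes, exposure, indices, stats.

``run_pipeline`` produces one master row per transect (Sl_1m, Sl_Cmax,
Exp_1m, Exp_Cmax, all macrophyte metrics, ESMI_TR, slope class) and one per
lake (averaged AvgSl / AvgExp, ESMI), then the slope-class indicator /
SIMPER / correlation / group-comparison reports.  Everything is a pure
function of the configuration and its seed; rerunning with the same config
yields byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bathymetry, community, fetch, indices, synthetic
from .geometry import LakeGeometry, Transect, write_ascii_grid, write_lake_geojson

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration of a synthetic study run.

    Defaults emulate the monitoring scale the pipeline is built around:
    16 lowland lakes carrying 260 transects in total (8-27 each), six years
    of hourly wind per lake, slope classes split at 1.32° / 8.42° on the
    deep littoral slope, 999 label permutations for the indicator test.
    """

    n_lakes: int = 16
    total_transects: int = 260
    cell_size: float = 2.0
    radius_range_m: tuple[float, float] = (250.0, 600.0)
    max_depth_range_m: tuple[float, float] = (5.0, 25.0)
    #: per-lake littoral slope angles drawn log-uniformly over this range,
    #: spanning gentle (<1.32°) through steep (>8.42°) littoral classes
    slope_angle_range_deg: tuple[float, float] = (0.6, 16.0)
    wind_concentration: float = 1.0
    mean_speed_ms: float = 3.5
    wind_years: int = 6
    log_base: float | None = None  # None = natural log in the exposure index
    toward_half_angle_deg: float = 45.0
    wind_convention: str = "from"
    gentle_max_deg: float = bathymetry.GENTLE_MAX_DEG
    steep_min_deg: float = bathymetry.STEEP_MIN_DEG
    n_permutations: int = 999
    min_occurrences: int = 4  # syntaxa with more than three observations
    trophic_effect: float = -1.5
    seed: int = 0
    outdir: str | None = None
    write_rasters: bool = False

    def __post_init__(self) -> None:
        if self.gentle_max_deg >= self.steep_min_deg:
            raise ValueError("slope-class thresholds must be ordered")
        if not self.n_lakes * 8 <= self.total_transects <= self.n_lakes * 27:
            raise ValueError("total_transects must be attainable with 8-27 transects per lake")


@dataclass
class PipelineResult:
    transects: pd.DataFrame
    lakes: pd.DataFrame
    indval: pd.DataFrame | None
    simper: dict | None
    correlations: pd.DataFrame
    group_tests: dict
    manifest: dict


_SHAPES = ("circle", "ellipse", "irregular-harmonic")
_PROFILES = ("conic", "planar-shelf", "two-slope")


def _transect_counts(n_lakes: int, total: int, rng: np.random.Generator) -> list[int]:
    """Per-lake transect counts in [8, 27] summing exactly to ``total``."""
    counts = rng.integers(8, 28, size=n_lakes)
    diff = total - int(counts.sum())
    while diff != 0:
        i = int(rng.integers(n_lakes))
        step = 1 if diff > 0 else -1
        if 8 <= counts[i] + step <= 27:
            counts[i] += step
            diff -= step
    return [int(c) for c in counts]


def _lake_level_evenness(obs: pd.DataFrame) -> float:
    """Pielou's J' of the lake-wide community: mean relative cover per syntaxon."""
    pooled = obs.groupby("syntaxon_code")["rel_cover_pct"].mean()
    _, j = indices.shannon_evenness(pooled.to_numpy())
    return j


def run_pipeline(config: RunConfig) -> PipelineResult:
    rng = np.random.default_rng(config.seed)
    counts = _transect_counts(config.n_lakes, config.total_transects, rng)
    lake_seeds = rng.integers(2**31, size=config.n_lakes)
    wind_seeds = rng.integers(2**31, size=config.n_lakes)
    comm_seeds = rng.integers(2**31, size=config.n_lakes)

    transect_rows: list[dict] = []
    lake_rows: list[dict] = []
    all_obs: list[pd.DataFrame] = []
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for li in range(config.n_lakes):
        lake_id = f"L{li + 1:02d}"
        radius = float(rng.uniform(*config.radius_range_m))
        lo_a, hi_a = config.slope_angle_range_deg
        slope_angle = float(np.exp(rng.uniform(np.log(lo_a), np.log(hi_a))))
        shore_slope = float(np.tan(np.radians(slope_angle)))
        profile = _PROFILES[li % len(_PROFILES)]
        max_depth = float(rng.uniform(*config.max_depth_range_m))
        if profile != "conic":
            # keep the basin's colonisable depth consistent with its shore slope
            max_depth = min(max_depth, shore_slope * radius * 0.9)
            max_depth = max(max_depth, 2.5)
        lake_spec = synthetic.SyntheticLakeSpec(
            lake_id=lake_id,
            shape=_SHAPES[li % len(_SHAPES)],
            radius_m=radius,
            axes_m=(radius * 1.25, radius * 0.8),
            max_depth_m=max_depth,
            profile=profile,
            shore_slope=None if profile == "conic" else shore_slope,
            n_transects=counts[li],
            cell_size=config.cell_size,
            seed=int(lake_seeds[li]),
        )
        geom, truth_grid, transects = synthetic.make_lake(lake_spec)
        grid = bathymetry.interpolate_depth(geom, cell_size=config.cell_size)
        slope = bathymetry.slope_raster(grid)

        c_max_lake = max(tr.c_max_tr for tr in transects)
        iso_cmax = bathymetry.cmax_isobath_depth(geom, c_max_lake)

        wind_spec = synthetic.SyntheticWindSpec(
            mean_direction_deg=float(rng.uniform(0.0, 360.0)),
            concentration=config.wind_concentration,
            mean_speed_ms=config.mean_speed_ms,
            years=config.wind_years,
            station_id=f"S{li + 1:02d}",
            seed=int(wind_seeds[li]),
        )
        wind = synthetic.make_wind(wind_spec)
        daily = fetch.daily_wind_summary(wind)
        h_ms = float(daily["speed_ms"].mean())

        comm_spec = synthetic.SyntheticCommunitySpec(
            trophic_effect=config.trophic_effect, seed=int(comm_seeds[li])
        )
        obs, tr_table, lake_attrs = synthetic.make_survey(geom, transects, comm_spec)
        all_obs.append(obs)
        tr_table = tr_table.set_index("transect_id")

        for tr in transects:
            sl1 = bathymetry.zonal_slope(
                bathymetry.transect_zone(tr, geom, grid, 1.0), slope
            )
            slc = bathymetry.zonal_slope(
                bathymetry.transect_zone(tr, geom, grid, iso_cmax), slope
            )
            rays = fetch.cast_fetch_rays(tr, geom)
            f_km = fetch.effective_fetch(rays)
            w = fetch.toward_share(
                daily, tr, half_angle_deg=config.toward_half_angle_deg, convention=config.wind_convention
            )
            exp1 = fetch.exposure(f_km, w, h_ms, 1.0, log_base=config.log_base)
            expc = fetch.exposure(f_km, w, h_ms, c_max_lake, log_base=config.log_base)
            metrics = indices.transect_metrics(obs, tr.transect_id)
            esmi_tr = indices.esmi_transect(metrics["J_prime"], tr.c_max_tr, geom.z_max)
            row = {
                "lake_id": lake_id,
                "transect_id": tr.transect_id,
                "sl_1m_deg": sl1,
                "sl_cmax_deg": slc,
                "sl_1m_pct": bathymetry.deg_to_pct(sl1),
                "sl_cmax_pct": bathymetry.deg_to_pct(slc),
                "slope_class": bathymetry.classify_slope(slc, config.gentle_max_deg, config.steep_min_deg),
                "fetch_km": f_km,
                "w": w,
                "h_ms": h_ms,
                "exp_1m": exp1,
                "exp_cmax": expc,
                "c_max_tr": tr.c_max_tr,
                "total_cover_pct": float(tr_table.loc[tr.transect_id, "total_cover_pct"]),
                "esmi_tr": esmi_tr,
                **metrics,
            }
            transect_rows.append(row)

        lake_tr = pd.DataFrame([r for r in transect_rows if r["lake_id"] == lake_id])
        iso25 = bathymetry.area_shallower_than(grid, 2.5)
        j_lake = _lake_level_evenness(obs)
        esmi = indices.esmi_lake(
            j_lake, lake_attrs["total_vegetated_area_N_ha"], iso25, lake_attrs["lake_area_P_ha"]
        )
        lake_rows.append(
            {
                "lake_id": lake_id,
                "n_transects": len(transects),
                "lake_area_P_ha": lake_attrs["lake_area_P_ha"],
                "z_max": geom.z_max,
                "c_max": c_max_lake,
                "tp_mgL": lake_attrs["tp_mgL"],
                "iso25_ha": iso25,
                "N_ha": lake_attrs["total_vegetated_area_N_ha"],
                "J_prime": j_lake,
                "esmi": esmi,
                "avg_sl_1m_deg": float(lake_tr["sl_1m_deg"].mean()),
                "avg_sl_cmax_deg": float(lake_tr["sl_cmax_deg"].mean()),
                "avg_exp_1m": float(lake_tr["exp_1m"].mean()),
                "avg_exp_cmax": float(lake_tr["exp_cmax"].mean()),
            }
        )
        if outdir:
            write_lake_geojson(geom, transects, outdir / f"{lake_id}.geojson")
            if config.write_rasters:
                write_ascii_grid(grid, outdir / f"{lake_id}_depth.asc")

    master = pd.DataFrame(transect_rows)
    lakes = pd.DataFrame(lake_rows)
    obs_all = pd.concat(all_obs, ignore_index=True)

    # community matrix (transect x syntaxon), syntaxa with > 3 observations
    mat = obs_all.pivot_table(
        index="transect_id", columns="syntaxon_code", values="rel_cover_pct", aggfunc="sum", fill_value=0.0
    ).reindex(master["transect_id"]).fillna(0.0)
    keep = (mat > 0).sum(axis=0) >= config.min_occurrences
    mat = mat.loc[:, keep]
    groups = master.set_index("transect_id").loc[mat.index, "slope_class"].to_numpy()

    iv_table = simper_out = None
    if len(set(groups)) >= 2 and not mat.empty:
        stat_seed = int(rng.integers(2**31))
        iv_table = community.indval_table(mat, groups, n_perm=config.n_permutations, seed=stat_seed)
        simper_out = community.simper(mat, groups)

    index_cols = ["total_cover_pct", "S_TOT", "S_He", "S_Hy", "S_Ch", "pct_N_Hy", "pct_N_Ch", "H_prime", "esmi_tr"]
    env_cols = ["sl_1m_deg", "sl_cmax_deg", "exp_1m", "exp_cmax"]
    correlations = community.correlation_table(master[index_cols], master[env_cols])
    if master["slope_class"].nunique() >= 2:
        group_tests = {
            m: community.group_comparison(master[m], master["slope_class"])
            for m in ("total_cover_pct", "esmi_tr")
        }
    else:
        logger.warning("all transects share one slope class; group comparisons skipped")
        group_tests = {}

    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "n_transect_rows": int(len(master)),
        "n_lake_rows": int(len(lakes)),
    }
    if outdir:
        master.to_csv(outdir / "master_transects.csv", index=False)
        lakes.to_csv(outdir / "lakes.csv", index=False)
        correlations.to_csv(outdir / "correlations.csv", index=False)
        obs_all.to_csv(outdir / "survey_observations.csv", index=False)
        if iv_table is not None:
            iv_table.to_csv(outdir / "indval.csv", index=False)
        if simper_out is not None:
            for (a, b), df in simper_out.items():
                df.to_csv(outdir / f"simper_{a}_vs_{b}.csv", index=False)
        manifest["output_hashes"] = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.glob("*.csv"))
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        transects=master,
        lakes=lakes,
        indval=iv_table,
        simper=simper_out,
        correlations=correlations,
        group_tests=group_tests,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# input validation for real (non-synthetic) runs

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    wind_csv: str | None = None,
    survey_csv: str | None = None,
    lake_geojson: str | None = None,
    cover_tolerance: float = 0.5,
) -> ValidationReport:
    """Schema and sanity checks on the three external inputs.

    Flags: per-transect relative covers not summing to 100, negative speeds,
    wind gaps over 30 days, isobaths deeper than the lake's Z_max, and
    malformed geometry.
    """
    rep = ValidationReport()
    if wind_csv:
        try:
            wind = pd.read_csv(wind_csv, parse_dates=["timestamp"])
            for col in ("direction_deg", "speed_ms"):
                if col not in wind.columns:
                    rep.errors.append(f"wind: missing column {col!r}")
            if "speed_ms" in wind.columns and (wind["speed_ms"] < 0).any():
                rep.errors.append("wind: negative speeds present")
            if "direction_deg" in wind.columns and not wind["direction_deg"].between(0, 360).all():
                rep.errors.append("wind: directions outside [0, 360]")
            gaps = wind["timestamp"].sort_values().diff()
            if (gaps > pd.Timedelta(days=30)).any():
                rep.warnings.append("wind: timestamp gap exceeding 30 days")
        except Exception as exc:  # malformed file
            rep.errors.append(f"wind: {exc}")
    if survey_csv:
        try:
            surv = pd.read_csv(survey_csv)
            needed = {"lake_id", "transect_id", "syntaxon_code", "group", "rel_cover_pct"}
            missing = needed - set(surv.columns)
            if missing:
                rep.errors.append(f"survey: missing columns {sorted(missing)}")
            else:
                sums = surv.groupby("transect_id")["rel_cover_pct"].sum()
                bad = sums[(sums - 100.0).abs() > cover_tolerance]
                for tid, s in bad.items():
                    rep.errors.append(f"survey: covers on transect {tid} sum to {s:.1f}, not 100")
        except Exception as exc:
            rep.errors.append(f"survey: {exc}")
    if lake_geojson:
        try:
            from .geometry import read_lake_geojson

            geom, _ = read_lake_geojson(lake_geojson)
            if geom.z_max is not None:
                for depth, _line in geom.isobaths:
                    if depth > geom.z_max:
                        rep.errors.append(f"geometry: isobath {depth} m deeper than z_max {geom.z_max} m")
        except Exception as exc:
            rep.errors.append(f"geometry: {exc}")
    return rep
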