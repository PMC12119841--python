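"""Bioregion-level predictors and the multi-predictor driver model.

Three predictors are computed from rasters and the phylogeny:

* **climate-change velocity** — per cell, the temporal rate of climate
  change divided by the local spatial climate gradient (km/yr): flat
  landscapes must track change by moving far, steep ones barely at all;
* **terrain roughness** — per cell, max minus min elevation over the 3x3
  neighbourhood, a topographic-complexity proxy;
* **NRI** (net relatedness index) — per cell, the negated z-score of the
  observed mean pairwise patristic distance among co-occurring species
  against a null that shuffles tip identities within the regional species
  pool (positive = phylogenetic clustering; a competition proxy).

These are averaged per bioregion, merged with supplied covariates
(time-integrated area, productivity, temperature) and a mean-rate
response, standardised, and fed to the spatial-error model with an
AIC-selected neighbourhood cutoff.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .grid import AssemblageGrid
from .sar import SARFit, fit_sar_error, select_cutoff
from .trees import Phylogeny

__all__ = [
    "climate_velocity",
    "roughness",
    "region_mean",
    "nri",
    "assemble_bioregion_table",
    "run_driver_model",
]

log = logging.getLogger(__name__)

#: kilometres per degree of latitude (spherical Earth mean radius)
KM_PER_DEGREE = 111.32


def _pad_odd(a: np.ndarray) -> np.ndarray:
    """1-cell border pad by odd reflection (extends linear ramps exactly)."""
    return np.pad(a, 1, mode="reflect", reflect_type="odd")


def spatial_gradient(surface: np.ndarray, cellsize_km: float) -> np.ndarray:
    """Slope magnitude of a raster (units per km), 3x3 average-maximum.

    Horn's eight-neighbour stencil: the x/y first derivatives are
    centre-weighted averages of the three finite differences across the
    window; the gradient is their Euclidean norm.  Borders use odd
    reflection so a linear ramp has the exact same slope everywhere.
    """
    if surface.ndim != 2 or min(surface.shape) < 3:
        raise ValueError("raster must be at least 3x3")
    z = _pad_odd(np.asarray(surface, float))
    dzdx = (
        (z[:-2, 2:] + 2.0 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2.0 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8.0 * cellsize_km)
    dzdy = (
        (z[2:, :-2] + 2.0 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2.0 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8.0 * cellsize_km)
    return np.sqrt(dzdx**2 + dzdy**2)


def climate_velocity(
    current: np.ndarray,
    past: np.ndarray,
    dt_years: float,
    cellsize_km: float,
    combine: str = "mean",
) -> np.ndarray:
    """Climate-change velocity (km/yr) of one or more variables.

    ``current`` / ``past`` are 2-D rasters for a single variable, or 3-D
    stacks (variable, row, col).  Per cell and variable,

        velocity = |current - past| / dt_years   (units/yr)
                   -----------------------------
                   spatial gradient of current    (units/km)

    with the spatial gradient from :func:`spatial_gradient` on the
    current-conditions surface.  Cells with zero spatial gradient are
    undefined (NaN, counted in the log) rather than infinite.  Variables
    are combined by ``mean`` (default) or ``median``.
    """
    cur = np.asarray(current, float)
    pst = np.asarray(past, float)
    if cur.shape != pst.shape:
        raise ValueError("current and past rasters must share the grid")
    if dt_years <= 0:
        raise ValueError("dt_years must be positive")
    if cur.ndim == 2:
        cur = cur[None]
        pst = pst[None]
    vels = np.empty_like(cur)
    for v in range(cur.shape[0]):
        temporal = np.abs(cur[v] - pst[v]) / dt_years
        spatial = spatial_gradient(cur[v], cellsize_km)
        with np.errstate(divide="ignore", invalid="ignore"):
            vel = np.where(spatial > 0, temporal / spatial, np.nan)
        n_undef = int(np.isnan(vel).sum())
        if n_undef:
            log.info("variable %d: %d cells with zero gradient flagged "
                     "undefined", v, n_undef)
        vels[v] = vel
    if combine == "mean":
        return np.nanmean(vels, axis=0) if vels.shape[0] > 1 else vels[0]
    if combine == "median":
        return np.nanmedian(vels, axis=0) if vels.shape[0] > 1 else vels[0]
    raise ValueError(f"unknown combine rule {combine!r}")


def velocity_over_horizons(
    stack: np.ndarray,
    dt_years: np.ndarray | list[float],
    cellsize_km: float,
    combine: str = "mean",
) -> np.ndarray:
    """Mean velocity of each past horizon against the present.

    ``stack`` has shape (n_variables, n_horizons, rows, cols) with horizon
    0 = present; ``dt_years[h-1]`` is the age of horizon h.  Each past
    horizon is compared with the present and the per-horizon velocities
    are averaged.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 4:
        raise ValueError("stack must be (variables, horizons, rows, cols)")
    n_h = stack.shape[1]
    if n_h < 2:
        raise ValueError("need at least one past horizon")
    dts = np.asarray(dt_years, float)
    if len(dts) != n_h - 1:
        raise ValueError("need one dt per past horizon")
    per_h = [
        climate_velocity(stack[:, 0], stack[:, h], dts[h - 1],
                         cellsize_km, combine=combine)
        for h in range(1, n_h)
    ]
    return np.nanmean(per_h, axis=0)


def roughness(elevation: np.ndarray) -> np.ndarray:
    """Per-cell max - min elevation over the 3x3 neighbourhood.

    Border cells use their available neighbours (edge replication).
    """
    from scipy import ndimage

    z = np.asarray(elevation, float)
    if z.ndim != 2 or min(z.shape) < 3:
        raise ValueError("raster must be at least 3x3")
    mx = ndimage.maximum_filter(z, size=3, mode="nearest")
    mn = ndimage.minimum_filter(z, size=3, mode="nearest")
    return mx - mn


def region_mean(
    raster: np.ndarray, bioregions: np.ndarray
) -> pd.Series:
    """NaN-aware mean of a raster within each bioregion."""
    r = np.asarray(raster, float).ravel()
    b = np.asarray(bioregions).ravel()
    if r.shape != b.shape:
        raise ValueError("raster and bioregion shapes differ")
    out = {}
    for j in np.unique(b):
        vals = r[b == j]
        if len(vals) == 0 or np.all(np.isnan(vals)):
            raise ValueError(f"region {j} has no raster cells with values")
        out[int(j)] = float(np.nanmean(vals))
    return pd.Series(out).rename_axis("region")


def nri(
    agrid: AssemblageGrid,
    tree: Phylogeny,
    bioregions: np.ndarray,
    n_rand: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Net relatedness index per bioregion (cell-level, then averaged).

    Per cell with richness >= 2, the observed mean pairwise patristic
    distance (MPD) is compared with ``n_rand`` null draws that shuffle tip
    identities among the regional species pool — the presence-absence
    structure (richness and range-size frequencies) is untouched, only
    which tip each pool member maps to changes:

        NRI = -(MPD_obs - mean MPD_null) / sd MPD_null.

    Cells whose null has zero variance (degenerate pools) are flagged
    undefined.  Returns (per-region mean NRI over member cells, per-cell
    table).
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    rng = np.random.default_rng(seed)
    missing = [s for s in agrid.species if s not in tree.tip_labels]
    if missing:
        raise KeyError(f"gridded species not on tree: {missing[:10]}")
    D = tree.patristic_matrix()
    tip_of = {lab: i for i, lab in enumerate(tree.tip_labels)}
    sp_tip = np.array([tip_of[s] for s in agrid.species])
    region_of_cell = np.asarray(bioregions).ravel()[agrid.cell_ids]

    rows = []
    region_cells: dict[int, list[int]] = {}
    for j in np.unique(region_of_cell):
        region_cells[int(j)] = np.flatnonzero(region_of_cell == j).tolist()

    n_skipped = 0
    for j, cells in region_cells.items():
        pool = np.flatnonzero(agrid.pam[cells].any(axis=0))
        pool_tips = sp_tip[pool]
        pos_in_pool = -np.ones(len(agrid.species), dtype=int)
        pos_in_pool[pool] = np.arange(len(pool))
        # member indices per cell, expressed in pool positions
        cell_members = []
        for c in cells:
            m = np.flatnonzero(agrid.pam[c])
            if len(m) < 2:
                n_skipped += 1
                continue
            cell_members.append((c, pos_in_pool[m]))
        if not cell_members:
            continue
        obs = {c: _mpd(D, pool_tips[m]) for c, m in cell_members}
        null_mpd = {c: np.empty(n_rand) for c, _ in cell_members}
        for r in range(n_rand):
            perm = rng.permutation(len(pool))
            tips_r = pool_tips[perm]
            for c, m in cell_members:
                null_mpd[c][r] = _mpd(D, tips_r[m])
        for c, m in cell_members:
            mu = null_mpd[c].mean()
            sd = null_mpd[c].std(ddof=1)
            if sd == 0:
                rows.append({"cell_id": agrid.cell_ids[c], "region": j,
                             "richness": len(m), "mpd_obs": obs[c],
                             "nri": np.nan})
                continue
            rows.append({
                "cell_id": agrid.cell_ids[c],
                "region": j,
                "richness": len(m),
                "mpd_obs": obs[c],
                "nri": -(obs[c] - mu) / sd,
            })
    if n_skipped:
        log.info("skipped %d cells with richness < 2", n_skipped)
    cell_table = pd.DataFrame(rows)
    if cell_table.empty:
        raise ValueError("no cells with richness >= 2")
    per_region = (
        cell_table.dropna(subset=["nri"])
        .groupby("region")["nri"].mean()
    )
    return per_region, cell_table


def _mpd(D: np.ndarray, tips: np.ndarray) -> float:
    sub = D[np.ix_(tips, tips)]
    k = len(tips)
    return float(sub.sum() / (k * (k - 1)))


DRIVER_COLUMNS = [
    "time_integrated_area",
    "productivity",
    "temperature",
    "roughness",
    "nri",
    "climatic_velocity",
]


def assemble_bioregion_table(
    summaries: pd.DataFrame,
    bioregions: np.ndarray,
    agrid: AssemblageGrid,
    velocity_raster: np.ndarray,
    roughness_raster: np.ndarray,
    nri_by_region: pd.Series,
    supplied: pd.DataFrame,
) -> pd.DataFrame:
    """Merge response and all six predictors into one per-region table.

    The response ``mean_rate`` is the mean over member cells of the
    cell-level mean tip rate (cells weight the response by occupancy).
    Raw predictor columns are kept alongside z-scored ``*_std`` copies.
    Constant predictors raise; pairwise collinearity above |r| = 0.95
    triggers a hard warning.
    """
    region_of_cell = np.asarray(bioregions).ravel()[
        summaries.index.to_numpy()
    ]
    resp = (
        summaries.assign(region=region_of_cell)
        .groupby("region")["mean_rate"].mean()
    )
    tab = pd.DataFrame({"mean_rate": resp})
    tab["climatic_velocity"] = region_mean(velocity_raster, bioregions)
    tab["roughness"] = region_mean(roughness_raster, bioregions)
    tab["nri"] = nri_by_region
    for col in ("time_integrated_area", "productivity", "temperature"):
        tab[col] = supplied[col]
    tab["centroid_lat"] = supplied["centroid_lat"]
    tab["centroid_lon"] = supplied["centroid_lon"]
    tab = tab.dropna(subset=["mean_rate", *DRIVER_COLUMNS])
    for col in DRIVER_COLUMNS:
        sd = tab[col].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"constant predictor {col!r} — dropped")
        tab[col + "_std"] = (tab[col] - tab[col].mean()) / sd
    corr = tab[[c + "_std" for c in DRIVER_COLUMNS]].corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    worst = np.abs(corr[iu]).max()
    if worst > 0.95:
        warnings.warn(
            f"collinear predictors (max |r| = {worst:.3f} > 0.95)",
            stacklevel=2,
        )
    return tab


def run_driver_model(
    table: pd.DataFrame,
    cutoffs: list[float] | None = None,
    min_regions: int = 10,
) -> tuple[SARFit, pd.DataFrame, float]:
    """Six-predictor spatial-error model over bioregions.

    Predictors enter standardised (comparable effect sizes); the
    neighbourhood cutoff is chosen by the lowest AIC over ``cutoffs``
    (default 10..100 degrees in steps of 10).  Returns (fit, AIC table,
    selected cutoff).
    """
    if len(table) < min_regions:
        raise ValueError(
            f"only {len(table)} regions; need >= {min_regions} to fit"
        )
    if cutoffs is None:
        cutoffs = [float(c) for c in range(10, 101, 10)]
    coords = table[["centroid_lat", "centroid_lon"]].to_numpy()
    X = table[[c + "_std" for c in DRIVER_COLUMNS]].to_numpy()
    y = table["mean_rate"].to_numpy()
    best, aic_table, fit = select_cutoff(
        X, y, coords, cutoffs, model="error", names=DRIVER_COLUMNS
    )
    return fit, aic_table, best


def effect_size_table(fit: SARFit) -> pd.DataFrame:
    """Per-predictor effect sizes with 95% CIs and significance flags."""
    ci = 1.959963984540054 * fit.bse
    out = pd.DataFrame(
        {
            "estimate": fit.params,
            "ci_low": fit.params - ci,
            "ci_high": fit.params + ci,
            "p_value": fit.pvalues,
            "significant_05": fit.pvalues < 0.05,
        }
    )
    return out.drop(index="intercept", errors="ignore")
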