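"""Synthetic-world generation: trees, traits, ranges, rasters, bioregions.

Everything downstream (assemblage grids, latitudinal regressions, the
state-dependent speciation test and the driver models) is exercised on
worlds built here, so each generator is deterministic under a fixed seed
and its statistical structure is documented:

* birth-death / BiSSE forward simulation conditioned on tip count,
* clade-structured ultrametric posteriors (fast and slow clades),
* spreading-dye contiguous ranges with a lognormal range-size
  distribution and optional latitudinal anchoring,
* smooth climate stacks with closed-form gradients/trends,
* Gaussian-filtered random elevation fields,
* Voronoi-like contiguous bioregion partitions with attached predictor
  tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .trees import Phylogeny

__all__ = [
    "GridSpec",
    "WorldConfig",
    "SyntheticWorld",
    "simulate_bd_tree",
    "simulate_bisse_tree",
    "simulate_clade_tree",
    "simulate_ranges",
    "simulate_climate_stack",
    "simulate_elevation",
    "partition_bioregions",
    "build_world",
]


# ----------------------------------------------------------------- grid ----
@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid. Rows run north to south, columns west to east."""

    lat_min: float = -60.0
    lat_max: float = 60.0
    lon_min: float = -30.0
    lon_max: float = 30.0
    resolution: float = 2.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("degenerate grid extent")

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) centroid arrays of shape (n_rows, n_cols)."""
        lat = self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution
        lon = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution
        return np.meshgrid(lat, lon, indexing="ij")

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rowcol(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.divmod(np.asarray(cell_id), self.n_cols)


# ---------------------------------------------------------------- trees ----
def simulate_bd_tree(
    birth: float,
    death: float,
    n_tips: int,
    seed: int | np.random.Generator,
    label_prefix: str = "t",
    max_retries: int = 1000,
) -> Phylogeny:
    """Forward birth-death simulation conditioned on the extant tip count.

    Starts from a crown pair, runs a Gillespie simulation, and stops at the
    moment the extant count first reaches ``n_tips`` plus a uniform fraction
    of the following inter-event waiting time (so terminal branches are
    strictly positive).  Replicates that go extinct are retried.
    """
    tree, _ = simulate_bisse_tree(
        (birth, birth), 0.0, n_tips, seed,
        death=(death, death), label_prefix=label_prefix,
        max_retries=max_retries,
    )
    return tree


def simulate_bisse_tree(
    birth: tuple[float, float],
    transition: float,
    n_tips: int,
    seed: int | np.random.Generator,
    death: tuple[float, float] = (0.0, 0.0),
    root_state: int = 0,
    label_prefix: str = "t",
    max_retries: int = 1000,
) -> tuple[Phylogeny, dict[str, int]]:
    """Joint forward simulation of a binary character and the tree.

    Lineages in state k speciate at ``birth[k]``, die at ``death[k]`` and
    flip state at rate ``transition`` (symmetric).  Conditioning on the
    extant tip count is as in :func:`simulate_bd_tree`.

    Returns the tree and a species -> state mapping.
    """
    rng = np.random.default_rng(seed)
    lam = np.asarray(birth, float)
    mu = np.asarray(death, float)
    if np.any(lam <= 0) or transition < 0 or np.any(mu < 0):
        raise ValueError("need birth rates > 0, death and transition >= 0")
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")

    for _ in range(max_retries):
        parent_of = [-1, 0, 0]
        birth_time = [0.0, 0.0, 0.0]
        state_of = [root_state, root_state, root_state]
        alive = [1, 2]
        t = 0.0
        failed = False
        while True:
            st = np.array([state_of[v] for v in alive])
            rates = lam[st] + mu[st] + transition
            total = rates.sum()
            dt = rng.exponential(1.0 / total)
            if len(alive) == n_tips:
                # stop inside this waiting interval
                t += rng.uniform() * dt
                break
            t += dt
            i = rng.choice(len(alive), p=rates / total)
            v = alive[i]
            u = rng.uniform() * rates[i]
            if u < lam[st[i]]:
                for _k in range(2):
                    parent_of.append(v)
                    birth_time.append(t)
                    state_of.append(state_of[v])
                alive[i] = len(parent_of) - 2
                alive.append(len(parent_of) - 1)
            elif u < lam[st[i]] + mu[st[i]]:
                alive.pop(i)
                if len(alive) < 2:
                    failed = True
                    break
            else:
                state_of[v] = 1 - state_of[v]
        if failed:
            continue
        return _reconstruct_extant_tree(
            parent_of, birth_time, state_of, alive, t, label_prefix
        )
    raise RuntimeError(
        f"birth-death simulation failed after {max_retries} retries "
        "(non-viable parameters?)"
    )


def _reconstruct_extant_tree(
    parent_of: list[int],
    birth_time: list[float],
    state_of: list[int],
    alive: list[int],
    t_now: float,
    label_prefix: str,
) -> tuple[Phylogeny, dict[str, int]]:
    """Prune extinct lineages and contract the resulting unifurcations.

    Event records form a tree in which every split created two child
    records; a record's lifespan runs from its birth to the birth of its
    children (if it split) or to the present.  The reconstructed tree of
    the extant sample keeps only records with living descendants; runs of
    single-kept-child records collapse into one branch spanning the run.
    """
    n = len(parent_of)
    keep = [False] * n
    for v in alive:
        while v != -1 and not keep[v]:
            keep[v] = True
            v = parent_of[v]
    kept_children: list[list[int]] = [[] for _ in range(n)]
    for v in range(n):
        if keep[v] and parent_of[v] != -1:
            kept_children[parent_of[v]].append(v)
    alive_set = set(alive)

    def descend(v: int) -> int:
        # skip records with exactly one surviving child lineage
        while len(kept_children[v]) == 1:
            v = kept_children[v][0]
        return v

    root = descend(0)
    parent_out: list[int] = []
    elen_out: list[float] = []
    tip_nodes: list[int] = []
    tip_states: list[int] = []
    stack: list[tuple[int, float, int]] = [(root, np.nan, -1)]
    while stack:
        v, start, parent_idx = stack.pop()
        idx = len(parent_out)
        parent_out.append(parent_idx)
        if v in alive_set:  # extant tip: branch runs to the present
            elen_out.append(t_now - start)
            tip_nodes.append(idx)
            tip_states.append(state_of[v])
        else:  # split: branch ends when the children were born
            split_time = birth_time[kept_children[v][0]]
            elen_out.append(0.0 if parent_idx == -1 else split_time - start)
            for c in reversed(kept_children[v]):
                stack.append((descend(c), split_time, idx))
    width = max(4, len(str(len(alive))))
    labels = [f"{label_prefix}{i:0{width}d}" for i in range(len(tip_nodes))]
    tree = Phylogeny(
        np.asarray(parent_out, dtype=np.int64),
        np.asarray(elen_out, dtype=float),
        labels,
        np.asarray(tip_nodes, dtype=np.int64),
    )
    traits = {lab: int(s) for lab, s in zip(labels, tip_states)}
    return tree, traits


def simulate_clade_tree(
    clade_sizes: list[int],
    clade_rates: list[float],
    seed: int | np.random.Generator,
    stem_buffer: float = 1.0,
    label_prefixes: list[str] | None = None,
) -> Phylogeny:
    """Ultrametric tree of independently simulated pure-birth clades.

    Each clade j is a Yule tree at rate ``clade_rates[j]`` with
    ``clade_sizes[j]`` tips; clades are attached to a root polytomy with
    stem lengths chosen so every tip sits at the same depth.  Used to plant
    rate heterogeneity (fast vs slow clades) with known structure.
    """
    rng = np.random.default_rng(seed)
    if len(clade_sizes) != len(clade_rates) or len(clade_sizes) < 2:
        raise ValueError("need >= 2 clades with matching sizes and rates")
    if label_prefixes is None:
        label_prefixes = [f"c{j}_" for j in range(len(clade_sizes))]
    clades = [
        simulate_bd_tree(r, 0.0, n, rng, label_prefix=p)
        for n, r, p in zip(clade_sizes, clade_rates, label_prefixes)
    ]
    heights = [c.node_depths()[c.tip_nodes].max() for c in clades]
    H = max(heights) + stem_buffer
    # merge into one node-array tree: root 0, then each clade shifted
    parents = [np.array([-1], dtype=np.int64)]
    elens = [np.array([0.0])]
    labels: list[str] = []
    tip_nodes: list[int] = []
    offset = 1
    for c, h in zip(clades, heights):
        p = c.parent.copy() + offset
        p[0] = 0  # clade root hangs off the global root
        e = c.edge_length.copy()
        e[0] = H - h  # stem makes the tree ultrametric
        parents.append(p)
        elens.append(e)
        labels.extend(c.tip_labels)
        tip_nodes.extend((c.tip_nodes + offset).tolist())
        offset += c.n_nodes
    return Phylogeny(
        np.concatenate(parents),
        np.concatenate(elens),
        labels,
        np.asarray(tip_nodes),
    )


# --------------------------------------------------------------- ranges ----
def simulate_ranges(
    species: list[str],
    grid: GridSpec,
    seed: int | np.random.Generator,
    size_mean_log: float = 2.5,
    size_sd_log: float = 1.0,
    anchor_lat: dict[str, float] | None = None,
    anchor_cell: dict[str, int] | None = None,
    sizes: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Spreading-dye contiguous ranges on the grid.

    Range size (in cells) is lognormal (right-skewed: many small-ranged
    species, few widespread ones) unless given explicitly.  Each range
    grows from a seed cell by repeatedly occupying a uniformly chosen
    unoccupied rook neighbour of the current range.  ``anchor_lat`` pins a
    species' seed cell to the grid row nearest that latitude (used to plant
    latitudinally structured clades); ``anchor_cell`` pins the seed cell
    itself (used to plant region-structured clades) and takes precedence.

    Returns species -> sorted array of occupied cell ids.
    """
    rng = np.random.default_rng(seed)
    nr, nc = grid.n_rows, grid.n_cols
    latc = grid.cell_centroids()[0][:, 0]
    ranges: dict[str, np.ndarray] = {}
    for sp in species:
        if sizes is not None:
            size = int(sizes[sp])
        else:
            size = int(np.clip(
                np.round(rng.lognormal(size_mean_log, size_sd_log)),
                1, nr * nc,
            ))
        if size > nr * nc:
            raise ValueError(
                f"requested range size {size} exceeds grid size {nr * nc}"
            )
        if anchor_cell is not None and sp in anchor_cell:
            row, col = (int(x) for x in grid.rowcol(anchor_cell[sp]))
        elif anchor_lat is not None and sp in anchor_lat:
            row = int(np.argmin(np.abs(latc - anchor_lat[sp])))
            col = int(rng.integers(nc))
        else:
            row = int(rng.integers(nr))
            col = int(rng.integers(nc))
        occupied = {(row, col)}
        frontier = [(row, col)]
        while len(occupied) < size:
            # uniformly pick a cell with a free neighbour, then a neighbour
            i = int(rng.integers(len(frontier)))
            r, c = frontier[i]
            nbrs = [
                (r + dr, c + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= r + dr < nr and 0 <= c + dc < nc
                and (r + dr, c + dc) not in occupied
            ]
            if not nbrs:
                frontier.pop(i)
                if not frontier:  # boxed in: restart frontier from range
                    frontier = [
                        cell for cell in occupied
                        if any(
                            0 <= cell[0] + dr < nr and 0 <= cell[1] + dc < nc
                            and (cell[0] + dr, cell[1] + dc) not in occupied
                            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                        )
                    ]
                    if not frontier:
                        break
                continue
            cell = nbrs[int(rng.integers(len(nbrs)))]
            occupied.add(cell)
            frontier.append(cell)
        ranges[sp] = np.sort(
            np.array([grid.cell_id(r, c) for r, c in occupied])
        )
    return ranges


# -------------------------------------------------------------- rasters ----
def simulate_climate_stack(
    grid: GridSpec,
    n_horizons: int,
    seed: int | np.random.Generator,
    n_variables: int = 1,
    gradient_per_deg: float = 0.5,
    trend_per_horizon: float = 1.0,
    noise_sd: float = 0.0,
    noise_smooth_cells: float = 3.0,
) -> np.ndarray:
    """Smooth climate rasters over time horizons.

    Returns array of shape (n_variables, n_horizons, n_rows, n_cols) where
    horizon 0 is the present.  Each variable is a deterministic meridional
    gradient (``gradient_per_deg`` units per degree latitude) plus a uniform
    temporal trend (``trend_per_horizon`` units per step into the past) plus
    optional Gaussian-smoothed noise.  With ``noise_sd=0`` the spatial
    gradient and temporal difference — hence climate velocity — have closed
    forms.
    """
    if n_horizons < 2:
        raise ValueError("need at least 2 time horizons")
    rng = np.random.default_rng(seed)
    lat, _lon = grid.cell_centroids()
    base = gradient_per_deg * lat
    out = np.empty((n_variables, n_horizons, grid.n_rows, grid.n_cols))
    for v in range(n_variables):
        for h in range(n_horizons):
            layer = base + trend_per_horizon * h
            if noise_sd > 0:
                noise = ndimage.gaussian_filter(
                    rng.normal(size=base.shape), noise_smooth_cells
                )
                layer = layer + noise_sd * noise / max(noise.std(), 1e-12)
            out[v, h] = layer
    return out


def simulate_elevation(
    grid: GridSpec,
    seed: int | np.random.Generator,
    relief: float = 500.0,
    smooth_cells: float = 2.0,
) -> np.ndarray:
    """Random elevation field: Gaussian-filtered white noise scaled to
    a standard deviation of ``relief`` (elevation units).  ``relief=0``
    yields a perfectly flat world."""
    rng = np.random.default_rng(seed)
    if relief == 0:
        return np.zeros((grid.n_rows, grid.n_cols))
    f = ndimage.gaussian_filter(
        rng.normal(size=(grid.n_rows, grid.n_cols)), smooth_cells
    )
    return relief * f / f.std()


def partition_bioregions(
    grid: GridSpec,
    n_regions: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voronoi-like contiguous partition of the grid into bioregions.

    Region membership is by nearest of ``n_regions`` random seed cells
    (Euclidean in grid coordinates), which yields contiguous convex-ish
    regions.  The attached predictor table carries supplied covariates
    (time-integrated area, productivity, temperature) drawn from lognormal
    / latitude-linked distributions — these are consumed, not derived, by
    the analysis.

    Returns (region_id raster of shape (n_rows, n_cols), predictor table).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 bioregions")
    rng = np.random.default_rng(seed)
    nr, nc = grid.n_rows, grid.n_cols
    if n_regions > nr * nc:
        raise ValueError("more regions than grid cells")
    seeds = rng.choice(nr * nc, size=n_regions, replace=False)
    sr, sc = np.divmod(seeds, nc)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    region = np.argmin(d2, axis=-1)
    lat, lon = grid.cell_centroids()
    rows = []
    for j in range(n_regions):
        mask = region == j
        mean_lat = lat[mask].mean()
        rows.append(
            {
                "region": j,
                "centroid_lat": mean_lat,
                "centroid_lon": lon[mask].mean(),
                "n_cells": int(mask.sum()),
                # supplied covariates: areas lognormal, productivity and
                # temperature decline with |latitude| as on a real planet
                "time_integrated_area": rng.lognormal(3.0, 0.5)
                * mask.sum(),
                "productivity": np.exp(-np.abs(mean_lat) / 40.0)
                * rng.lognormal(0.0, 0.3),
                "temperature": 28.0 - 0.45 * np.abs(mean_lat)
                + rng.normal(0.0, 1.5),
            }
        )
    return region, pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------- world ----
@dataclass
class WorldConfig:
    """Parameters of a synthetic world (defaults are the study conditions
    at desk scale: a two-clade radiation on a 60x30-cell grid with a fast
    high-latitude clade, a 100-tree posterior analogue reduced to a small
    sample, 11 paleo horizons and a 32-region partition analogue)."""

    grid: GridSpec = field(default_factory=GridSpec)
    n_species: int = 200
    n_posterior: int = 10
    clade_fractions: tuple[float, ...] = (0.75, 0.25)
    clade_rates: tuple[float, ...] = (0.1, 0.4)
    clade_anchor_lat: tuple[float | None, ...] = (None, None)
    trait_lambda: tuple[float, float] = (0.1, 0.1)
    trait_q: float = 0.02
    size_mean_log: float = 2.5
    size_sd_log: float = 1.0
    n_horizons: int = 11
    climate_gradient: float = 0.5
    climate_trend: float = 1.0
    climate_noise_sd: float = 0.0
    n_climate_vars: int = 3
    relief: float = 500.0
    n_bioregions: int = 16
    seed: int = 0

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["grid"] = vars(self.grid)
        return json.dumps(d, default=str, sort_keys=True)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    posterior: list[Phylogeny]
    ranges: dict[str, np.ndarray]
    traits: dict[str, int]
    clade_of: dict[str, int]
    climate: np.ndarray
    elevation: np.ndarray
    bioregions: np.ndarray
    region_table: pd.DataFrame


def build_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world from one config (deterministic)."""
    rng = np.random.default_rng(config.seed)
    fr = np.asarray(config.clade_fractions, float)
    sizes = np.maximum(2, np.round(fr / fr.sum() * config.n_species)).astype(int)
    posterior = [
        simulate_clade_tree(
            sizes.tolist(), list(config.clade_rates),
            rng.integers(2**31),
        )
        for _ in range(config.n_posterior)
    ]
    species = posterior[0].tip_labels
    clade_of = {sp: int(sp.split("_")[0][1:]) for sp in species}
    anchors: dict[str, float] = {}
    for sp in species:
        a = config.clade_anchor_lat[clade_of[sp]]
        if a is not None:
            # split the anchor across hemispheres, jittered
            sign = 1 if rng.uniform() < 0.5 else -1
            anchors[sp] = sign * a + rng.normal(0, 3.0)
    ranges = simulate_ranges(
        species, config.grid, rng.integers(2**31),
        size_mean_log=config.size_mean_log,
        size_sd_log=config.size_sd_log,
        anchor_lat=anchors if anchors else None,
    )
    traits = {
        sp: int(st)
        for sp, st in zip(
            species,
            (np.random.default_rng(rng.integers(2**31))
             .uniform(size=len(species)) < 0.5).astype(int),
        )
    }
    climate = simulate_climate_stack(
        config.grid, config.n_horizons, rng.integers(2**31),
        n_variables=config.n_climate_vars,
        gradient_per_deg=config.climate_gradient,
        trend_per_horizon=config.climate_trend,
        noise_sd=config.climate_noise_sd,
    )
    elevation = simulate_elevation(
        config.grid, rng.integers(2**31), relief=config.relief
    )
    bioregions, region_table = partition_bioregions(
        config.grid, config.n_bioregions, rng.integers(2**31)
    )
    return SyntheticWorld(
        config=config,
        posterior=posterior,
        ranges=ranges,
        traits=traits,
        clade_of=clade_of,
        climate=climate,
        elevation=elevation,
        bioregions=bioregions,
        region_table=region_table,
    )


# ------------------------------------------------------------- planted ----
def default_horizon_ages(n_horizons: int) -> np.ndarray:
    """Ages (years before present) of the past climate horizons.

    Evenly log-spaced from ~20 kyr to 3.3 Myr, echoing a paleo record that
    samples both late-Quaternary oscillations and the Plio-Pleistocene.
    """
    if n_horizons < 2:
        raise ValueError("need at least 2 horizons")
    return np.logspace(np.log10(2.0e4), np.log10(3.3e6), n_horizons - 1)


def planted_gradient_config(seed: int = 0) -> WorldConfig:
    """Study conditions for the planted inverse latitudinal gradient.

    A 350-species radiation in which 40% of the species form a fast clade
    (birth rate 0.8 vs 0.05) whose ranges are anchored near 45 degrees of
    latitude in both hemispheres, with modest range sizes so the rate
    surface mixes well at the neighbourhood scale of the spatial model —
    a world whose assemblage mean rate rises away from the equator while
    richness does not.
    """
    return WorldConfig(
        grid=GridSpec(lat_min=-60, lat_max=60, lon_min=-30, lon_max=30,
                      resolution=2.5),
        n_species=350,
        n_posterior=3,
        clade_fractions=(0.6, 0.4),
        clade_rates=(0.05, 0.8),
        clade_anchor_lat=(None, 45.0),
        size_mean_log=2.0,
        size_sd_log=0.8,
        seed=seed,
    )


def planted_driver_config(seed: int = 0) -> WorldConfig:
    """Study conditions for the planted driver-effect world.

    32 bioregions on an 80x80-degree grid, ten species per region with
    modest range sizes (so clades mostly stay inside their home region),
    and a 3-tree posterior.
    """
    return WorldConfig(
        grid=GridSpec(lat_min=-40, lat_max=40, lon_min=-40, lon_max=40,
                      resolution=2.5),
        n_species=320,
        n_posterior=3,
        n_bioregions=32,
        size_mean_log=2.0,
        size_sd_log=0.8,
        seed=seed,
    )


def build_driver_world(
    config: WorldConfig,
    effect_velocity: float = 1.2,
    effect_roughness: float = 1.2,
    base_rate: float = 0.12,
) -> tuple[SyntheticWorld, pd.DataFrame, np.ndarray, np.ndarray]:
    """World whose regional speciation rates track velocity and roughness.

    Climate (with smooth noise, so velocity varies in space) and elevation
    are generated first; per-bioregion mean climate velocity and roughness
    are standardised and set the log birth rate of one clade per region:

        log lambda_j = log(base_rate) + effect_velocity * z(velocity_j)
                                      + effect_roughness * z(roughness_j)

    Each region's clade is range-anchored inside that region, so the
    planted effects propagate through the full assemblage pipeline.

    Returns (world, per-region truth table, velocity raster, roughness
    raster).
    """
    from .drivers import region_mean, roughness as roughness_op, \
        velocity_over_horizons

    rng = np.random.default_rng(config.seed)
    grid = config.grid
    noise_sd = config.climate_noise_sd if config.climate_noise_sd > 0 else 2.0
    climate = simulate_climate_stack(
        grid, config.n_horizons, rng.integers(2**31),
        n_variables=config.n_climate_vars,
        gradient_per_deg=config.climate_gradient,
        trend_per_horizon=config.climate_trend,
        noise_sd=noise_sd,
    )
    elevation = simulate_elevation(
        grid, rng.integers(2**31), relief=config.relief
    )
    bioregions, region_table = partition_bioregions(
        grid, config.n_bioregions, rng.integers(2**31)
    )
    cellsize_km = 111.32 * grid.resolution
    vel = velocity_over_horizons(
        climate, default_horizon_ages(config.n_horizons), cellsize_km
    )
    rough = roughness_op(elevation)
    v_reg = region_mean(vel, bioregions)
    r_reg = region_mean(rough, bioregions)
    zv = (v_reg - v_reg.mean()) / v_reg.std(ddof=0)
    zr = (r_reg - r_reg.mean()) / r_reg.std(ddof=0)
    lam = base_rate * np.exp(effect_velocity * zv + effect_roughness * zr)
    lam = lam.clip(0.02, 3.0)

    n_reg = config.n_bioregions
    per = max(2, config.n_species // n_reg)
    sizes = [per] * n_reg
    rates = [float(lam.loc[j]) for j in range(n_reg)]
    posterior = [
        simulate_clade_tree(sizes, rates, rng.integers(2**31))
        for _ in range(config.n_posterior)
    ]
    species = posterior[0].tip_labels
    clade_of = {sp: int(sp.split("_")[0][1:]) for sp in species}
    cells_of_region = {
        j: np.flatnonzero(bioregions.ravel() == j) for j in range(n_reg)
    }
    anchor_cell = {
        sp: int(rng.choice(cells_of_region[clade_of[sp]]))
        for sp in species
    }
    ranges = simulate_ranges(
        species, grid, rng.integers(2**31),
        size_mean_log=config.size_mean_log,
        size_sd_log=config.size_sd_log,
        anchor_cell=anchor_cell,
    )
    traits = {sp: 0 for sp in species}
    world = SyntheticWorld(
        config=config,
        posterior=posterior,
        ranges=ranges,
        traits=traits,
        clade_of=clade_of,
        climate=climate,
        elevation=elevation,
        bioregions=bioregions,
        region_table=region_table,
    )
    truth = pd.DataFrame(
        {"velocity": v_reg, "roughness": r_reg, "planted_rate": lam}
    )
    return world, truth, vel, rough
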