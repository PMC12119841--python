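"""Assemblage grids: presence-absence matrices and per-cell rate summaries.

Species ranges (sets of grid cells) are collated into a cells x species
presence-absence matrix (PAM); per-cell summaries of the member species'
tip speciation rates (arithmetic mean, maximum, coefficient of variation)
are the response surfaces of the geographic analysis.  Species are also
classified tropical / non-tropical by the latitude of their range centroid
relative to the tropics of Cancer and Capricorn (23.44 degrees).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GridSpec

__all__ = [
    "AssemblageGrid",
    "build_pam",
    "cell_summaries",
    "classify_latitude",
    "order_subset",
    "TROPICS_LATITUDE",
]

log = logging.getLogger(__name__)

#: Latitude of the tropics of Cancer / Capricorn in decimal degrees.
TROPICS_LATITUDE = 23.44


@dataclass
class AssemblageGrid:
    """Cells x species presence-absence matrix with cell geometry.

    ``pam`` is a boolean array of shape (n_cells, n_species); only cells
    with at least one species are retained.  ``cell_ids`` index into the
    underlying :class:`~speciogeo.simulate.GridSpec`; centroids are in
    decimal degrees.
    """

    grid: GridSpec
    cell_ids: np.ndarray
    cell_lat: np.ndarray
    cell_lon: np.ndarray
    species: list[str]
    pam: np.ndarray

    @property
    def richness(self) -> np.ndarray:
        return self.pam.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_sparse_csv(self, path: str) -> None:
        """Long-format PAM export: one (cell_id, species) row per presence."""
        rows, cols = np.nonzero(self.pam)
        pd.DataFrame(
            {
                "cell_id": self.cell_ids[rows],
                "species": [self.species[c] for c in cols],
            }
        ).to_csv(path, index=False)


def build_pam(
    ranges: dict[str, np.ndarray],
    grid: GridSpec,
    rates: pd.DataFrame | None = None,
) -> AssemblageGrid:
    """Build the presence-absence matrix from cell-set ranges.

    A species is present in a cell when its range occupies any part of the
    cell (ranges are stored as cell-id sets, so occupancy is membership).
    Cells with zero species are dropped (count logged).  If ``rates`` is
    given, species absent from the rate table are excluded with a warning
    listing them — mirroring the intersection of range data with the
    phylogeny.
    """
    species = sorted(ranges)
    if rates is not None:
        missing = [s for s in species if s not in rates.index]
        if missing:
            warnings.warn(
                f"excluding {len(missing)} species with ranges but no "
                f"rates: {missing[:10]}{'...' if len(missing) > 10 else ''}",
                stacklevel=2,
            )
            species = [s for s in species if s in rates.index]
    if not species:
        raise ValueError("no species left after rate-table intersection")
    for s in species:
        if len(ranges[s]) == 0:
            raise ValueError(f"species {s!r} has an empty range")
    n_cells = grid.n_cells
    pam_full = np.zeros((n_cells, len(species)), dtype=bool)
    for j, s in enumerate(species):
        pam_full[np.asarray(ranges[s]), j] = True
    occupied = pam_full.any(axis=1)
    n_dropped = int((~occupied).sum())
    log.info("dropping %d empty cells of %d", n_dropped, n_cells)
    cell_ids = np.flatnonzero(occupied)
    lat, lon = grid.cell_centroids()
    return AssemblageGrid(
        grid=grid,
        cell_ids=cell_ids,
        cell_lat=lat.ravel()[cell_ids],
        cell_lon=lon.ravel()[cell_ids],
        species=species,
        pam=pam_full[occupied],
    )


def cell_summaries(
    agrid: AssemblageGrid, rates: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell mean, max and coefficient of variation of member tip rates.

    ``cv_rate`` is the percent sample coefficient of variation
    (100 * sd / mean with the n-1 standard deviation); it is NaN for
    richness-1 cells, where dispersion is undefined.
    """
    missing = [s for s in agrid.species if s not in rates.index]
    if missing:
        raise KeyError(f"species without rates: {missing[:10]}")
    r = rates.loc[agrid.species, "dr_mean"].to_numpy(float)
    pam = agrid.pam
    richness = pam.sum(axis=1)
    total = pam @ r
    mean = total / richness
    # max over members without densifying per cell
    mx = np.where(pam, r[None, :], -np.inf).max(axis=1)
    sq = pam @ (r**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sq - richness * mean**2) / (richness - 1)
        var = np.maximum(var, 0.0)  # numerical floor
        cv = 100.0 * np.sqrt(var) / mean
    cv[richness < 2] = np.nan
    return pd.DataFrame(
        {
            "cell_id": agrid.cell_ids,
            "lat": agrid.cell_lat,
            "lon": agrid.cell_lon,
            "richness": richness,
            "mean_rate": mean,
            "max_rate": mx,
            "cv_rate": cv,
        }
    ).set_index("cell_id")


def classify_latitude(
    ranges: dict[str, np.ndarray],
    grid: GridSpec,
    boundary: float = TROPICS_LATITUDE,
    method: str = "area_weighted",
) -> pd.DataFrame:
    """Tropical / non-tropical classification by range latitudinal midpoint.

    The midpoint is the area-weighted mean of member-cell centroid
    latitudes (cell area is proportional to cos(latitude) on a geographic
    grid); ``method="bounding_box"`` uses the midpoint of the range's
    latitudinal extent instead.  Species with |midpoint| <= ``boundary``
    are tropical (the boundary itself is inclusive).
    """
    lat = grid.cell_centroids()[0].ravel()
    rows = []
    for sp in sorted(ranges):
        cells = np.asarray(ranges[sp])
        if len(cells) == 0:
            raise ValueError(f"species {sp!r} has an empty range")
        cell_lats = lat[cells]
        if method == "area_weighted":
            w = np.cos(np.radians(cell_lats))
            mid = float(np.average(cell_lats, weights=w))
        elif method == "bounding_box":
            mid = float((cell_lats.min() + cell_lats.max()) / 2.0)
        else:
            raise ValueError(f"unknown midpoint method {method!r}")
        rows.append(
            {
                "species": sp,
                "midpoint_lat": mid,
                "tropical": abs(mid) <= boundary,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def order_subset(
    agrid: AssemblageGrid,
    taxon_map: dict[str, str],
    group: str,
) -> AssemblageGrid:
    """Restrict the PAM to one taxonomic group's species.

    ``taxon_map`` assigns each species to exactly one group label; cells
    left empty after the restriction are dropped.
    """
    unknown = [s for s in agrid.species if s not in taxon_map]
    if unknown:
        raise KeyError(f"species without a group: {unknown[:10]}")
    if group not in set(taxon_map.values()):
        raise KeyError(f"unknown group label {group!r}")
    keep = [i for i, s in enumerate(agrid.species) if taxon_map[s] == group]
    if not keep:
        raise ValueError(f"group {group!r} matches no gridded species")
    pam = agrid.pam[:, keep]
    occupied = pam.any(axis=1)
    return AssemblageGrid(
        grid=agrid.grid,
        cell_ids=agrid.cell_ids[occupied],
        cell_lat=agrid.cell_lat[occupied],
        cell_lon=agrid.cell_lon[occupied],
        species=[agrid.species[i] for i in keep],
        pam=pam[occupied],
    )
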