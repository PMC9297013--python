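"""Grid geometry, occupancy matrices, range diameters and dispersal pools.

The gain null model draws immigrants from a dispersal-limited candidate
pool: each species' dispersal ability is approximated as half its longest
great-circle range diameter D, a cell's colonizable radius is the mean
dispersal ability of the species currently occupying it, and candidates are
all species with at least one occupied cell centroid within that radius.

All distances are centroid-to-centroid haversine on a sphere of radius
6371 km; longitude wrap-around is handled by the formula itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "Grid",
    "OccurrenceMatrix",
    "SpeciesRangeSummary",
    "DispersalPool",
    "great_circle_distance",
    "pairwise_cell_distances",
    "longest_range_diameter",
    "range_summaries",
    "colonizable_radius",
    "gain_candidate_pool",
]

EARTH_RADIUS_KM = 6371.0


def _validate_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 360):
        raise ValueError("longitude out of plausible range")


def great_circle_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine distance in kilometres; accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=np.float64) for x in (lat1, lon1, lat2, lon2))
    _validate_coords(lat1, lon1)
    _validate_coords(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class Grid:
    """Ordered grid cells with centroid coordinates in decimal degrees."""

    cell_ids: tuple[str, ...]
    lats: np.ndarray
    lons: np.ndarray
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        _validate_coords(self.lats, self.lons)
        # normalize longitude to [-180, 180)
        lons = ((np.asarray(self.lons, dtype=np.float64) + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "lats", np.asarray(self.lats, dtype=np.float64))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def index_of(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(cell_id)
        except ValueError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary cells-by-species occupancy for one time slice."""

    grid: Grid
    species: tuple[str, ...]
    values: np.ndarray  # bool, (n_cells, n_species)
    slice_tag: str = "current"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError(
                f"occupancy shape {vals.shape} does not match "
                f"{self.grid.n_cells} cells x {len(self.species)} species"
            )
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("non-binary occupancy values")
        object.__setattr__(self, "values", vals.astype(bool))

    def species_at(self, cell_index: int) -> frozenset:
        present = self.values[cell_index]
        return frozenset(s for s, v in zip(self.species, present) if v)

    def cells_of(self, species_label: str) -> np.ndarray:
        j = self.species.index(species_label)
        return np.flatnonzero(self.values[:, j])


def pairwise_cell_distances(grid: Grid) -> np.ndarray:
    """(n_cells, n_cells) haversine distance matrix between centroids."""
    return great_circle_distance(
        grid.lats[:, None], grid.lons[:, None], grid.lats[None, :], grid.lons[None, :]
    )


def longest_range_diameter(lats, lons) -> float:
    """Maximum pairwise great-circle distance among occupied centroids.

    A single-cell range has diameter 0.  Brute-force O(k^2) pairwise scan.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=np.float64))
    lons = np.atleast_1d(np.asarray(lons, dtype=np.float64))
    if lats.size == 0:
        raise ValueError("empty centroid list")
    if lats.size == 1:
        return 0.0
    d = great_circle_distance(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    return float(d.max())


@dataclass(frozen=True)
class SpeciesRangeSummary:
    species: str
    n_cells: int
    diameter_km: float
    dispersal_km: float  # = diameter / 2


def range_summaries(
    occ: OccurrenceMatrix, cell_dist: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-species occupied-cell count, longest range diameter D and D/2.

    Species absent from every cell get diameter NaN (no range to measure).
    """
    if cell_dist is None:
        cell_dist = pairwise_cell_distances(occ.grid)
    rows = []
    for j, sp in enumerate(occ.species):
        cells = np.flatnonzero(occ.values[:, j])
        if cells.size == 0:
            rows.append((sp, 0, np.nan, np.nan))
            continue
        diameter = float(cell_dist[np.ix_(cells, cells)].max()) if cells.size > 1 else 0.0
        rows.append((sp, int(cells.size), diameter, diameter / 2.0))
    return pd.DataFrame(rows, columns=["species", "n_cells", "diameter_km", "dispersal_km"]).set_index(
        "species"
    )


def colonizable_radius(
    cell_index: int, occ: OccurrenceMatrix, summaries: pd.DataFrame
) -> float | None:
    """Mean dispersal ability (D/2) over the cell's current species.

    Returns None for a cell with no current species (no assemblage to
    average over).
    """
    present = [s for s, v in zip(occ.species, occ.values[cell_index]) if v]
    if not present:
        return None
    return float(summaries.loc[present, "dispersal_km"].mean())


@dataclass(frozen=True)
class DispersalPool:
    """Gain-null candidate pool for one focal cell."""

    cell_id: str
    radius_km: float
    candidates: frozenset

    def __post_init__(self) -> None:
        if self.radius_km < 0:
            raise ValueError("negative colonizable radius")


def gain_candidate_pool(
    cell_index: int,
    radius_km: float,
    occ: OccurrenceMatrix,
    remaining,
    cell_dist_row: np.ndarray | None = None,
) -> DispersalPool:
    """Species with an occupied cell centroid within ``radius_km`` of the
    focal cell, minus the remaining set.

    Locally lost species sit at distance 0 and stay eligible: gains are
    added on top of the remaining set, so only the remaining species are
    excluded.
    """
    if cell_dist_row is None:
        g = occ.grid
        cell_dist_row = great_circle_distance(
            g.lats[cell_index], g.lons[cell_index], g.lats, g.lons
        )
    near = cell_dist_row <= radius_km
    reachable = occ.values[near].any(axis=0)
    candidates = {s for s, r in zip(occ.species, reachable) if r} - set(remaining)
    return DispersalPool(
        cell_id=occ.grid.cell_ids[cell_index],
        radius_km=float(radius_km),
        candidates=frozenset(candidates),
    )
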