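"""Readers and writers for the pipeline's file formats.

Trees travel as newick with branch lengths.  Occupancy travels as wide CSV:
mandatory ``cell_id, lat, lon`` columns followed by one 0/1 column per
species, one row per grid cell — human-inspectable for toy inputs.  A
sparse long format (``cell_id, species`` pairs) is accepted as an alternate
dialect for large inputs.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .spatial import Grid, OccurrenceMatrix
from .tree import PhyloTree

log = logging.getLogger(__name__)

__all__ = [
    "read_tree",
    "write_tree",
    "read_occurrence",
    "write_occurrence",
    "write_scenario",
]

_META_COLS = ("cell_id", "lat", "lon")


def read_tree(path: str | os.PathLike) -> PhyloTree:
    """Parse a newick file into a validated :class:`PhyloTree`."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_tree(tree: PhyloTree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")


def read_occurrence(
    path: str | os.PathLike,
    tree: PhyloTree | None = None,
    slice_tag: str = "current",
    resolution: float = 0.5,
    dialect: str = "wide",
) -> OccurrenceMatrix:
    """Read an occupancy CSV into an :class:`OccurrenceMatrix`.

    When a tree is given, every species column must be a tree tip (error
    lists the offenders); tree tips absent from the matrix are allowed and
    logged.  Sparse dialect expects cell metadata columns plus a trailing
    ``species`` column of present pairs.
    """
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file missing columns {missing}")

    if dialect == "wide":
        species = tuple(str(c).strip() for c in df.columns if c not in _META_COLS)
        cells = df[list(_META_COLS)]
        values = df[[c for c in df.columns if c not in _META_COLS]].to_numpy()
        if not np.isin(values, [0, 1]).all():
            bad = sorted(set(values.ravel()) - {0, 1})
            raise ValueError(f"non-binary occupancy values: {bad}")
    elif dialect == "sparse":
        if "species" not in df.columns:
            raise ValueError("sparse dialect needs a 'species' column")
        cells = df[list(_META_COLS)].drop_duplicates("cell_id")
        species = tuple(sorted(df["species"].astype(str).str.strip().unique()))
        sp_index = {s: j for j, s in enumerate(species)}
        cell_index = {c: i for i, c in enumerate(cells["cell_id"])}
        values = np.zeros((len(cells), len(species)), dtype=bool)
        for cid, sp in zip(df["cell_id"], df["species"].astype(str).str.strip()):
            values[cell_index[cid], sp_index[sp]] = True
    else:
        raise ValueError(f"unknown occurrence dialect {dialect!r}")

    if cells["cell_id"].duplicated().any():
        dupes = sorted(cells.loc[cells["cell_id"].duplicated(), "cell_id"].unique())
        raise ValueError(f"duplicate cell ids: {dupes}")

    grid = Grid(
        cell_ids=tuple(str(c) for c in cells["cell_id"]),
        lats=cells["lat"].to_numpy(dtype=np.float64),
        lons=cells["lon"].to_numpy(dtype=np.float64),
        resolution=resolution,
    )
    if tree is not None:
        unknown = sorted(set(species) - set(tree.tip_labels))
        if unknown:
            raise ValueError(f"species columns not found in tree: {unknown}")
        extra = set(tree.tip_labels) - set(species)
        if extra:
            log.info("%d tree tips absent from the occurrence matrix", len(extra))
    return OccurrenceMatrix(grid=grid, species=species, values=values, slice_tag=slice_tag)


def write_occurrence(occ: OccurrenceMatrix, path: str | os.PathLike) -> None:
    meta = pd.DataFrame(
        {
            "cell_id": occ.grid.cell_ids,
            "lat": occ.grid.lats,
            "lon": occ.grid.lons,
        }
    )
    species = pd.DataFrame(occ.values.astype(int), columns=list(occ.species))
    pd.concat([meta, species], axis=1).to_csv(path, index=False)


def write_scenario(scenario, out_dir: str | os.PathLike) -> dict:
    """Write tree + both slices + config sidecar; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "tree": os.path.join(out_dir, "tree.nwk"),
        "current": os.path.join(out_dir, "current.csv"),
        "future": os.path.join(out_dir, "future.csv"),
        "config": os.path.join(out_dir, "scenario_config.json"),
    }
    write_tree(scenario.tree, paths["tree"])
    write_occurrence(scenario.current, paths["current"])
    write_occurrence(scenario.future, paths["future"])
    with open(paths["config"], "w") as fh:
        fh.write(scenario.config_json() + "\n")
    return paths
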