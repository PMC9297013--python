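"""Synthetic trees, grids and paired current/future occupancy matrices.

Stands in for the study system this pipeline targets: gridded
presence-absence projections of many species for two time slices, with
species' occupancy driven by a climate-envelope caricature.  Each species
occupies a rectangular band of cells — a latitudinal niche (optimum +
breadth) crossed with a longitudinal extent — and "climate change" moves or
rescales those bands:

* ``random`` — every species' latitudinal optimum shifts by an independent
  sign-symmetric draw, producing phylogenetically unstructured loss and
  gain (the basis of the null-calibration checks);
* ``uniform_poleward`` — all shifts share the poleward direction with
  species-specific magnitudes;
* ``clade_biased_loss`` — species of one designated clade contract toward
  their niche centre by the effect-size fraction (1.0 = vanish everywhere)
  while all others persist unchanged;
* ``clade_biased_gain`` — the designated clade expands into new cells;
* ``random_dropout`` — every species-cell presence is independently lost
  with a fixed probability, so that conditional on a cell and its loss
  count, the lost species are an exactly uniform draw from the assemblage.
  This is the reference scenario for null-model calibration checks: the
  band-shift modes produce losses that are phylogenetically random only on
  average over scenarios (edge species are the ones lost, and with a single
  shared tree the per-cell quantiles are mutually dependent), whereas
  per-presence dropout satisfies the exchangeability premise cell by cell.

A latitudinal optimum can carry phylogenetic signal (a Brownian-motion
trait evolved along the tree, blended with an independent draw), so both
phylogenetically random and phylogenetically biased scenarios are
available.  Species whose current range does not exceed the minimum cell
count are resampled, mirroring the range-size filter applied to real
range-map data before modelling.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import asdict, dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .spatial import Grid, OccurrenceMatrix
from .tree import PhyloTree

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "simulate_tree",
    "select_clade",
    "simulate_current_ranges",
    "simulate_future_ranges",
    "simulate_scenario",
]

SHIFT_MODES = (
    "random",
    "uniform_poleward",
    "clade_biased_loss",
    "clade_biased_gain",
    "random_dropout",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full recipe for one synthetic scenario; a pure function of its fields.

    Defaults give a 40 x 40 cell regional grid at 0.5 degree resolution and
    128 species, every species occupying strictly more than
    ``min_range_cells`` cells in the current slice.
    """

    n_species: int = 128
    lat_min: float = 30.0
    lat_max: float = 50.0
    lon_min: float = 0.0
    lon_max: float = 20.0
    resolution: float = 0.5
    breadth_min: float = 3.0  # degrees latitude
    breadth_max: float = 8.0
    lon_width_min_frac: float = 0.3  # fraction of the grid's lon extent
    lon_width_max_frac: float = 1.0
    phylo_signal: float = 0.0  # 0 = i.i.d. optima, 1 = fully Brownian
    shift_mode: str = "random"
    shift_sd: float = 1.5  # degrees, random / poleward shift scale
    effect_size: float = 0.5  # contraction/expansion fraction, clade modes
    dropout_p: float = 0.15  # per-presence loss probability, random_dropout
    clade_fraction: float = 0.25  # target clade size as share of species
    min_range_cells: int = 10  # retained species occupy strictly more
    max_resample: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.shift_mode not in SHIFT_MODES:
            raise ValueError(f"unknown shift mode {self.shift_mode!r}")
        if not (0.0 <= self.phylo_signal <= 1.0):
            raise ValueError("phylo_signal must be in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """One simulated study: tree, grid, the two occupancy slices, niches."""

    config: ScenarioConfig
    tree: PhyloTree
    grid: Grid
    current: OccurrenceMatrix
    future: OccurrenceMatrix
    niches: pd.DataFrame  # per-species niche parameters, current slice
    clade: frozenset  # designated clade tips (clade-biased modes)

    def config_json(self) -> str:
        return json.dumps(asdict(self.config), indent=2, sort_keys=True)


def simulate_tree(n_species: int, seed: int) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree, depth scaled to 1, tips sp0001...

    Deterministic per seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 tips")
    rng = _random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.seed_node.edge.length = None  # drop the stem above the root
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth == 0:  # n=2 stops at the first split; make it a unit cherry
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
    else:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / depth
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:04d}"
    return PhyloTree(tree)


def select_clade(tree: PhyloTree, fraction: float = 0.25) -> frozenset:
    """Designate the most phylogenetically distinct clade of moderate size.

    Among internal clades holding between ~5% of the tips (at least 4) and
    ~``fraction`` of the tips, choose the one with the largest unique
    branch length per member (clade subtree plus stem, divided by tip
    count).  Losing such a clade removes disproportionately much
    evolutionary history, which is what the clade-biased scenarios are for;
    a dense recent radiation of the same size would be phylogenetically
    redundant and its loss indistinguishable from random.  Deterministic;
    ties go to preorder position.
    """
    n = tree.n_tips

    def pick(lo: int, hi: int):
        best = None
        for pos, node in enumerate(tree.dendropy_tree.preorder_node_iter()):
            if node.is_leaf() or node.parent_node is None:
                continue
            tips = [lf.taxon.label for lf in node.leaf_iter()]
            if not (lo <= len(tips) <= hi):
                continue
            stem = node.edge.length or 0.0
            subtree = sum(
                nd.edge.length for nd in node.preorder_iter() if nd is not node
            )
            score = ((subtree + stem) / len(tips), -pos)
            if best is None or score > best[0]:
                best = (score, frozenset(tips))
        return best

    lo = max(4, int(np.ceil(0.05 * n)))
    hi = max(lo, int(np.floor(fraction * n)))
    best = pick(lo, hi) or pick(2, max(hi, n // 2))  # small trees: widen
    if best is None:
        raise ValueError("tree has no internal clade in the eligible size range")
    return best[1]


def _make_grid(cfg: ScenarioConfig) -> Grid:
    half = cfg.resolution / 2.0
    lats = np.arange(cfg.lat_min + half, cfg.lat_max, cfg.resolution)
    lons = np.arange(cfg.lon_min + half, cfg.lon_max, cfg.resolution)
    lon_grid, lat_grid = np.meshgrid(lons, lats)
    lat_flat, lon_flat = lat_grid.ravel(), lon_grid.ravel()
    ids = tuple(f"cell{i:05d}" for i in range(lat_flat.size))
    return Grid(cell_ids=ids, lats=lat_flat, lons=lon_flat, resolution=cfg.resolution)


def _brownian_trait(tree: PhyloTree, rng: np.random.Generator) -> np.ndarray:
    """One Brownian-motion trait per tip, evolved along branch lengths."""
    values: dict[int, float] = {}
    dtree = tree.dendropy_tree
    values[id(dtree.seed_node)] = 0.0
    tip_values: dict[str, float] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            step = rng.normal(0.0, np.sqrt(max(node.edge.length, 0.0)))
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            tip_values[node.taxon.label] = values[id(node)]
    return np.asarray([tip_values[lb] for lb in tree.tip_labels])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _draw_optima(tree: PhyloTree, cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Latitudinal optima over the grid's lat extent, with optional signal."""
    n = tree.n_tips
    z_iid = rng.normal(size=n)
    s = cfg.phylo_signal
    if s > 0:
        z_brown = _standardize(_brownian_trait(tree, rng))
        z = s * z_brown + np.sqrt(1.0 - s**2) * _standardize(z_iid)
    else:
        z = z_iid
    u = norm.cdf(z)
    return cfg.lat_min + u * (cfg.lat_max - cfg.lat_min)


def _occupancy(grid: Grid, niches: pd.DataFrame) -> np.ndarray:
    lat = grid.lats[:, None]
    lon = grid.lons[:, None]
    opt = niches["lat_opt"].to_numpy()[None, :]
    half_b = niches["breadth"].to_numpy()[None, :] / 2.0
    lon_c = niches["lon_center"].to_numpy()[None, :]
    half_w = niches["lon_width"].to_numpy()[None, :] / 2.0
    return (np.abs(lat - opt) <= half_b) & (np.abs(lon - lon_c) <= half_w)


def simulate_current_ranges(
    tree: PhyloTree, cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[OccurrenceMatrix, pd.DataFrame]:
    """Current-slice occupancy plus the niche table that generated it.

    Each species gets a latitudinal band (optimum, breadth) and a
    longitudinal extent; occupancy is the set of cells whose centroid falls
    in the rectangle.  Species at or below the minimum range size are
    re-drawn (fresh optimum/breadth/extent) until the filter passes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    grid = _make_grid(cfg)
    n = tree.n_tips
    lon_extent = cfg.lon_max - cfg.lon_min

    optima = _draw_optima(tree, cfg, rng)
    breadth = rng.uniform(cfg.breadth_min, cfg.breadth_max, size=n)
    lon_center = rng.uniform(cfg.lon_min, cfg.lon_max, size=n)
    lon_width = rng.uniform(cfg.lon_width_min_frac, cfg.lon_width_max_frac, size=n) * lon_extent

    niches = pd.DataFrame(
        {
            "species": list(tree.tip_labels),
            "lat_opt": optima,
            "breadth": breadth,
            "lon_center": lon_center,
            "lon_width": lon_width,
        }
    ).set_index("species")

    occ = _occupancy(grid, niches)
    for j in range(n):
        tries = 0
        while occ[:, j].sum() <= cfg.min_range_cells:
            tries += 1
            if tries > cfg.max_resample:
                raise ValueError(
                    "grid too small for the minimum range size: widen the "
                    "extent, coarsen the filter or broaden the niches"
                )
            niches.iloc[j, 0] = cfg.lat_min + rng.uniform() * (cfg.lat_max - cfg.lat_min)
            niches.iloc[j, 1] = rng.uniform(cfg.breadth_min, cfg.breadth_max)
            niches.iloc[j, 2] = rng.uniform(cfg.lon_min, cfg.lon_max)
            niches.iloc[j, 3] = rng.uniform(cfg.lon_width_min_frac, cfg.lon_width_max_frac) * lon_extent
            occ[:, [j]] = _occupancy(grid, niches.iloc[[j]])
    matrix = OccurrenceMatrix(grid=grid, species=tree.tip_labels, values=occ, slice_tag="current")
    return matrix, niches


def simulate_future_ranges(
    current: OccurrenceMatrix,
    tree: PhyloTree,
    cfg: ScenarioConfig,
    niches: pd.DataFrame,
    clade: frozenset,
    rng: np.random.Generator | None = None,
) -> OccurrenceMatrix:
    """Future-slice occupancy under the configured range-shift mode."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    fut = niches.copy()
    n = len(fut)
    in_clade = fut.index.isin(clade)

    if cfg.shift_mode == "random":
        fut["lat_opt"] = fut["lat_opt"] + rng.normal(0.0, cfg.shift_sd, size=n)
    elif cfg.shift_mode == "uniform_poleward":
        fut["lat_opt"] = fut["lat_opt"] + np.abs(rng.normal(0.0, cfg.shift_sd, size=n))
    elif cfg.shift_mode == "clade_biased_loss":
        shrink = 1.0 - cfg.effect_size
        fut.loc[in_clade, "breadth"] *= shrink
        fut.loc[in_clade, "lon_width"] *= shrink
    elif cfg.shift_mode == "clade_biased_gain":
        grow = 1.0 + cfg.effect_size
        fut.loc[in_clade, "breadth"] *= grow
        fut.loc[in_clade, "lon_width"] *= grow
    elif cfg.shift_mode == "random_dropout":
        keep = rng.random(current.values.shape) >= cfg.dropout_p
        occ = current.values & keep
        return OccurrenceMatrix(
            grid=current.grid, species=current.species, values=occ, slice_tag="future"
        )
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown shift mode {cfg.shift_mode!r}")

    occ = _occupancy(current.grid, fut)
    return OccurrenceMatrix(
        grid=current.grid, species=current.species, values=occ, slice_tag="future"
    )


def simulate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Full scenario bundle; deterministic per config (seeds included)."""
    tree = simulate_tree(cfg.n_species, cfg.seed)
    clade = select_clade(tree, cfg.clade_fraction)
    current, niches = simulate_current_ranges(
        tree, cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    )
    future = simulate_future_ranges(
        current, tree, cfg, niches, clade,
        np.random.default_rng(np.random.SeedSequence([cfg.seed, 2])),
    )
    return Scenario(
        config=cfg, tree=tree, grid=current.grid, current=current,
        future=future, niches=niches, clade=clade,
    )
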