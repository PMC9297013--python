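"""Randomization null models for the loss and gain components of change.

The observed loss (gain) component of Faith PD and MPD change in a cell is
compared against the same component recomputed under random species removal
(addition):

* **loss null** — the same number of species as projected to be lost is
  removed uniformly at random, without replacement, from the cell's current
  assemblage (the species pool is the focal assemblage itself);
* **gain null** — the same number of species as projected to be gained is
  drawn uniformly without replacement from the dispersal-limited candidate
  pool and added on top of the remaining species.

Both metrics are evaluated on the *same* replicate draw, so their null
distributions are paired within a cell/component.  The observed component
is located in the replicate distribution by a tail quantile q (mid-rank tie
rule); q below the low threshold or above the high threshold is flagged
significant, mirroring a two-sided p-value read off both tails.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .spatial import DispersalPool
from .transition import AssemblageTransition
from .tree import (
    PatristicMatrix,
    PhyloTree,
    faith_pd,
    mpd,
    mpd_over_masks,
    pd_over_masks,
)

__all__ = [
    "NullConfig",
    "NullDistribution",
    "cell_rng",
    "random_loss_null",
    "random_gain_null",
    "tail_quantile",
    "flag_significance",
]


@dataclass(frozen=True)
class NullConfig:
    """Replication count, significance thresholds and the master seed."""

    n_reps: int = 1000
    low: float = 0.05
    high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 < self.low < self.high < 1.0):
            raise ValueError("thresholds must satisfy 0 < low < high < 1")


@dataclass(frozen=True)
class NullDistribution:
    """Replicate deltas and the observed component's position among them."""

    cell_id: str
    metric: str  # FaithPD | MPD
    component: str  # loss | gain
    observed: float | None
    replicates: np.ndarray | None
    q: float | None
    flag: str  # sig_low | sig_high | ns | untestable
    reason: str | None = None
    n_reps: int = 0


_COMPONENT_CODE = {"loss": 1, "gain": 2}


def cell_rng(cfg: NullConfig, cell_id: str, component: str) -> np.random.Generator:
    """Independent, order-invariant substream keyed by (seed, cell, component)."""
    key = zlib.crc32(cell_id.encode("utf-8"))
    ss = np.random.SeedSequence([cfg.seed, key, _COMPONENT_CODE[component]])
    return np.random.default_rng(ss)


def tail_quantile(replicates: np.ndarray, observed: float) -> float:
    """Position of the observed delta in the replicate distribution.

    q = (#{r < obs} + 0.5 * #{r = obs}) / n.  The mid-rank half-weight on
    ties guarantees a degenerate (constant) null is never significant.
    """
    replicates = np.asarray(replicates, dtype=np.float64)
    defined = replicates[~np.isnan(replicates)]
    if defined.size == 0:
        raise ValueError("no defined replicates")
    below = np.count_nonzero(defined < observed)
    ties = np.count_nonzero(defined == observed)
    return (below + 0.5 * ties) / defined.size


def flag_significance(q: float, cfg: NullConfig) -> str:
    if q < cfg.low:
        return "sig_low"
    if q > cfg.high:
        return "sig_high"
    return "ns"


def _untestable(cell_id: str, metric: str, component: str, reason: str) -> NullDistribution:
    return NullDistribution(
        cell_id=cell_id,
        metric=metric,
        component=component,
        observed=None,
        replicates=None,
        q=None,
        flag="untestable",
        reason=reason,
    )


def _finish(
    cell_id: str,
    metric: str,
    component: str,
    observed: float,
    replicates: np.ndarray,
    cfg: NullConfig,
) -> NullDistribution:
    q = tail_quantile(replicates, observed)
    return NullDistribution(
        cell_id=cell_id,
        metric=metric,
        component=component,
        observed=float(observed),
        replicates=replicates,
        q=q,
        flag=flag_significance(q, cfg),
        n_reps=cfg.n_reps,
    )


def random_loss_null(
    tree: PhyloTree,
    dist: PatristicMatrix,
    tr: AssemblageTransition,
    cfg: NullConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, NullDistribution]:
    """Null for the loss component: drop |S_lost| random species from
    S_current, n_reps times; delta = metric(survivors) - metric(current).

    Returns one NullDistribution per metric, both driven by the same draws.
    Because each replicate removes exactly |S_lost| species, the surviving
    count is constant across replicates; MPD is untestable whenever that
    count (or the current count) falls below two.
    """
    if rng is None:
        rng = cell_rng(cfg, tr.cell_id, "loss")
    cell = tr.cell_id
    n_lost = len(tr.lost)
    if n_lost == 0:
        return {m: _untestable(cell, m, "loss", "no loss") for m in ("FaithPD", "MPD")}

    cur = sorted(tr.current)
    n_cur = len(cur)
    cur_idx = tree.indices_of(cur)
    n_surv = n_cur - n_lost

    # one shared set of draws for both metrics
    keys = rng.random((cfg.n_reps, n_cur))
    masks = np.ones((cfg.n_reps, n_cur), dtype=bool)
    if n_lost < n_cur:
        removed = np.argpartition(keys, n_lost - 1, axis=1)[:, :n_lost]
    else:
        removed = np.broadcast_to(np.arange(n_cur), (cfg.n_reps, n_cur))
    np.put_along_axis(masks, removed, False, axis=1)

    # observed survivors evaluated through the same batched code path as the
    # replicates, so exact ties in degenerate nulls stay exact
    obs_mask = np.asarray([[s in tr.remaining for s in cur]])
    pd_cur = faith_pd(tree, tr.current).value
    pd_reps = pd_over_masks(tree, cur_idx, masks) - pd_cur
    pd_obs = float(pd_over_masks(tree, cur_idx, obs_mask)[0]) - pd_cur
    out = {"FaithPD": _finish(cell, "FaithPD", "loss", pd_obs, pd_reps, cfg)}

    if n_cur < 2:
        out["MPD"] = _untestable(cell, "MPD", "loss", "MPD undefined for baseline")
    elif n_surv < 2:
        out["MPD"] = _untestable(cell, "MPD", "loss", "MPD undefined in replicates")
    else:
        mpd_cur = mpd(dist, tr.current).value
        dist_sub = dist.submatrix(dist.indices_of(cur))
        mpd_reps = mpd_over_masks(dist_sub, masks) - mpd_cur
        mpd_obs = float(mpd_over_masks(dist_sub, obs_mask)[0]) - mpd_cur
        out["MPD"] = _finish(cell, "MPD", "loss", mpd_obs, mpd_reps, cfg)
    return out


def random_gain_null(
    tree: PhyloTree,
    dist: PatristicMatrix,
    tr: AssemblageTransition,
    pool: DispersalPool,
    cfg: NullConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, NullDistribution]:
    """Null for the gain component: add |S_gained| random pool species to
    S_remaining, n_reps times; delta = metric(remaining + draw) -
    metric(remaining)."""
    if rng is None:
        rng = cell_rng(cfg, tr.cell_id, "gain")
    cell = tr.cell_id
    n_gain = len(tr.gained)
    if n_gain == 0:
        return {m: _untestable(cell, m, "gain", "no gain") for m in ("FaithPD", "MPD")}
    cand = sorted(pool.candidates)
    if len(cand) < n_gain:
        return {
            m: _untestable(cell, m, "gain", "pool too small") for m in ("FaithPD", "MPD")
        }

    rem = sorted(tr.remaining)
    n_rem = len(rem)
    # projected gains may lie outside the pool; pad them in as extra
    # columns (never drawn) so the observed delta runs through the same
    # batched code path as the replicates
    extra = sorted(tr.gained - pool.candidates)
    labels = rem + cand + extra  # mask columns follow this order exactly
    idx = tree.indices_of(labels)

    masks = np.zeros((cfg.n_reps, len(labels)), dtype=bool)
    masks[:, :n_rem] = True
    keys = rng.random((cfg.n_reps, len(cand)))
    chosen = np.argpartition(keys, n_gain - 1, axis=1)[:, :n_gain]
    np.put_along_axis(masks, n_rem + chosen, True, axis=1)
    obs_mask = np.asarray([[s in tr.future for s in labels]])

    pd_rem = faith_pd(tree, tr.remaining).value
    pd_reps = pd_over_masks(tree, idx, masks) - pd_rem
    pd_obs = float(pd_over_masks(tree, idx, obs_mask)[0]) - pd_rem
    out = {"FaithPD": _finish(cell, "FaithPD", "gain", pd_obs, pd_reps, cfg)}

    if n_rem < 2:
        out["MPD"] = _untestable(cell, "MPD", "gain", "MPD undefined for baseline")
    else:
        mpd_rem = mpd(dist, tr.remaining).value
        dist_sub = dist.submatrix(dist.indices_of(labels))
        mpd_reps = mpd_over_masks(dist_sub, masks) - mpd_rem
        mpd_obs = float(mpd_over_masks(dist_sub, obs_mask)[0]) - mpd_rem
        out["MPD"] = _finish(cell, "MPD", "gain", mpd_obs, mpd_reps, cfg)
    return out
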