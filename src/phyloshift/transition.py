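"""Per-cell assemblage transitions and loss/gain decomposition of change.

Between the two time slices each cell's species partition into persisting,
lost (extinction or emigration) and gained (immigration) sets.  Net change
in each metric then splits exactly into a loss component, metric(remaining)
- metric(current), and a gain component, metric(remaining + gained) -
metric(remaining); gains are added on top of the *remaining* set so that
the two components are comparable and telescope to the net change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import MetricValue, PatristicMatrix, PhyloTree, faith_pd, mpd

__all__ = [
    "AssemblageTransition",
    "CellChangeRecord",
    "make_transition",
    "percent_change",
    "decompose_metric_change",
]


@dataclass(frozen=True)
class AssemblageTransition:
    """Partition of one cell's species between two time slices."""

    cell_id: str
    current: frozenset
    future: frozenset
    remaining: frozenset
    lost: frozenset
    gained: frozenset

    @classmethod
    def from_sets(cls, cell_id: str, current, future) -> "AssemblageTransition":
        current = frozenset(current)
        future = frozenset(future)
        return cls(
            cell_id=cell_id,
            current=current,
            future=future,
            remaining=current & future,
            lost=current - future,
            gained=future - current,
        )


def make_transition(
    current_row: np.ndarray,
    future_row: np.ndarray,
    species: tuple[str, ...] | list[str],
    cell_id: str = "",
) -> AssemblageTransition:
    """Build a transition from two aligned 0/1 rows over the same species."""
    current_row = np.asarray(current_row)
    future_row = np.asarray(future_row)
    if current_row.shape != future_row.shape or len(current_row) != len(species):
        raise ValueError(
            f"row length mismatch: current {current_row.shape}, "
            f"future {future_row.shape}, species {len(species)}"
        )
    cur = {s for s, v in zip(species, current_row) if v}
    fut = {s for s, v in zip(species, future_row) if v}
    return AssemblageTransition.from_sets(cell_id, cur, fut)


def percent_change(old, new) -> MetricValue:
    """Proportional change, in percent: 100 * (new - old) / old.

    Undefined (with a reason code) when the baseline is zero or either
    operand is itself undefined.
    """
    if isinstance(old, MetricValue):
        if not old.defined:
            return MetricValue("pct_change", None, defined=False, reason="baseline undefined")
        old = old.value
    if isinstance(new, MetricValue):
        if not new.defined:
            return MetricValue("pct_change", None, defined=False, reason="new value undefined")
        new = new.value
    if old == 0:
        return MetricValue("pct_change", None, defined=False, reason="zero baseline")
    return MetricValue("pct_change", 100.0 * (new - old) / old)


@dataclass(frozen=True)
class CellChangeRecord:
    """Total and decomposed per-cell changes in SR, Faith PD and MPD."""

    cell_id: str
    sr_current: int
    sr_future: int
    n_lost: int
    n_gained: int
    pct_change_sr: MetricValue
    pct_change_pd: MetricValue
    pct_change_mpd: MetricValue
    pd_current: float
    pd_future: float
    loss_delta_pd: MetricValue
    gain_delta_pd: MetricValue
    loss_delta_mpd: MetricValue
    gain_delta_mpd: MetricValue

    def to_row(self) -> dict:
        """Flatten to one CSV row; undefined values become NaN + reason."""
        row: dict = {
            "cell_id": self.cell_id,
            "sr_current": self.sr_current,
            "sr_future": self.sr_future,
            "n_lost": self.n_lost,
            "n_gained": self.n_gained,
            "pd_current": self.pd_current,
            "pd_future": self.pd_future,
        }
        for name, mv in [
            ("pct_change_sr", self.pct_change_sr),
            ("pct_change_pd", self.pct_change_pd),
            ("pct_change_mpd", self.pct_change_mpd),
            ("loss_delta_pd", self.loss_delta_pd),
            ("gain_delta_pd", self.gain_delta_pd),
            ("loss_delta_mpd", self.loss_delta_mpd),
            ("gain_delta_mpd", self.gain_delta_mpd),
        ]:
            row[name] = mv.value if mv.defined else np.nan
            row[name + "_reason"] = mv.reason if not mv.defined else ""
        return row


def _delta(after: MetricValue, before: MetricValue, name: str) -> MetricValue:
    if not (after.defined and before.defined):
        reason = after.reason if not after.defined else before.reason
        return MetricValue(name, None, defined=False, reason=reason)
    return MetricValue(name, after.value - before.value)


def decompose_metric_change(
    tree: PhyloTree, dist: PatristicMatrix, tr: AssemblageTransition
) -> CellChangeRecord:
    """Per-cell totals plus loss/gain components for Faith PD and MPD.

    The components telescope: loss_delta + gain_delta = metric(future) -
    metric(current) whenever all terms are defined, since
    future = remaining + gained.
    """
    pd_cur = faith_pd(tree, tr.current)
    pd_rem = faith_pd(tree, tr.remaining)
    pd_fut = faith_pd(tree, tr.future)
    mpd_cur = mpd(dist, tr.current)
    mpd_rem = mpd(dist, tr.remaining)
    mpd_fut = mpd(dist, tr.future)

    return CellChangeRecord(
        cell_id=tr.cell_id,
        sr_current=len(tr.current),
        sr_future=len(tr.future),
        n_lost=len(tr.lost),
        n_gained=len(tr.gained),
        pct_change_sr=percent_change(len(tr.current), len(tr.future)),
        pct_change_pd=percent_change(pd_cur, pd_fut),
        pct_change_mpd=percent_change(mpd_cur, mpd_fut),
        pd_current=pd_cur.value,
        pd_future=pd_fut.value,
        loss_delta_pd=_delta(pd_rem, pd_cur, "loss_delta_pd"),
        gain_delta_pd=_delta(pd_fut, pd_rem, "gain_delta_pd"),
        loss_delta_mpd=_delta(mpd_rem, mpd_cur, "loss_delta_mpd"),
        gain_delta_mpd=_delta(mpd_fut, mpd_rem, "gain_delta_mpd"),
    )
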