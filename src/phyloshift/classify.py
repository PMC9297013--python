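"""Joint MPD / Faith PD restructuring categories for grid cells.

Cells are placed in the plane of percent change in Faith PD (x) versus
percent change in MPD (y).  Cells in the lowest quantile (default quartile)
of combined change are set aside as ``least_change``; the rest fall into
four quadrants around per-axis centers:

* MPD up, PD down   -> increasing phylogenetic **over_dispersion**
* both down         -> increasing phylogenetic **homogenization**
* MPD down, PD up   -> increasing phylogenetic **clustering**
* both up           -> increasing phylogenetic **diversification**

Centers default to the per-axis medians; a ``zero`` mode uses the origin
instead, reading the category names literally as signs of change.  The
magnitude of "combined change" is not pinned down by the category scheme
itself; this package uses the Euclidean norm of the two axes after
centering on their medians and scaling by their interquartile ranges
(robust and unit-free).  The definition tag travels with the output so
alternative definitions can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassificationConfig", "CATEGORIES", "combined_change", "classify_cells"]

CATEGORIES = (
    "over_dispersion",
    "homogenization",
    "clustering",
    "diversification",
    "least_change",
    "undefined",
)


@dataclass(frozen=True)
class ClassificationConfig:
    threshold_mode: str = "median"  # median | zero
    least_change_fraction: float = 0.25
    combined_tag: str = "iqr_scaled_euclidean"

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("median", "zero"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if not (0.0 <= self.least_change_fraction < 1.0):
            raise ValueError("least-change fraction must be in [0, 1)")


def combined_change(
    pct_pd, pct_mpd, axis_centers: tuple[float, float], axis_scales: tuple[float, float]
) -> np.ndarray | float:
    """Euclidean norm of the centered, scaled (PD, MPD) change vector."""
    c_pd, c_mpd = axis_centers
    s_pd, s_mpd = axis_scales
    return np.hypot(
        (np.asarray(pct_pd, dtype=np.float64) - c_pd) / s_pd,
        (np.asarray(pct_mpd, dtype=np.float64) - c_mpd) / s_mpd,
    )


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75.0, 25.0])
    scale = float(q75 - q25)
    return scale if scale > 0 else 1.0


def classify_cells(records: pd.DataFrame, cfg: ClassificationConfig) -> pd.DataFrame:
    """Assign one restructuring category per cell.

    ``records`` needs columns cell_id, pct_change_pd, pct_change_mpd (NaN
    marks an undefined percent change; such cells come out ``undefined``).
    Returns a copy with ``combined_change`` and ``category`` columns added.
    Ties at the least-change boundary are broken by cell-id order so the
    excluded count is exact.
    """
    out = records.copy()
    pd_chg = out["pct_change_pd"].to_numpy(dtype=np.float64)
    mpd_chg = out["pct_change_mpd"].to_numpy(dtype=np.float64)
    defined = ~(np.isnan(pd_chg) | np.isnan(mpd_chg))
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no cells with defined percent changes on both axes")
    if n_def < 4:
        raise ValueError(f"need >= 4 cells with defined changes, got {n_def}")

    med_pd = float(np.median(pd_chg[defined]))
    med_mpd = float(np.median(mpd_chg[defined]))
    scales = (_iqr(pd_chg[defined]), _iqr(mpd_chg[defined]))
    combined = np.full(len(out), np.nan)
    combined[defined] = combined_change(
        pd_chg[defined], mpd_chg[defined], (med_pd, med_mpd), scales
    )

    category = np.full(len(out), "undefined", dtype=object)

    # least-change exclusion: lowest `fraction` of defined cells, ties by cell id
    k = int(np.floor(cfg.least_change_fraction * n_def))
    def_positions = np.flatnonzero(defined)
    cell_rank = out["cell_id"].astype(str).to_numpy()[def_positions].argsort(kind="stable").argsort()
    order = np.lexsort((cell_rank, combined[def_positions]))
    least = def_positions[order[:k]]
    category[least] = "least_change"

    if cfg.threshold_mode == "median":
        c_pd, c_mpd = med_pd, med_mpd
    else:
        c_pd, c_mpd = 0.0, 0.0

    rest = np.setdiff1d(def_positions, least)
    pd_up = pd_chg[rest] > c_pd
    mpd_up = mpd_chg[rest] > c_mpd
    # a cell exactly at both centers has no direction of change to classify
    centered = (pd_chg[rest] == c_pd) & (mpd_chg[rest] == c_mpd)
    quadrant = np.where(
        mpd_up & ~pd_up,
        "over_dispersion",
        np.where(
            ~mpd_up & ~pd_up,
            "homogenization",
            np.where(~mpd_up & pd_up, "clustering", "diversification"),
        ),
    )
    quadrant = np.where(centered, "least_change", quadrant)
    category[rest] = quadrant

    out["combined_change"] = combined
    out["category"] = category
    out.attrs["combined_tag"] = cfg.combined_tag
    out.attrs["threshold_mode"] = cfg.threshold_mode
    return out
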