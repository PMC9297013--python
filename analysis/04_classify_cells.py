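"""Classify cells into phylogenetic-restructuring categories.

Takes the per-cell change table from 02_assemblage_change.py, excludes the
least-changed quartile of cells (combined PD/MPD change), and splits the
rest by the median of each axis into over-dispersion (MPD up, PD down),
homogenization (both down), clustering (MPD down, PD up) and
diversification (both up).  Writes results/analysis/cell_categories.csv
and prints the category table.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import phyloshift as ps

BASE = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main() -> None:
    changes = pd.read_csv(os.path.join(BASE, "cell_changes.csv"))
    out_df = ps.classify_cells(changes, ps.ClassificationConfig(least_change_fraction=0.25))
    out = os.path.join(BASE, "cell_categories.csv")
    out_df.to_csv(out, index=False)

    counts = out_df["category"].value_counts()
    print(f"{len(out_df)} cells classified (threshold mode: median, grey fraction 0.25)")
    for cat, cnt in counts.items():
        print(f"  {cat:16s} {cnt:5d}  ({100 * cnt / len(out_df):.1f}%)")
    opposite = counts.get("over_dispersion", 0) + counts.get("clustering", 0)
    print(f"PD and MPD move in opposite directions in {100 * opposite / len(out_df):.1f}% "
          "of cells (over-dispersion + clustering)")
    print(f"written to {os.path.relpath(out)}")


if __name__ == "__main__":
    main()
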