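# phyloshift

Assemblage-level phylogenetic change between two gridded projection time
slices: per-cell change in species richness (SR), Faith's phylogenetic
diversity (PD) and mean pairwise distance (MPD), decomposed into the parts
caused by species loss and species gain, tested against randomization null
models, and classified into four phylogenetic-restructuring categories.

It is written for macroecologists working with species distribution model
(SDM) output: a rooted phylogeny (newick) plus two presence–absence
matrices (grid cells × species) for a "current" and a "future" slice.

## What it computes

For the species set *S* of a cell, Faith PD is the total branch length of
the union of root-to-tip paths, PD(S) = Σ<sub>b ∈ spanned(S)</sub> ℓ(b)
(the path to the root is included), and MPD is the mean patristic distance
over unordered pairs, MPD(S) = Σ<sub>i<j</sub> d(i,j) / C(|S|,2).

Between slices, each cell's species partition into persisting
(S<sub>rem</sub>), lost and gained sets, and each metric X's net change
splits exactly into

    ΔX_loss = X(S_rem) − X(S_cur)        (removals)
    ΔX_gain = X(S_rem ∪ S_gain) − X(S_rem)   (additions)
    ΔX_loss + ΔX_gain = X(S_fut) − X(S_cur)

Each observed component is compared to 1000 randomized replicates: the
loss null removes |S<sub>lost</sub>| species uniformly from the current
assemblage; the gain null adds |S<sub>gain</sub>| species drawn from a
dispersal-limited pool (species with an occupied cell within the focal
cell's colonizable radius — the mean over resident species of half their
longest great-circle range diameter, D/2). The observed component's tail
quantile q in the replicate distribution is flagged significant when
q < 0.05 or q > 0.95 (two-sided).

Finally, cells are placed in the plane of percent PD change versus percent
MPD change, the least-changed quartile is set aside, and the rest are split
by the per-axis medians into over-dispersion (MPD↑ PD↓), homogenization
(both ↓), clustering (MPD↓ PD↑) and diversification (both ↑).

A synthetic-data module generates the full input bundle (Yule tree,
lat/lon grid, climate-envelope ranges, several range-shift modes with
optional phylogenetic signal), so every stage can be exercised without
external data. See `docs/methods.md` for models, parameters and caveats.

## Worked example

The `analysis/` scripts run the whole study on synthetic scenarios:

```sh
python analysis/01_simulate_scenarios.py
python analysis/02_assemblage_change.py
python analysis/03_null_models.py
python analysis/04_classify_cells.py
```

`01` writes a random-shift world and a clade-loss world (1600 cells ×
128 species; the clade-loss world contracts a 7-species, phylogenetically
distinct clade by 90%). `02` prints, for the random-shift world:

```
analyzed 1600 cells (0 empty dropped)
mean pct change: SR -2.02%, PD -1.75%, MPD -0.67%
1538 cells lose AND gain species; in 474 of them the net PD change is under
a quarter of the loss component (turnover masked by net change)
```

— i.e. net change hides most turnover, which is why the decomposition
exists. `03` contrasts the null-model outcomes of the two worlds:

```
[random_shift]   FaithPD loss: 392 testable, sig_low 0.036, sig_high 0.054
[clade_loss]     FaithPD loss: 306 testable, sig_low 0.209, sig_high 0.000
```

Random shifts flag close to the nominal rate, while losing a distinct
clade produces a four-to-six-fold excess of cells whose PD loss is
significantly worse than random. `04` prints the category table
(25.0% least change; 24.6% diversification; 24.6% homogenization;
13.2% clustering; 12.6% over-dispersion for this scenario).

The same pipeline runs on your own files through the CLI:

```sh
phyloshift simulate --n-species 64 --seed 7 --out scenario/
phyloshift analyze --tree scenario/tree.nwk --current scenario/current.csv \
    --future scenario/future.csv --reps 1000 --seed 7 --out run/
phyloshift report --out-dir run/
```

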