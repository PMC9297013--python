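# Methods

## Metrics

**Faith PD** of a species set is the summed branch length of the union of
root-to-tip paths. The path to the global root of the input tree is
included — the convention of mainstream community-phylogenetics software,
and the only one that gives a single-species assemblage a defined,
positive PD. An empty set has PD 0 (the degenerate value when a cell loses
everything). **MPD** is the unweighted mean patristic distance over
unordered pairs of distinct species; it is undefined below two species.
Inputs are presence–absence, so no abundance weighting anywhere.
Multifurcations and zero-length branches are accepted; every non-root edge
must carry a length ≥ 0 and tip labels must be unique.

Internally the tree is flattened to a boolean tip-by-edge matrix of
root-path membership, so PD of a subset is a masked sum and a whole batch
of randomized assemblages is one matrix product; patristic distances come
from the same matrix (d(i,j) = depth_i + depth_j − 2·shared). All
arithmetic is float64; observed component deltas are evaluated through the
same batched code path as the null replicates so that a degenerate
(deterministic) null yields exact ties rather than float-noise
asymmetries.

## Transition and decomposition

Cells with an empty current assemblage are dropped (counted and logged):
there is no assemblage to change. For the rest, the species partition into
persisting, lost and gained sets, and each metric's change decomposes as
loss = X(remaining) − X(current), gain = X(remaining ∪ gained) −
X(remaining). Gains are added on top of the *remaining* set, keeping the
two components comparable and making them telescope exactly to the net
change. Percent changes with a zero or undefined baseline are reported
undefined with a machine-readable reason and excluded from classification
for that metric; this avoids infinities the source definitions never
address.

## Null models

Loss: remove |S_lost| species uniformly at random, without replacement,
from the current assemblage, 1000 times (configurable); the species pool
is the focal assemblage itself. Gain: draw |S_gained| species uniformly
from the dispersal-limited candidate pool and add them to the remaining
set. Both metrics are recomputed on the *same* draw, so PD and MPD null
distributions are paired within a cell/component. Replicates are
independent; the same subset may recur.

The observed component is located by the tail quantile
q = (#{r < obs} + ½·#{r = obs}) / n (mid-rank tie rule: a constant null
can never be significant), and flagged `sig_low` / `sig_high` when q falls
below 0.05 or above 0.95 — one quantile read against both tails,
equivalent to a two-sided p-value at 10% nominal rate. No small-sample
(+1) correction is applied; thresholds are configurable. Components are
`untestable`, with a reason code, when there is no loss (gain), when the
gain pool is smaller than the gain count, and for MPD when any replicate
set would drop below two species. Because every replicate removes or adds
the same number of species, the replicate set sizes are constant within a
cell/component, so that last rule reduces to a deterministic size check
performed before sampling.

Randomness: one master seed; per-cell, per-component substreams are keyed
by (seed, crc32(cell id), component), so results are independent of cell
processing order and identical configurations reproduce byte-identical
output files.

## Dispersal pool

A species' dispersal ability is half its longest range diameter D (maximum
pairwise great-circle distance among its occupied cell centroids; 0 for a
single cell). A cell's colonizable radius is the mean dispersal ability of
its *current* residents, and the candidate pool is every species with at
least one occupied centroid within that radius, minus the remaining set.
Two open choices are resolved as follows and exposed as switches: the
occupancy slice defining "occurs within reach" defaults to the current
slice (immigrants must live near the focal cell today), and locally lost
species remain eligible candidates (they occur at distance 0; only the
remaining set is excluded, since gains stack on the remaining species).
Distances are centroid-to-centroid haversine on a 6371 km sphere; no
within-cell extent is added, longitude wrap-around is inherent to the
formula, and the range-diameter scan is a plain O(k²) pass, fine at these
problem sizes.

## Classification

Cells with both percent changes defined are placed in the (ΔPD%, ΔMPD%)
plane. "Combined change" — not pinned down by the category scheme itself —
is defined here as the Euclidean norm after centering each axis on its
median and scaling by its interquartile range (robust and unit-free; IQR 0
falls back to 1); the definition tag travels with the output so
alternatives can be compared. The lowest quartile (configurable fraction)
of combined change is `least_change`, with boundary ties broken by cell-id
order so the excluded count is exact. Remaining cells fall into quadrants
around per-axis centers: the medians by default, or the origin in `zero`
mode (reading the category names literally as signs). "Above" means
strictly greater than the center; a cell exactly at both centers has no
direction of change and is assigned `least_change` regardless of the
quantile — the rule that makes a no-change scenario classify entirely as
least change instead of inventing directions from ties. Cells with an
undefined axis are `undefined`. The six labels partition every analyzed
cell.

## Synthetic data

The generator emulates gridded SDM output — binary occupancy per species
per slice on a 0.5° lat/lon grid — not the SDM machinery itself. Each
species occupies a rectangle: a latitudinal band (optimum + breadth)
crossed with a longitudinal extent, a climate-envelope caricature in which
poleward shifts, trailing-edge loss and leading-edge gain emerge
naturally. Defaults: 128 species on a 40 × 40-cell regional grid (20° ×
20°), latitudinal breadth uniform on 3–8°, longitudinal extent uniform on
30–100% of the grid width, every species occupying strictly more than 10
cells in the current slice (failing species are redrawn), mirroring the
range-size filter applied to real range-map data before modelling. The
tree is a pure-birth (Yule) tree with depth normalized to 1, so metric
magnitudes are comparable across runs. Latitudinal optima can carry
phylogenetic signal s ∈ [0, 1]: a Brownian trait evolved along the tree is
blended with an independent draw (weight s) and mapped through the normal
CDF onto the latitude range.

Shift modes: `random` (i.i.d. sign-symmetric optimum shifts, sd 1.5°),
`uniform_poleward` (shared direction, species-specific magnitude),
`clade_biased_loss` / `clade_biased_gain` (one designated clade contracts
toward its niche centre or expands, by the effect-size fraction; 1.0 means
absent everywhere), and `random_dropout` (each presence independently lost
with probability 0.15, no gains). The designated clade is the most
phylogenetically distinct one of moderate size — among clades holding
roughly 5–25% of the tips, the one with the largest unique branch length
per member — because losing a *distinct* clade removes disproportionate
evolutionary history, whereas a dense recent radiation of the same size is
phylogenetically redundant and its loss looks random. The full scenario
bundle is a pure function of its config, seeds included.

`random_dropout` exists because of a subtlety in calibrating the nulls.
Band-shift losses are phylogenetically random only *on average over
scenarios*: within one fixed scenario the species lost from a cell are the
ones whose range edge crosses it, and with a single shared tree the
per-cell quantiles are mutually dependent, so an i.i.d. uniformity test
over the cells of one shift scenario rejects at well above its nominal
rate even though the marginal distribution is uniform (verified by pooling
cells across many independent scenarios). Per-presence dropout makes each
cell's lost set an exactly uniform draw conditional on its count, which is
the premise a calibration check actually needs; the shift modes remain the
realistic scenarios for everything else.

## Check design and problem sizes

The verification suite uses: a 64-tip tree and 50 random subsets for the
metric oracles (brute-force root-path union and pairwise double loop,
agreement to 1e-9); the full 1600-cell, 128-species scenario for the
telescoping identity; a `random_dropout` scenario thinned to every second
row and column (~360 testable cells, weakening residual dependence between
neighbouring assemblages that share most species) with 500 replicates for
calibration — Kolmogorov–Smirnov statistic under the 5% critical value and
flagged fraction inside the 95% binomial band around 10%; and a family of
three scenario seeds per contraction level (0.3 / 0.6 / 0.9) for the
directional-power check, whose sig_low rates must rise monotonically and
beat the random-shift baseline. `scripts/acceptance.py` recomputes all of
these from scratch from a single seed.

## Limitations

Synthetic ranges are rectangles with a single niche axis; real SDM
projections are patchy, multivariate and spatially autocorrelated in ways
the generator does not imitate, so passing checks demonstrate correctness
and calibration of the *pipeline*, not realism of any particular ecological
conclusion. The phylogeny is treated as fixed and known; there is no
propagation of phylogenetic uncertainty. MPD components are silently
untestable for very small assemblages (by design, with reason codes).
Significance flags are per-cell quantile reads with no multiple-testing
control across cells — the intended use is mapping broad patterns of
non-randomness, not cell-level inference. Neighbouring cells share most of
their species, so flags and quantiles are spatially correlated; any
field-level summary of them should account for that.
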