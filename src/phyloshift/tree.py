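"""Rooted phylogeny container and assemblage-level diversity metrics.

The two metrics used throughout the pipeline are

* **Faith PD** — the total branch length of the union of root-to-tip paths
  of the species in an assemblage.  The path to the global root is included
  (the convention of standard community-phylogenetics software; it is also
  the only convention under which a single-species assemblage has a defined,
  positive PD).  PD of the empty set is 0, the natural degenerate value when
  every species is lost from a cell.
* **MPD** — the unweighted mean patristic (tree-path) distance over all
  unordered pairs of distinct species; undefined for fewer than two species.

The tree is stored as flat arrays: one row of a boolean tip-by-edge matrix
per tip marks the edges on its path to the root, so PD of any subset is a
masked sum and whole batches of randomized assemblages reduce to a single
matrix product (see :func:`pd_over_masks`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PatristicMatrix",
    "MetricValue",
    "faith_pd",
    "mpd",
    "patristic_matrix",
    "pd_over_masks",
    "mpd_over_masks",
]


@dataclass(frozen=True)
class MetricValue:
    """A possibly-undefined assemblage metric value.

    ``defined`` is False when the metric has no value for the given input
    (e.g. MPD of fewer than two species); ``reason`` then carries a short
    machine-readable explanation.
    """

    name: str
    value: float | None
    defined: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.defined and self.value is None:
            raise ValueError(f"{self.name}: defined metric must carry a value")
        if not self.defined and self.value is not None:
            raise ValueError(f"{self.name}: undefined metric must not carry a value")


class TreeValidationError(ValueError):
    """Raised when an input tree violates the rooted-phylogeny invariants."""


class PhyloTree:
    """A rooted, branch-length-bearing phylogeny over a species universe.

    Parameters
    ----------
    dendropy_tree
        A rooted :class:`dendropy.Tree`.  Every non-root edge must carry a
        branch length >= 0; tip labels must be unique; >= 2 tips required.
        Multifurcations and zero-length branches are accepted.
    """

    def __init__(self, dendropy_tree: dendropy.Tree):
        self._dendropy = dendropy_tree
        labels: list[str] = []
        edge_lengths: list[float] = []
        node_edge_index: dict[int, int] = {}
        parent_of: dict[int, int | None] = {}

        root = dendropy_tree.seed_node
        for node in dendropy_tree.preorder_node_iter():
            if node is root:
                parent_of[id(node)] = None
                continue
            length = node.edge.length
            if length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise TreeValidationError(
                    f"edge above node {name!r} has no branch length"
                )
            if length < 0:
                name = node.taxon.label if node.taxon else "<internal>"
                raise TreeValidationError(
                    f"edge above node {name!r} has negative length {length}"
                )
            node_edge_index[id(node)] = len(edge_lengths)
            edge_lengths.append(float(length))
            parent_of[id(node)] = id(node.parent_node)

        tip_paths: list[list[int]] = []
        for leaf in dendropy_tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise TreeValidationError("unlabelled tip encountered")
            labels.append(leaf.taxon.label.strip())
            path = []
            node = leaf
            while node is not root:
                path.append(node_edge_index[id(node)])
                node = node.parent_node
            tip_paths.append(path)

        if len(labels) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")

        self._labels: tuple[str, ...] = tuple(labels)
        self._index = {lb: i for i, lb in enumerate(labels)}
        self._edge_lengths = np.asarray(edge_lengths, dtype=np.float64)
        n_tips, n_edges = len(labels), len(edge_lengths)
        tip_edges = np.zeros((n_tips, n_edges), dtype=bool)
        for i, path in enumerate(tip_paths):
            tip_edges[i, path] = True
        self._tip_edges = tip_edges

    # -- basic accessors ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise TreeValidationError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def edge_lengths(self) -> np.ndarray:
        return self._edge_lengths

    @property
    def tip_edge_matrix(self) -> np.ndarray:
        """Boolean (n_tips, n_edges) matrix of root-path edge membership."""
        return self._tip_edges

    @property
    def total_branch_length(self) -> float:
        return float(self._edge_lengths.sum())

    def as_newick(self) -> str:
        return self._dendropy.as_string(schema="newick").strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dendropy

    def indices_of(self, species) -> np.ndarray:
        """Map species labels to tip indices, preserving iteration order."""
        unknown = sorted(s for s in species if s not in self._index)
        if unknown:
            raise KeyError(f"species not found in tree: {unknown}")
        return np.asarray([self._index[s] for s in species], dtype=np.intp)


@dataclass(frozen=True)
class PatristicMatrix:
    """Symmetric tip-to-tip path-length distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {lb: i for i, lb in enumerate(self.labels)}
        )

    def indices_of(self, species) -> np.ndarray:
        unknown = sorted(s for s in species if s not in self._index)
        if unknown:
            raise KeyError(f"species not found in distance matrix: {unknown}")
        return np.asarray([self._index[s] for s in species], dtype=np.intp)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, indices: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(indices, indices)]


def patristic_matrix(tree: PhyloTree) -> PatristicMatrix:
    """All pairwise tip-to-tip path lengths.

    d(i, j) is the summed length of edges on the path between tips i and j,
    computed as depth_i + depth_j - 2 * (shared root-path length).
    """
    weighted = tree.tip_edge_matrix * tree.edge_lengths  # (n, E)
    depths = weighted.sum(axis=1)
    shared = weighted @ tree.tip_edge_matrix.T
    dist = depths[:, None] + depths[None, :] - 2.0 * shared
    np.fill_diagonal(dist, 0.0)
    # guard against tiny negative round-off
    np.maximum(dist, 0.0, out=dist)
    return PatristicMatrix(labels=tree.tip_labels, values=dist)


def faith_pd(tree: PhyloTree, species) -> MetricValue:
    """Faith PD of a species set (rooted convention; empty set -> 0)."""
    species = set(species)
    if not species:
        return MetricValue("FaithPD", 0.0)
    idx = tree.indices_of(species)
    covered = tree.tip_edge_matrix[idx].any(axis=0)
    return MetricValue("FaithPD", float(tree.edge_lengths[covered].sum()))


def mpd(dist: PatristicMatrix, species) -> MetricValue:
    """Unweighted mean pairwise patristic distance over distinct pairs."""
    species = set(species)
    if len(species) < 2:
        return MetricValue("MPD", None, defined=False, reason="fewer than 2 species")
    idx = dist.indices_of(species)
    sub = dist.submatrix(idx)
    k = len(idx)
    return MetricValue("MPD", float(sub.sum() / (k * (k - 1))))


def pd_over_masks(tree: PhyloTree, tip_indices: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Faith PD for a batch of assemblages over a fixed species pool.

    ``masks`` is (n_reps, len(tip_indices)) boolean membership; each row is
    one assemblage.  Returns an (n_reps,) float array.  Empty rows get 0.
    """
    sub = tree.tip_edge_matrix[tip_indices].astype(np.float32)
    counts = masks.astype(np.float32) @ sub  # edge use counts, exact in f32
    return np.asarray((counts > 0.5) @ tree.edge_lengths, dtype=np.float64)


def mpd_over_masks(dist_sub: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """MPD for a batch of assemblages given the pool's distance submatrix.

    Rows with fewer than two members yield NaN.
    """
    m = masks.astype(np.float64)
    pair_sums = np.einsum("ri,ij,rj->r", m, dist_sub, m)
    k = m.sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, pair_sums / np.where(denom > 0, denom, 1.0), np.nan)
    return out
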