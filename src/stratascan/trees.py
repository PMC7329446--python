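"""Gene trees from ortholog groups and W-haplotype placement classification.

For each ortholog group (four within-species haplotypes, optional congener
species, one outgroup) a distance gene tree is built with neighbor joining
on Jukes–Cantor distances, with node support from a column-resampling
bootstrap.  The tree is read rooted on the outgroup and the placement of
the candidate W haplotype decides the call:

* W_DIVERGENT — one female haplotype falls outside the smallest clade
  containing the other three within-species haplotypes, with the decisive
  bipartition supported above the threshold (recombination between Z and W
  ceased before the congener speciations);
* W_RECENT — both female haplotypes nest inside the within-species clade
  with supported monophyly (suppression after speciation, or incomplete);
* UNRESOLVED — neither pattern reaches the support threshold.

Precomputed trees (e.g. maximum-likelihood trees in Newick with support
values on internal nodes) are accepted directly by ``classify_topology``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "FilteredAlignment",
    "TopologyCall",
    "filter_alignment",
    "jc69_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "root_tree",
    "classify_topology",
    "supports_from_tree",
    "split_key",
]

GAP_CHARS = b"-.?Nn"

W_DIVERGENT = "W_DIVERGENT"
W_RECENT = "W_RECENT"
UNRESOLVED = "UNRESOLVED"
SKIPPED = "SKIPPED"


class AlignmentError(ValueError):
    pass


@dataclass
class FilteredAlignment:
    """Rectangular alignment after gap-column and missing-taxon filtering."""

    taxa: list[str]
    matrix: np.ndarray          # (n_taxa, n_cols) uint8 character codes

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxa")

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]


@dataclass
class TopologyCall:
    gene: str
    call: str
    support: float = float("nan")
    w_label: str | None = None
    w_outside_congeners: bool | None = None


def _to_matrix(sequences: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise AlignmentError("alignment is not rectangular")
    return np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), -1).copy()


def _is_gap(matrix: np.ndarray) -> np.ndarray:
    gap = np.zeros(matrix.shape, dtype=bool)
    for ch in GAP_CHARS:
        gap |= matrix == ch
    return gap


def filter_alignment(
    taxa: Sequence[str],
    sequences: Sequence[str],
    max_col_gap: float = 0.40,
    max_taxon_missing: float = 0.40,
) -> FilteredAlignment:
    """Drop gappy columns, then gappy taxa, then re-check columns once.

    Columns with a gap fraction strictly above ``max_col_gap`` are removed
    first; taxa whose remaining rows are more than ``max_taxon_missing``
    gaps are removed next; surviving columns are filtered one more time.
    """
    if len(taxa) != len(sequences):
        raise AlignmentError("taxa/sequence count mismatch")
    matrix = _to_matrix(sequences)
    taxa = list(taxa)

    def col_filter(m):
        gap_frac = _is_gap(m).mean(axis=0)
        keep = gap_frac <= max_col_gap
        if not keep.any():
            raise AlignmentError("all columns removed by the gap filter")
        return m[:, keep]

    matrix = col_filter(matrix)
    taxon_gap = _is_gap(matrix).mean(axis=1)
    keep_taxa = taxon_gap <= max_taxon_missing
    taxa = [t for t, k in zip(taxa, keep_taxa) if k]
    matrix = matrix[keep_taxa]
    if not taxa:
        raise AlignmentError("all taxa removed by the missing-data filter")
    matrix = col_filter(matrix)
    return FilteredAlignment(taxa, matrix)


def jc69_distance(row1: np.ndarray, row2: np.ndarray) -> float:
    """Jukes–Cantor distance over columns where both rows are non-gap.

    Returns NaN (saturated) when the mismatch fraction reaches 3/4.
    """
    r1 = np.asarray(row1)
    r2 = np.asarray(row2)
    valid = ~(_is_gap(r1[None, :])[0] | _is_gap(r2[None, :])[0])
    n = int(valid.sum())
    if n == 0:
        raise AlignmentError("no comparable columns between rows")
    p = float((r1[valid] != r2[valid]).mean())
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return float(-0.75 * np.log(arg))


def distance_matrix(aln: FilteredAlignment, saturation_cap: float = 0.7499) -> np.ndarray:
    """Pairwise JC69 distance matrix; saturated pairs capped, not NaN."""
    n = len(aln.taxa)
    gaps = _is_gap(aln.matrix)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gaps[i] | gaps[j])
            nv = int(valid.sum())
            if nv == 0:
                raise AlignmentError("no comparable columns between rows")
            p = float((aln.matrix[i, valid] != aln.matrix[j, valid]).mean())
            p = min(p, saturation_cap)
            dm[i, j] = dm[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return dm


def neighbor_joining(dm: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Standard neighbor joining; consistent (exact) on additive matrices."""
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1] or dm.shape[0] != len(labels):
        raise ValueError("distance matrix / label mismatch")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(DistanceMatrix(dm, list(labels)))


def split_key(side: frozenset, all_taxa: frozenset) -> frozenset:
    """Canonical key for an unrooted bipartition: the side not containing
    the lexicographically smallest taxon."""
    ref = min(all_taxa)
    return frozenset(all_taxa - side) if ref in side else frozenset(side)


def _tree_splits(tree: TreeNode, all_taxa: frozenset) -> set[frozenset]:
    """Internal (non-trivial) bipartitions of a tree, canonicalized."""
    splits = set()
    for subset in tree.subsets():
        side = frozenset(subset)
        if 1 < len(side) < len(all_taxa) - 1:
            splits.add(split_key(side, all_taxa))
    return splits


def bootstrap_support(
    aln: FilteredAlignment,
    n_boot: int = 100,
    seed: int | None = None,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap support per bipartition.

    Columns are resampled with replacement, the NJ tree rebuilt and the
    recurrence of every internal bipartition counted.  Keys are canonical
    ``split_key`` frozensets; a 3-taxon alignment has no internal
    bipartitions and yields an empty mapping.
    """
    rng = np.random.default_rng(seed)
    taxa = aln.taxa
    all_taxa = frozenset(taxa)
    n = len(taxa)
    if n < 4:
        return {}
    ncols = aln.n_cols
    gaps = _is_gap(aln.matrix)
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    neq = np.stack([(aln.matrix[i] != aln.matrix[j]) & ~(gaps[i] | gaps[j])
                    for i, j in pair_idx])
    valid = np.stack([~(gaps[i] | gaps[j]) for i, j in pair_idx])
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        draw = rng.integers(0, ncols, size=ncols)
        mult = np.bincount(draw, minlength=ncols).astype(float)
        mism = neq @ mult
        comp = valid @ mult
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(comp > 0, mism / np.maximum(comp, 1), 0.0)
        p = np.minimum(p, 0.7499)
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        dm = np.zeros((n, n))
        for (i, j), dist in zip(pair_idx, d):
            dm[i, j] = dm[j, i] = dist
        tree = nj(DistanceMatrix(dm, taxa))
        for split in _tree_splits(tree, all_taxa):
            counts[split] = counts.get(split, 0) + 1
    return {s: c / n_boot for s, c in counts.items()}


def root_tree(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root the tree on the outgroup's pendant edge (idempotent)."""
    tip = tree.find(outgroup)  # raises MissingNodeError when absent
    return tree.root_at(tip, above=True)


def supports_from_tree(tree: TreeNode) -> dict[frozenset, float]:
    """Bipartition supports read off a tree's internal node labels.

    Numeric internal labels (the Newick support convention) are used;
    values above 1 are interpreted as percentages.
    """
    all_taxa = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, float] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        value = getattr(node, "support", None)
        if value is None and node.name is not None:
            try:
                value = float(node.name)
            except ValueError:
                value = None
        if value is None:
            continue
        if value > 1:
            value = value / 100.0
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_taxa) - 1:
            out[split_key(side, all_taxa)] = float(value)
    return out


def classify_topology(
    tree: TreeNode,
    gene: str = "",
    female_labels: Sequence[str] = ("female_h1", "female_h2"),
    male_labels: Sequence[str] = ("male_h1", "male_h2"),
    outgroup: str = "outgroup",
    congener_labels: Sequence[str] = ("congener1", "congener2"),
    support: Mapping[frozenset, float] | None = None,
    min_support: float = 0.75,
) -> TopologyCall:
    """Classify the W placement in one rooted-on-outgroup gene tree.

    Requires both female haplotypes and at least one male haplotype; genes
    missing a female haplotype are SKIPPED.  ``support`` maps canonical
    bipartitions to support fractions (from ``bootstrap_support`` or
    ``supports_from_tree``); bipartitions not in the mapping default to
    support 1 only when the mapping itself is None (fully trusted tree).
    """
    tips = {t.name for t in tree.tips()}
    females = [f for f in female_labels if f in tips]
    males = [m for m in male_labels if m in tips]
    congeners = [c for c in congener_labels if c in tips]
    if len(females) < 2:
        return TopologyCall(gene, SKIPPED)
    if not males or outgroup not in tips:
        return TopologyCall(gene, SKIPPED)

    all_taxa = frozenset(tips)
    # clades = split sides not containing the outgroup (rooted reading)
    clades = []
    for split in _tree_splits(tree, all_taxa):
        side = split if outgroup not in split else frozenset(all_taxa - split)
        clades.append(side)

    def support_of(side: frozenset) -> float:
        if support is None:
            return 1.0
        return float(support.get(split_key(side, all_taxa), 0.0))

    sv = frozenset(females) | frozenset(males)

    # Supported monophyly of all within-species haplotypes (W included)
    # means the W joined after the congener speciations: the recent pattern
    # pre-empts the divergent test whenever congeners allow the distinction,
    # guarding against long-branch artifacts placing the W basal *inside*
    # a well-supported species clade.
    if congeners:
        for c in clades:
            if c == sv and support_of(c) > min_support:
                return TopologyCall(gene, W_RECENT, support_of(c))

    best: tuple[float, str, frozenset] | None = None
    for f in females:
        others = sv - {f}
        containing = [c for c in clades if others <= c]
        if not containing:
            continue
        minimal = min(containing, key=len)
        if f in minimal:
            continue
        s = support_of(minimal)
        if best is None or s > best[0]:
            best = (s, f, minimal)

    if best is not None and best[0] > min_support:
        s, f, minimal = best
        outside = None
        if congeners:
            with_cong = (sv - {f}) | frozenset(congeners)
            outside = any(with_cong <= c and f not in c for c in clades)
        return TopologyCall(gene, W_DIVERGENT, s, f, outside)

    # recent pattern: within-species haplotypes monophyletic with support
    if not congeners and sv == all_taxa - {outgroup}:
        return TopologyCall(gene, W_RECENT, 1.0)
    for c in clades:
        if c == sv:
            s = support_of(c)
            if s > min_support:
                return TopologyCall(gene, W_RECENT, s)
    return TopologyCall(gene, UNRESOLVED,
                        best[0] if best is not None else float("nan"))
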