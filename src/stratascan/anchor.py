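"""Allelic-scaffold removal, chromosome anchoring and lift-over filtering.

Operates on generic pairwise alignment records (PAF-convention coordinates:
0-based half-open, strand-relative query intervals already projected to the
forward strand of the query).  Three concerns live here:

* dedup — a scaffold whose alignments to a longer scaffold cover more than
  25% of its repeat-masked length at >80% identity is an allelic variant
  (haplotig) and is removed from the non-redundant assembly;
* anchoring — scaffolds are tied to reference chromosomes through tiling
  paths (neighboring alignments with <10 kb gaps on both query and target
  linked into one path; the longest path assigns the chromosome), oriented
  when >70% of aligned bp agree on a direction, discarded when <10% of the
  scaffold aligns, and flagged unlocalized when the longest path disagrees
  with the scaffold's overall alignment placement;
* lift-over QC — genes whose per-gene haplotype-alignment count falls below
  the lower bootstrap 95% confidence bound of the mean count (expected 2
  for fully phased diploid regions) are excluded as likely paralog hits.

Thresholds stated as strict inequalities are honored strictly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlignmentRecord",
    "AnchorAssignment",
    "TilingPath",
    "read_paf",
    "write_paf",
    "find_allelic_scaffolds",
    "discard_low_aligned",
    "build_tiling_paths",
    "assign_orientation",
    "mark_unlocalized",
    "anchor_scaffold",
    "anchor_all",
    "haplotype_coverage_filter",
]

FORWARD = "FORWARD"
REVERSE = "REVERSE"
KEPT_ORIGINAL = "KEPT_ORIGINAL"
UNPLACED = "UNPLACED"


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment interval (PAF mandatory-column equivalent)."""

    query: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    target: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    block_len: int

    def __post_init__(self):
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query interval for {self.query}: "
                             f"{self.qstart}-{self.qend} (len {self.qlen})")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target interval for {self.query}->{self.target}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.block_len <= 0 or not (0 <= self.matches <= self.block_len):
            raise ValueError("matches/block_len inconsistent")

    @property
    def identity(self) -> float:
        return self.matches / self.block_len

    @property
    def q_aligned(self) -> int:
        return self.qend - self.qstart


@dataclass
class TilingPath:
    target: str
    records: list[AlignmentRecord]

    @property
    def aligned_bp(self) -> int:
        return sum(r.q_aligned for r in self.records)

    @property
    def tstart(self) -> int:
        return min(r.tstart for r in self.records)

    @property
    def tend(self) -> int:
        return max(r.tend for r in self.records)


@dataclass
class AnchorAssignment:
    scaffold: str
    chromosome: str        # UNPLACED when dropped / unassignable
    orientation: str | None
    localized: bool
    aligned_fraction: float

    def __post_init__(self):
        if self.chromosome == UNPLACED and self.orientation is not None:
            raise ValueError("orientation defined for unplaced scaffold")


# ---------------------------------------------------------------------------
# PAF I/O
# ---------------------------------------------------------------------------


def read_paf(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs 12 mandatory columns")
            records.append(AlignmentRecord(
                f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                f[5], int(f[6]), int(f[7]), int(f[8]), int(f[9]), int(f[10])))
    return records


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(map(str, (
                r.query, r.qlen, r.qstart, r.qend, r.strand,
                r.target, r.tlen, r.tstart, r.tend, r.matches, r.block_len, 255,
            ))) + "\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(a[0] - b[1], b[0] - a[1], 0)


def _by_query(records: Iterable[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    out: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        out.setdefault(r.query, []).append(r)
    return out


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------


def find_allelic_scaffolds(
    self_alignments: Iterable[AlignmentRecord],
    masked_lengths: Mapping[str, int],
    min_overlap: float = 0.25,
    min_identity: float = 0.80,
) -> set[str]:
    """Scaffolds redundant with a longer scaffold (allelic variants).

    A scaffold is redundant iff, for some strictly longer scaffold (by
    repeat-masked length), the union of its alignment intervals at identity
    strictly above ``min_identity`` covers strictly more than ``min_overlap``
    of its own masked length.  The removal set is computed on the original
    record set, so it does not depend on input order.
    """
    per_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in self_alignments:
        if r.query == r.target or r.identity <= min_identity:
            continue
        for query, target, iv in ((r.query, r.target, (r.qstart, r.qend)),
                                  (r.target, r.query, (r.tstart, r.tend))):
            per_pair.setdefault((query, target), []).append(iv)
    redundant: set[str] = set()
    for (query, target), ivs in per_pair.items():
        if query not in masked_lengths or target not in masked_lengths:
            raise KeyError(f"missing masked length for {query!r} or {target!r}")
        if masked_lengths[target] <= masked_lengths[query]:
            continue
        if masked_lengths[query] <= 0:
            redundant.add(query)
            continue
        if _union_length(ivs) / masked_lengths[query] > min_overlap:
            redundant.add(query)
    return redundant


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def discard_low_aligned(records: Sequence[AlignmentRecord], min_fraction: float = 0.10) -> bool:
    """True = keep the scaffold; drop iff aligned fraction < ``min_fraction``."""
    if not records:
        return False
    qlen = records[0].qlen
    aligned = _union_length([(r.qstart, r.qend) for r in records])
    return aligned / qlen >= min_fraction


def build_tiling_paths(records: Sequence[AlignmentRecord], max_gap: int = 10_000) -> list[TilingPath]:
    """Link neighboring alignments into tiling paths per target chromosome.

    Records are chained (after sorting by target position within each
    chromosome) when both the target gap and the query gap to the previous
    record are strictly below ``max_gap``.
    """
    paths: list[TilingPath] = []
    by_target: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_target.setdefault(r.target, []).append(r)
    for target in sorted(by_target):
        recs = sorted(by_target[target], key=lambda r: (r.tstart, r.tend))
        current: list[AlignmentRecord] = []
        for r in recs:
            if current:
                prev = current[-1]
                tgap = _interval_gap((prev.tstart, prev.tend), (r.tstart, r.tend))
                qgap = _interval_gap((prev.qstart, prev.qend), (r.qstart, r.qend))
                if tgap < max_gap and qgap < max_gap:
                    current.append(r)
                    continue
                paths.append(TilingPath(target, current))
            current = [r]
        if current:
            paths.append(TilingPath(target, current))
    return paths


def assign_orientation(path_records: Sequence[AlignmentRecord], ratio: float = 0.70) -> str:
    """FORWARD/REVERSE when one direction holds > ``ratio`` of aligned bp."""
    fwd = sum(r.q_aligned for r in path_records if r.strand == "+")
    rev = sum(r.q_aligned for r in path_records if r.strand == "-")
    total = fwd + rev
    if total == 0:
        return KEPT_ORIGINAL
    if fwd / total > ratio:
        return FORWARD
    if rev / total > ratio:
        return REVERSE
    return KEPT_ORIGINAL


def mark_unlocalized(
    longest_path: TilingPath,
    all_records: Sequence[AlignmentRecord],
    min_span_overlap: float = 0.50,
) -> bool:
    """True when the longest path agrees with the overall alignment placement.

    Agreement requires (a) the longest path's chromosome to hold the
    majority of the scaffold's total aligned bp, and (b) the path's target
    span to overlap at least ``min_span_overlap`` of the scaffold's overall
    aligned span on that chromosome.
    """
    bp_by_chrom: dict[str, int] = {}
    for r in all_records:
        bp_by_chrom[r.target] = bp_by_chrom.get(r.target, 0) + r.q_aligned
    majority = max(bp_by_chrom, key=lambda c: (bp_by_chrom[c], c))
    if longest_path.target != majority:
        return False
    chrom_recs = [r for r in all_records if r.target == longest_path.target]
    span_s = min(r.tstart for r in chrom_recs)
    span_e = max(r.tend for r in chrom_recs)
    if span_e == span_s:
        return True
    inter = max(0, min(span_e, longest_path.tend) - max(span_s, longest_path.tstart))
    return inter / (span_e - span_s) >= min_span_overlap


def anchor_scaffold(
    records: Sequence[AlignmentRecord],
    max_gap: int = 10_000,
    orient_ratio: float = 0.70,
    min_fraction: float = 0.10,
) -> AnchorAssignment | None:
    """Full anchoring decision for one scaffold's reference alignments.

    Returns None when the scaffold is discarded for low aligned fraction;
    discarded scaffolds never receive an assignment.
    """
    if not records:
        raise ValueError("anchor_scaffold needs at least one record")
    scaffold = records[0].query
    if any(r.query != scaffold for r in records):
        raise ValueError("anchor_scaffold expects records of a single scaffold")
    aligned_fraction = _union_length([(r.qstart, r.qend) for r in records]) / records[0].qlen
    if not discard_low_aligned(records, min_fraction):
        return None
    paths = build_tiling_paths(records, max_gap)
    longest = max(paths, key=lambda p: (p.aligned_bp, p.target))
    orientation = assign_orientation(longest.records, orient_ratio)
    localized = mark_unlocalized(longest, records)
    return AnchorAssignment(scaffold, longest.target, orientation, localized, aligned_fraction)


def anchor_all(records: Iterable[AlignmentRecord], **kwargs) -> dict[str, AnchorAssignment]:
    """Anchor every scaffold with records; discarded scaffolds are omitted."""
    out = {}
    for q, recs in sorted(_by_query(records).items()):
        assignment = anchor_scaffold(recs, **kwargs)
        if assignment is not None:
            out[q] = assignment
    return out


# ---------------------------------------------------------------------------
# lift-over haplotype-coverage filter
# ---------------------------------------------------------------------------


def haplotype_coverage_filter(
    gene_hap_counts: Mapping[str, float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[set[str], float]:
    """Keep genes whose haplotype-alignment count reaches the bootstrap bound.

    Bootstraps the mean haplotype count over genes (``n_boot`` resamples)
    and excludes genes whose count falls strictly below the 2.5th percentile
    of the bootstrap means (the ~1.6x bound in a mostly-diploid gene set).
    Returns (kept genes, lower bound).
    """
    if not gene_hap_counts:
        raise ValueError("empty gene set")
    genes = sorted(gene_hap_counts)
    counts = np.array([gene_hap_counts[g] for g in genes], dtype=float)
    rng = np.random.default_rng(seed)
    means = rng.choice(counts, size=(n_boot, len(counts)), replace=True).mean(axis=1)
    lower = float(np.percentile(means, 2.5))
    kept = {g for g, c in zip(genes, counts) if c >= lower}
    return kept, lower
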