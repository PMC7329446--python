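"""Scaffold and region classification from window statistics.

Turns the windowed log2 F:M coverage and SNP-density ratios into calls per
scaffold, against null envelopes built from autosomes only:

* Z_DIVERGED (old-stratum signature) — female coverage deficit: scaffold
  mean log2 coverage ratio below the autosomal bootstrap CI *and*
  permutation-significant (females keep a single Z copy; the diverged W
  reads no longer map);
* RECENT_SDR (young-stratum signature) — near-equal coverage but a
  permutation-significant excess of female SNP density (W-specific
  polymorphism accumulating before divergence reduces mapping);
* W_SPECIFIC — female-only scaffolds: excess log2 F:M coverage over the
  *entire* scaffold length (every smoothed window above the CI), after
  excluding scaffolds whose normalized female coverage is below 10% of the
  genome average (unmappably repeat-dense candidates);
* AUTOSOMAL_LIKE / LOW_COVERAGE_EXCLUDED otherwise.

Scaffold significance requires both the CI breach and a scaffold-vs-
autosome permutation test at alpha = 0.05, which keeps the per-scaffold
false-positive rate at or below the permutation level.  Strata are then
delimited on scaffolds ordered along the anchored sex chromosome, with
window-level refinement for Z-W chimeric scaffolds, and W degeneration is
quantified by repeat enrichment (rank-sum tests) and by gene-loss calls
from translated-search records (80% query-coverage rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .winstats import (
    CIEnvelope,
    moving_average,
    permutation_null_means,
    permutation_pvalue,
)

__all__ = [
    "RegionCall",
    "StratumSegment",
    "GeneLossCall",
    "TranslatedHit",
    "classify_scaffold",
    "classify_scaffolds",
    "detect_w_scaffolds",
    "delimit_sdr",
    "repeat_enrichment_test",
    "repeat_fraction_per_window",
    "infer_gene_loss",
]

AUTOSOMAL_LIKE = "AUTOSOMAL_LIKE"
Z_DIVERGED = "Z_DIVERGED"
RECENT_SDR = "RECENT_SDR"
W_SPECIFIC = "W_SPECIFIC"
LOW_COVERAGE_EXCLUDED = "LOW_COVERAGE_EXCLUDED"


@dataclass
class RegionCall:
    scaffold: str
    call: str
    mean_log2_cov: float
    mean_log2_snp: float
    cov_low: bool = False
    cov_high: bool = False
    snp_high: bool = False
    p_cov_less: float = float("nan")
    p_cov_greater: float = float("nan")
    p_snp_greater: float = float("nan")


@dataclass
class StratumSegment:
    stratum: str                   # "I" or "II"
    start: int                     # bp on the anchored sex chromosome
    end: int
    scaffolds: tuple[str, ...]

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranslatedHit:
    """One translated-search alignment of a protein query to a scaffold."""

    query: str
    target: str
    query_coverage: float
    identity: float = float("nan")
    n_disruptions: int = 0

    def __post_init__(self):
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query coverage must lie in [0, 1]")
        if self.n_disruptions < 0:
            raise ValueError("disruption count must be non-negative")


@dataclass(frozen=True)
class GeneLossCall:
    gene: str
    status: str                    # PRESENT | PSEUDOGENIZED | NOT_RECOVERED
    query_coverage: float
    disruptions: int


def _scaffold_means(df: pd.DataFrame) -> tuple[float, float, np.ndarray, np.ndarray]:
    cov = df["log2_cov"].to_numpy(dtype=float)
    snp = df["log2_snp"].to_numpy(dtype=float)
    cov = cov[np.isfinite(cov)]
    snp = snp[np.isfinite(snp)]
    mean_cov = float(cov.mean()) if len(cov) else float("nan")
    mean_snp = float(snp.mean()) if len(snp) else float("nan")
    return mean_cov, mean_snp, cov, snp


def classify_scaffold(
    scaffold_windows: pd.DataFrame,
    cov_ci: CIEnvelope,
    snp_ci: CIEnvelope,
    null_cov: np.ndarray,
    null_snp: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    _null_cov_sorted: np.ndarray | None = None,
    _null_snp_sorted: np.ndarray | None = None,
) -> RegionCall:
    """Decision-table call for one scaffold from its window statistics.

    ``null_cov``/``null_snp`` are the autosomal window pools (sex chromosome
    excluded) used for both the permutation tests and, upstream, the CIs.
    Precomputed sorted permutation-mean distributions may be supplied to
    amortize the permutation cost across scaffolds of equal window count.
    """
    if cov_ci is None or snp_ci is None:
        raise ValueError("confidence envelopes are required")
    scaffold = str(scaffold_windows["scaffold"].iloc[0])
    mean_cov, mean_snp, cov, snp = _scaffold_means(scaffold_windows)
    if len(cov) == 0:
        raise ValueError(f"scaffold {scaffold!r} has no defined windows")

    if _null_cov_sorted is None:
        _null_cov_sorted = permutation_null_means(null_cov, len(cov), n_perm, seed)
    p_cov_less = permutation_pvalue(mean_cov, _null_cov_sorted, "less")
    p_cov_greater = permutation_pvalue(mean_cov, _null_cov_sorted, "greater")
    cov_low = mean_cov < cov_ci.lower and p_cov_less < alpha
    cov_high = mean_cov > cov_ci.upper and p_cov_greater < alpha

    snp_high = False
    p_snp_greater = float("nan")
    if len(snp):
        if _null_snp_sorted is None:
            _null_snp_sorted = permutation_null_means(null_snp, len(snp), n_perm, seed)
        p_snp_greater = permutation_pvalue(mean_snp, _null_snp_sorted, "greater")
        snp_high = mean_snp > snp_ci.upper and p_snp_greater < alpha

    if cov_low:
        call = Z_DIVERGED
    elif snp_high and not cov_high:
        call = RECENT_SDR
    else:
        call = AUTOSOMAL_LIKE
    return RegionCall(scaffold, call, mean_cov, mean_snp, cov_low, cov_high,
                      snp_high, p_cov_less, p_cov_greater, p_snp_greater)


def classify_scaffolds(
    windows: pd.DataFrame,
    autosome_scaffolds: Sequence[str],
    n_boot: int = 1000,
    block: int = 25,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    w_floor: float = 0.10,
    smooth: int = 25,
) -> dict[str, RegionCall]:
    """Classify every scaffold in a window table.

    ``autosome_scaffolds`` defines the null class and must exclude the sex
    chromosome entirely, including the pseudo-autosomal region.  W-specific
    detection runs first (whole-scaffold coverage excess / low-coverage
    exclusion); remaining scaffolds go through the decision table.
    Permutation null distributions are cached per target window count — the
    pool and statistic are identical across scaffolds of equal size.
    """
    from .winstats import bootstrap_ci

    auto = windows[windows["scaffold"].isin(set(autosome_scaffolds))]
    if auto.empty:
        raise ValueError("no autosomal windows available for the null class")
    null_cov = auto["log2_cov"].to_numpy(dtype=float)
    null_snp = auto["log2_snp"].to_numpy(dtype=float)
    cov_ci = bootstrap_ci(null_cov, n_boot, block, seed=seed)
    snp_ci = bootstrap_ci(null_snp, n_boot, block, seed=None if seed is None else seed + 1)

    w_calls = detect_w_scaffolds(windows, cov_ci, w_floor=w_floor, smooth=smooth)

    cov_cache: dict[int, np.ndarray] = {}
    snp_cache: dict[int, np.ndarray] = {}
    calls: dict[str, RegionCall] = {}
    for i, (scaffold, df) in enumerate(windows.groupby("scaffold", sort=True)):
        if scaffold in w_calls:
            mean_cov, mean_snp, _, _ = _scaffold_means(df)
            calls[scaffold] = RegionCall(scaffold, w_calls[scaffold], mean_cov, mean_snp)
            continue
        k_cov = int(np.isfinite(df["log2_cov"].to_numpy(dtype=float)).sum())
        k_snp = int(np.isfinite(df["log2_snp"].to_numpy(dtype=float)).sum())
        if k_cov not in cov_cache:
            cov_cache[k_cov] = permutation_null_means(
                null_cov, k_cov, n_perm, None if seed is None else seed + 100 + k_cov)
        if k_snp > 0 and k_snp not in snp_cache:
            snp_cache[k_snp] = permutation_null_means(
                null_snp, k_snp, n_perm, None if seed is None else seed + 200 + k_snp)
        calls[scaffold] = classify_scaffold(
            df, cov_ci, snp_ci, null_cov, null_snp, n_perm, seed, alpha,
            _null_cov_sorted=cov_cache[k_cov],
            _null_snp_sorted=snp_cache.get(k_snp),
        )
    return calls


def detect_w_scaffolds(
    windows: pd.DataFrame,
    cov_ci: CIEnvelope,
    w_floor: float = 0.10,
    smooth: int = 25,
) -> dict[str, str]:
    """W-specific / low-coverage calls per scaffold.

    Scaffolds whose normalized female coverage is below ``w_floor`` of the
    genome average are excluded (likely highly repetitive, unmappable).  A
    remaining scaffold is W-specific iff its scaffold-level log2 F:M
    coverage exceeds the autosomal CI upper bound and the excess holds over
    the entire scaffold length: every smoothed window above the bound.
    """
    out: dict[str, str] = {}
    for scaffold, df in windows.groupby("scaffold", sort=True):
        f_norm = float(df["cov_f_norm"].mean())
        if f_norm < w_floor:
            out[str(scaffold)] = LOW_COVERAGE_EXCLUDED
            continue
        mean_cov, _, cov, _ = _scaffold_means(df)
        if not len(cov) or not (mean_cov > cov_ci.upper):
            continue
        smoothed = moving_average(df["log2_cov"].to_numpy(dtype=float), smooth)
        smoothed = smoothed[np.isfinite(smoothed)]
        if len(smoothed) and (smoothed > cov_ci.upper).all():
            out[str(scaffold)] = W_SPECIFIC
    return out


def delimit_sdr(
    anchored_order: Sequence[str],
    calls: Mapping[str, RegionCall],
    windows: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    window_null_quantiles: tuple[float, float] | None = None,
    window: int = 10_000,
    min_run: int = 2,
) -> list[StratumSegment]:
    """Strata segments along the anchored sex chromosome.

    ``anchored_order`` lists the sex-chromosome scaffolds in chromosome
    order (scaffolds without an anchor are the caller's problem and are
    simply not passed).  Z_DIVERGED scaffolds contribute stratum I,
    RECENT_SDR scaffolds stratum II; adjacent segments of the same stratum
    merge.  When window-level null quantiles for log2 coverage are given,
    Z_DIVERGED scaffolds are refined to the runs of windows below the lower
    quantile (at least ``min_run`` windows), which trims W-chimeric
    insertions out of stratum I.
    """
    segments: list[StratumSegment] = []
    offset = 0
    for scaffold in anchored_order:
        if scaffold not in scaffold_lengths:
            raise KeyError(f"no length for anchored scaffold {scaffold!r}")
        length = scaffold_lengths[scaffold]
        call = calls.get(scaffold)
        if call is None:
            offset += length
            continue
        if call.call == Z_DIVERGED:
            if window_null_quantiles is not None:
                df = windows[windows["scaffold"] == scaffold].sort_values("start")
                vals = df["log2_cov"].to_numpy(dtype=float)
                below = np.isfinite(vals) & (vals < window_null_quantiles[0])
                for run_start, run_end in _runs(below, min_run):
                    seg_s = offset + int(df["start"].iloc[run_start])
                    seg_e = offset + int(df["end"].iloc[run_end - 1])
                    segments.append(StratumSegment("I", seg_s, seg_e, (scaffold,)))
            else:
                segments.append(StratumSegment("I", offset, offset + length, (scaffold,)))
        elif call.call == RECENT_SDR:
            segments.append(StratumSegment("II", offset, offset + length, (scaffold,)))
        offset += length
    return _merge_segments(segments)


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    return runs


def _merge_segments(segments: list[StratumSegment]) -> list[StratumSegment]:
    merged: list[StratumSegment] = []
    for seg in sorted(segments, key=lambda s: s.start):
        if merged and merged[-1].stratum == seg.stratum and merged[-1].end == seg.start:
            prev = merged.pop()
            merged.append(StratumSegment(prev.stratum, prev.start, seg.end,
                                         prev.scaffolds + seg.scaffolds))
        else:
            merged.append(seg)
    return merged


def repeat_fraction_per_window(
    intervals: np.ndarray | Sequence[tuple[int, int]],
    length: int,
    window: int = 10_000,
) -> np.ndarray:
    """Fraction of each non-overlapping window covered by repeat intervals."""
    cov = np.zeros(length + 1, dtype=np.int64)
    for s, e in np.asarray(intervals).reshape(-1, 2):
        cov[max(0, int(s))] += 1
        cov[min(length, int(e))] -= 1
    per_site = np.cumsum(cov[:-1]) > 0
    edges = np.arange(0, length + window, window)
    edges[-1] = min(edges[-1], length)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    sums = np.add.reduceat(per_site.astype(float), edges[:-1])
    return sums / np.diff(edges)


def repeat_enrichment_test(
    w_fractions: Sequence[float],
    z_sdr_fractions: Sequence[float],
    genome_fractions: Sequence[float],
) -> dict[str, float]:
    """One-sided rank-sum tests of repeat density: W above genome, W above Z-SDR."""
    w = np.asarray(w_fractions, dtype=float)
    z = np.asarray(z_sdr_fractions, dtype=float)
    g = np.asarray(genome_fractions, dtype=float)
    if len(w) == 0 or len(z) == 0 or len(g) == 0:
        raise ValueError("repeat enrichment test needs non-empty groups")
    p_genome = float(stats.mannwhitneyu(w, g, alternative="greater").pvalue)
    p_zsdr = float(stats.mannwhitneyu(w, z, alternative="greater").pvalue)
    return {"p_w_vs_genome": p_genome, "p_w_vs_zsdr": p_zsdr,
            "median_w": float(np.median(w)), "median_genome": float(np.median(g)),
            "median_zsdr": float(np.median(z))}


def infer_gene_loss(
    gene: str,
    hits: Sequence[TranslatedHit],
    min_qcov: float = 0.80,
) -> GeneLossCall:
    """Gene-loss call from translated-search records against the homolog.

    The best hit (highest query coverage) decides: PSEUDOGENIZED when it
    covers at least ``min_qcov`` of the protein with one or more frame
    disruptions (premature stops / frameshifts), PRESENT when it covers
    that much cleanly, NOT_RECOVERED otherwise.
    """
    if not hits:
        return GeneLossCall(gene, "NOT_RECOVERED", 0.0, 0)
    best = max(hits, key=lambda h: (h.query_coverage, -h.n_disruptions))
    if best.query_coverage >= min_qcov:
        status = "PSEUDOGENIZED" if best.n_disruptions >= 1 else "PRESENT"
    else:
        status = "NOT_RECOVERED"
    return GeneLossCall(gene, status, best.query_coverage, best.n_disruptions)
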