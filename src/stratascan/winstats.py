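"""Windowed coverage and SNP-density statistics from per-site nucleotide profiles.

This module implements the window-scan layer of the sex-linked region
analysis: per-site A/C/G/T read-count profiles from one female and one male
sample are summarized in non-overlapping windows (default 10 kb) as mean
read depth and SNP density, each normalized by the individual's genome-wide
median, and contrasted between the sexes as log2 F:M ratios (with a small
pseudocount to avoid log of zero).  Null envelopes for those ratios come
from a block bootstrap over autosomal windows, and scaffold-level deviations
are scored with permutation tests against the autosomal window pool.

Profiles are 1-based position tables (``scaffold  pos  A  C  G  T``);
windows are 0-based half-open internally and in all written output.
Positions absent from a profile are implicitly depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteProfile",
    "SiteCall",
    "CIEnvelope",
    "ProfileParseError",
    "read_profiles",
    "load_profile_counts",
    "call_snps",
    "call_snps_counts",
    "snp_density",
    "window_coverage",
    "window_table",
    "scaffold_window_stats",
    "add_ratio_columns",
    "normalize",
    "log2_ratio",
    "moving_average",
    "bootstrap_ci",
    "permutation_null_means",
    "permutation_pvalue",
    "permutation_test",
]

BASES = "ACGT"
DEFAULT_WINDOW = 10_000
DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_MAF = 0.30
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class SiteProfile:
    """One profiled site: scaffold, 1-based position and A/C/G/T read counts."""

    scaffold: str
    pos: int
    counts: tuple[int, int, int, int]


class SiteCall(Enum):
    SNP = "SNP"
    NOT_SNP = "NOT_SNP"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class CIEnvelope:
    """Percentile bootstrap confidence interval for a mean of blocked windows."""

    lower: float
    upper: float
    n_boot: int
    block: int
    seed: int | None = None

    def __post_init__(self):
        if self.upper < self.lower:
            raise ValueError("CI upper bound below lower bound")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


class ProfileParseError(ValueError):
    """Malformed profile line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def read_profiles(path) -> Iterator[SiteProfile]:
    """Stream ``scaffold pos A C G T`` records from a tab-separated file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ProfileParseError(path, lineno, f"expected 6 columns, got {len(fields)}")
            scaffold = fields[0]
            try:
                pos = int(fields[1])
                counts = tuple(int(x) for x in fields[2:6])
            except ValueError as exc:
                raise ProfileParseError(path, lineno, f"non-integer field: {exc}") from None
            if pos < 1:
                raise ProfileParseError(path, lineno, f"position must be >= 1, got {pos}")
            if any(c < 0 for c in counts):
                raise ProfileParseError(path, lineno, f"negative count in {counts}")
            yield SiteProfile(scaffold, pos, counts)  # type: ignore[arg-type]


def load_profile_counts(path, scaffold_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Load a profile file into dense per-scaffold ``(length, 4)`` count arrays.

    Positions not present in the file are depth 0.  A position beyond the
    declared scaffold length is an error, as is an undeclared scaffold.
    """
    counts: dict[str, np.ndarray] = {}
    for rec in read_profiles(path):
        if rec.scaffold not in scaffold_lengths:
            raise ValueError(f"scaffold {rec.scaffold!r} not in scaffold lengths")
        length = scaffold_lengths[rec.scaffold]
        if rec.pos > length:
            raise ValueError(
                f"position {rec.pos} exceeds length {length} of scaffold {rec.scaffold!r}"
            )
        arr = counts.setdefault(rec.scaffold, np.zeros((length, 4), dtype=np.int64))
        arr[rec.pos - 1] = rec.counts
    for name, length in scaffold_lengths.items():
        counts.setdefault(name, np.zeros((length, 4), dtype=np.int64))
    return counts


def call_snps(counts: Sequence[int], min_depth: int = DEFAULT_MIN_DEPTH,
              min_maf: float = DEFAULT_MIN_MAF) -> SiteCall:
    """Classify one site from its four base counts.

    EXCLUDED below the depth threshold; SNP iff the site is bi-allelic
    (exactly two bases with non-zero counts) with minor allele frequency at
    or above ``min_maf``; NOT_SNP otherwise.
    """
    c = np.asarray(counts)
    if c.shape != (4,) or (c < 0).any():
        raise ValueError("counts must be four non-negative integers")
    depth = int(c.sum())
    if depth < min_depth:
        return SiteCall.EXCLUDED
    nonzero = c[c > 0]
    if len(nonzero) == 2 and nonzero.min() / depth >= min_maf:
        return SiteCall.SNP
    return SiteCall.NOT_SNP


def call_snps_counts(counts: np.ndarray, min_depth: int = DEFAULT_MIN_DEPTH,
                     min_maf: float = DEFAULT_MIN_MAF) -> np.ndarray:
    """Vectorized site calls for an ``(n, 4)`` count matrix.

    Returns int8 codes: 1 = SNP, 0 = NOT_SNP, -1 = EXCLUDED.
    """
    counts = np.asarray(counts)
    depth = counts.sum(axis=1)
    n_alleles = (counts > 0).sum(axis=1)
    minor = np.where(n_alleles == 2, depth - counts.max(axis=1), 0)
    out = np.zeros(len(counts), dtype=np.int8)
    out[depth < min_depth] = -1
    is_snp = (depth >= min_depth) & (n_alleles == 2) & (minor >= min_maf * depth)
    out[is_snp] = 1
    return out


def snp_density(n_snps: int, n_passing: int) -> float:
    """SNPs per site passing the depth threshold; NaN when no site passes."""
    if n_passing < 0 or n_snps < 0 or n_snps > max(n_passing, 0):
        raise ValueError("inconsistent SNP/passing-site counts")
    if n_passing == 0:
        return float("nan")
    return n_snps / n_passing


def _window_edges(length: int, window: int) -> np.ndarray:
    if length <= 0 or window <= 0:
        raise ValueError("length and window must be positive")
    edges = np.arange(0, length + window, window)
    edges[-1] = min(edges[-1], length)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    return edges


def _window_means(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    sums = np.add.reduceat(values.astype(float), edges[:-1])
    sizes = np.diff(edges)
    return sums / sizes


def _window_sums(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values.astype(np.int64), edges[:-1])


def window_coverage(depth: np.ndarray, length: int, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Mean per-site depth in non-overlapping windows for one scaffold.

    ``depth`` is the dense per-site depth vector (absent sites already 0).
    The trailing partial window is kept with its true size.
    """
    depth = np.asarray(depth)
    if len(depth) != length:
        raise ValueError("depth vector length does not match scaffold length")
    edges = _window_edges(length, window)
    return pd.DataFrame(
        {"start": edges[:-1], "end": edges[1:], "cov": _window_means(depth, edges)}
    )


def scaffold_window_stats(
    scaffold: str,
    length: int,
    depth_f: np.ndarray,
    snp_f: np.ndarray,
    pass_f: np.ndarray,
    depth_m: np.ndarray,
    snp_m: np.ndarray,
    pass_m: np.ndarray,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-window raw statistics for one scaffold from per-site vectors.

    ``snp_*`` and ``pass_*`` are boolean per-site vectors (SNP called; depth
    threshold passed).  Densities are NaN where no site passes.
    """
    for v in (depth_f, snp_f, pass_f, depth_m, snp_m, pass_m):
        if len(v) != length:
            raise ValueError("per-site vector length mismatch")
    edges = _window_edges(length, window)
    n_f = _window_sums(np.asarray(snp_f, dtype=np.int64), edges)
    p_f = _window_sums(np.asarray(pass_f, dtype=np.int64), edges)
    n_m = _window_sums(np.asarray(snp_m, dtype=np.int64), edges)
    p_m = _window_sums(np.asarray(pass_m, dtype=np.int64), edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens_f = np.where(p_f > 0, n_f / np.maximum(p_f, 1), np.nan)
        dens_m = np.where(p_m > 0, n_m / np.maximum(p_m, 1), np.nan)
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "start": edges[:-1],
            "end": edges[1:],
            "cov_f": _window_means(np.asarray(depth_f), edges),
            "cov_m": _window_means(np.asarray(depth_m), edges),
            "snp_f": n_f,
            "snp_m": n_m,
            "sites_pass_f": p_f,
            "sites_pass_m": p_m,
            "dens_f": dens_f,
            "dens_m": dens_m,
        }
    )


def window_table(
    counts_f: Mapping[str, np.ndarray],
    counts_m: Mapping[str, np.ndarray],
    scaffold_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_maf: float = DEFAULT_MIN_MAF,
) -> pd.DataFrame:
    """Full window table from dense ``(L, 4)`` count matrices per scaffold."""
    frames = []
    for name in scaffold_lengths:
        length = scaffold_lengths[name]
        cf = counts_f[name]
        cm = counts_m[name]
        calls_f = call_snps_counts(cf, min_depth, min_maf)
        calls_m = call_snps_counts(cm, min_depth, min_maf)
        frames.append(
            scaffold_window_stats(
                name, length,
                cf.sum(axis=1), calls_f == 1, calls_f >= 0,
                cm.sum(axis=1), calls_m == 1, calls_m >= 0,
                window=window,
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return add_ratio_columns(df)


def normalize(values, pseudo_median_check: bool = True) -> np.ndarray:
    """Divide values by their median (NaNs ignored); median must be positive."""
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).all():
        raise ValueError("cannot normalize: no defined values")
    med = np.nanmedian(arr)
    if med <= 0:
        raise ValueError(
            "median of values is zero; inspect the input profiles (all-zero "
            "coverage or densities cannot be normalized)"
        )
    return arr / med


def log2_ratio(f_norm, m_norm, pseudo: float = DEFAULT_PSEUDOCOUNT):
    """log2 of (f + pseudo)/(m + pseudo); antisymmetric under swapping f and m."""
    f = np.asarray(f_norm, dtype=float)
    m = np.asarray(m_norm, dtype=float)
    if np.nanmin(f, initial=0.0) < 0 or np.nanmin(m, initial=0.0) < 0:
        raise ValueError("normalized values must be non-negative")
    out = np.log2((f + pseudo) / (m + pseudo))
    return float(out) if out.ndim == 0 else out


def add_ratio_columns(df: pd.DataFrame, pseudo: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Add normalized coverage/density columns and log2 F:M ratio columns.

    Coverage and SNP density are normalized per individual by the genome-wide
    median window value before the pseudocounted log2 ratio is taken.
    """
    df = df.copy()
    df["cov_f_norm"] = normalize(df["cov_f"])
    df["cov_m_norm"] = normalize(df["cov_m"])
    df["dens_f_norm"] = normalize(df["dens_f"])
    df["dens_m_norm"] = normalize(df["dens_m"])
    df["log2_cov"] = log2_ratio(df["cov_f_norm"], df["cov_m_norm"], pseudo)
    df["log2_snp"] = log2_ratio(df["dens_f_norm"], df["dens_m_norm"], pseudo)
    return df


def moving_average(series, k: int = 25) -> np.ndarray:
    """Centered moving average with truncated edges; NaNs are skipped.

    The half-width is ``k // 2``; an even ``k`` therefore behaves like
    ``k + 1``.  Positions whose whole neighborhood is NaN stay NaN.
    """
    if k < 1:
        raise ValueError("window size k must be >= 1")
    x = np.asarray(series, dtype=float)
    h = k // 2
    valid = np.isfinite(x)
    vals = np.where(valid, x, 0.0)
    kernel = np.ones(2 * h + 1)
    sums = np.convolve(vals, kernel, mode="same")
    ns = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ns > 0, sums / ns, np.nan)
    return out


def bootstrap_ci(
    values,
    n_boot: int = 1000,
    block: int = 25,
    level: float = 0.95,
    seed: int | None = None,
) -> CIEnvelope:
    """Percentile bootstrap CI for the mean of random blocks of windows.

    Draws ``n_boot`` sets of ``block`` window values with replacement, takes
    each set's mean and returns the central ``level`` percentile envelope of
    those means.  The caller must pass autosomal windows only (the sex
    chromosome, including its pseudo-autosomal region, is excluded upstream).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < block:
        raise ValueError(f"need at least {block} defined window values, got {len(arr)}")
    rng = np.random.default_rng(seed)
    draws = rng.choice(arr, size=(n_boot, block), replace=True)
    means = draws.mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return CIEnvelope(float(lo), float(hi), n_boot, block, seed)


def permutation_null_means(
    null_values,
    k: int,
    n_perm: int = 10_000,
    seed: int | None = None,
    _chunk: int = 2000,
) -> np.ndarray:
    """Sorted means of ``n_perm`` draws of ``k`` null values without replacement."""
    pool = np.asarray(null_values, dtype=float)
    pool = pool[np.isfinite(pool)]
    n = len(pool)
    if k < 1:
        raise ValueError("target size must be >= 1")
    if n < k:
        raise ValueError(f"null pool ({n}) smaller than target size ({k})")
    rng = np.random.default_rng(seed)
    means = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(_chunk, n_perm - done)
        # random k-subsets per row via partial argsort of uniform keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        means[done:done + m] = pool[idx].mean(axis=1)
        done += m
    means.sort()
    return means


def permutation_pvalue(observed: float, sorted_null_means: np.ndarray, side: str) -> float:
    """Add-one permutation p-value from a precomputed sorted null distribution."""
    n_perm = len(sorted_null_means)
    if side == "greater":
        n_extreme = n_perm - np.searchsorted(sorted_null_means, observed, side="left")
    elif side == "less":
        n_extreme = np.searchsorted(sorted_null_means, observed, side="right")
    else:
        raise ValueError("side must be 'greater' or 'less'")
    return (1 + int(n_extreme)) / (1 + n_perm)


def permutation_test(
    target_values,
    null_values,
    n_perm: int = 10_000,
    side: str = "greater",
    seed: int | None = None,
) -> float:
    """One-sided permutation test of mean(target) against the autosomal pool.

    Each permutation draws ``len(target)`` values from the null pool without
    replacement; the p-value uses the add-one estimator so it is never 0
    (minimum 1/(n_perm+1)).  Ties count as as-or-more extreme.
    """
    target = np.asarray(target_values, dtype=float)
    target = target[np.isfinite(target)]
    if len(target) == 0:
        raise ValueError("target is empty (no defined window values)")
    null_sorted = permutation_null_means(null_values, len(target), n_perm, seed)
    return permutation_pvalue(float(target.mean()), null_sorted, side)


def write_window_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
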