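"""Synonymous/non-synonymous divergence between gametolog haplotype pairs.

Two estimators are provided for pairwise coding-sequence divergence:

* ``ng86_estimate`` — Nei–Gojobori-style counting: synonymous and
  non-synonymous sites per codon (mutations to stop codons excluded,
  remaining opportunities renormalized to 3 per codon), observed differences
  averaged over equally weighted minimal mutation pathways, and a
  Jukes–Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3).

* ``yn00_estimate`` — an approximate Yang–Nielsen (2000)-style method:
  codon frequencies from the pair (F3x4), transition/transversion ratio
  kappa estimated from fourfold-degenerate and nondegenerate sites with a
  Kimura two-parameter correction, kappa- and frequency-weighted site
  counting, likelihood-weighted mutation pathways, K80-style distance
  correction applied separately at synonymous and non-synonymous sites, and
  iteration of the dN/dS ratio used in the pathway weights until convergence.

Both estimators share the convention that with kappa = 1 and uniform codon
frequencies the weighted site counts reduce exactly to the NG86 counts.
Saturation (undefined distance) is reported as a flag, not an exception.

The module also houses the upstream QC of coding sequences (valid ATG start,
no internal stop, >= 120 nt, triplet length) and the downstream region-level
comparison of per-gene estimates (Mann–Whitney U against the genome
background), with the dS > 0.2 ortholog-misassignment filter in between.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CodonAlignment",
    "DnDsEstimate",
    "QCResult",
    "qc_cds",
    "prepare_pair",
    "ng86_sites",
    "ng86_estimate",
    "yn00_estimate",
    "filter_ds",
    "compare_regions",
    "jc_correction",
]

NT = "TCAG"
NT_INDEX = {b: i for i, b in enumerate(NT)}
CODONS = ["".join(c) for c in itertools.product(NT, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
AA = np.array([_CODE[c] for c in CODONS])
IS_STOP = AA == "*"
SENSE = np.flatnonzero(~IS_STOP)
STOPS = {"TAA", "TAG", "TGA"}

_TS_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in _TS_PAIRS


# Per-codon single-nucleotide mutant table: for each of the 64 codons, the
# 9 possible point mutations with target index, transition flag, stop flag
# and synonymy flag (synonymy undefined/False for mutations to stops).
MUT_TARGET = np.zeros((64, 9), dtype=np.int64)
MUT_TS = np.zeros((64, 9), dtype=bool)
MUT_STOP = np.zeros((64, 9), dtype=bool)
MUT_SYN = np.zeros((64, 9), dtype=bool)
for _ci, _codon in enumerate(CODONS):
    _k = 0
    for _pos in range(3):
        for _nb in NT:
            if _nb == _codon[_pos]:
                continue
            _t = _codon[:_pos] + _nb + _codon[_pos + 1:]
            _ti = CODON_INDEX[_t]
            MUT_TARGET[_ci, _k] = _ti
            MUT_TS[_ci, _k] = _is_transition(_codon[_pos], _nb)
            MUT_STOP[_ci, _k] = IS_STOP[_ti]
            MUT_SYN[_ci, _k] = (not IS_STOP[_ti]) and AA[_ti] == AA[_ci]
            _k += 1


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str  # OK, AMBIGUOUS, NO_START, TOO_SHORT, NOT_TRIPLET, INTERNAL_STOP

    def __bool__(self) -> bool:
        return self.passed


def qc_cds(seq: str, min_length: int = 120) -> QCResult:
    """QC one coding sequence: ATG start, length, triplet, internal stops.

    A terminal stop codon is allowed.  Non-ACGT characters fail with reason
    AMBIGUOUS; codon-based estimation requires unambiguous triplets.
    """
    s = seq.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in s):
        return QCResult(False, "AMBIGUOUS")
    if len(s) < min_length:
        return QCResult(False, "TOO_SHORT")
    if len(s) % 3 != 0:
        return QCResult(False, "NOT_TRIPLET")
    if not s.startswith("ATG"):
        return QCResult(False, "NO_START")
    codons = [s[i:i + 3] for i in range(0, len(s), 3)]
    internal = codons[:-1]
    if any(c in STOPS for c in internal):
        return QCResult(False, "INTERNAL_STOP")
    return QCResult(True, "OK")


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pair of equal-length coding sequences, as codon indices."""

    codons1: np.ndarray
    codons2: np.ndarray

    def __post_init__(self):
        if self.codons1.shape != self.codons2.shape:
            raise SequenceError("aligned sequences differ in codon count")
        for arr in (self.codons1, self.codons2):
            if IS_STOP[arr].any():
                raise SequenceError("internal stop codon in alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons1)

    @classmethod
    def from_sequences(cls, seq1: str, seq2: str) -> "CodonAlignment":
        return prepare_pair(seq1, seq2)


def _encode_codons(seq: str) -> np.ndarray:
    if len(seq) % 3:
        raise SequenceError("sequence length not divisible by 3")
    return np.array([CODON_INDEX[seq[i:i + 3]] for i in range(0, len(seq), 3)],
                    dtype=np.int64)


def prepare_pair(seq1: str, seq2: str) -> CodonAlignment:
    """Build a codon alignment from two aligned nucleotide sequences.

    Codon columns containing a gap or ambiguity character in either sequence
    are dropped pairwise (single-column removal would break the reading
    frame).  Terminal stop codons are stripped.
    """
    s1 = seq1.upper().replace("U", "T")
    s2 = seq2.upper().replace("U", "T")
    if len(s1) != len(s2):
        raise SequenceError("aligned sequences differ in length")
    n = len(s1) - len(s1) % 3
    kept1, kept2 = [], []
    for i in range(0, n, 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        kept1.append(c1)
        kept2.append(c2)
    if kept1 and (kept1[-1] in STOPS or kept2[-1] in STOPS):
        kept1.pop()
        kept2.pop()
    if not kept1:
        raise SequenceError("no comparable codons after filtering")
    return CodonAlignment(_encode_codons("".join(kept1)), _encode_codons("".join(kept2)))


@dataclass
class DnDsEstimate:
    """Site counts, observed differences and corrected distances for a pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    kappa: float
    method: str
    n_codons: int
    flags: tuple[str, ...] = ()

    @property
    def saturated(self) -> bool:
        return "SATURATED" in self.flags

    @property
    def defined(self) -> bool:
        return np.isfinite(self.dS) and np.isfinite(self.dN)

    @property
    def omega(self) -> float:
        return self.dN / self.dS if self.dS > 0 else float("nan")


def _codon_sites(kappa: float, pi: np.ndarray) -> np.ndarray:
    """Synonymous site count per codon under mutation weights kappa and pi.

    Weight of each non-stop point mutation is (kappa if transition else 1)
    times the target codon's frequency; the synonymous fraction of total
    weight, scaled to 3 sites per codon.  kappa=1 with uniform pi gives the
    NG86 counts.
    """
    w = np.where(MUT_TS, kappa, 1.0) * pi[MUT_TARGET]
    w = np.where(MUT_STOP, 0.0, w)
    tot = w.sum(axis=1)
    syn = (w * MUT_SYN).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, syn / np.where(tot > 0, tot, 1.0), 0.0)
    return 3.0 * frac


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts for one sense codon."""
    codon = codon.upper().replace("U", "T")
    if codon not in CODON_INDEX:
        raise SequenceError(f"not a codon: {codon!r}")
    ci = CODON_INDEX[codon]
    if IS_STOP[ci]:
        raise SequenceError(f"stop codon: {codon}")
    s = _codon_sites(1.0, np.ones(64))[ci]
    return float(s), float(3.0 - s)


def _pathway_counts(c1: int, c2: int, kappa: float, omega: float,
                    pi: np.ndarray | None, equal_weights: bool) -> np.ndarray:
    """Weighted pathway-averaged difference counts for one codon pair.

    Returns [Sd_ts, Sd_tv, Nd_ts, Nd_tv].  Pathways passing through stop
    codons are excluded; if every pathway is blocked, pathways are weighted
    equally with stop-adjacent steps counted as non-synonymous.
    """
    a, b = CODONS[c1], CODONS[c2]
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return np.zeros(4)

    def steps_for(order, allow_stops):
        cur = a
        steps = []
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS and not allow_stops:
                return None
            ts = _is_transition(cur[pos], b[pos])
            if nxt in STOPS or cur in STOPS:
                syn = False
            else:
                syn = _CODE[cur] == _CODE[nxt]
            steps.append((syn, ts, nxt))
            cur = nxt
        return steps

    def accumulate(allow_stops):
        counts = np.zeros(4)
        total_w = 0.0
        for order in itertools.permutations(diff):
            steps = steps_for(order, allow_stops)
            if steps is None:
                continue
            if equal_weights:
                w = 1.0
            else:
                w = 1.0
                for syn, ts, nxt in steps:
                    w *= (kappa if ts else 1.0)
                    w *= (1.0 if syn else omega)
                    if pi is not None:
                        w *= pi[CODON_INDEX[nxt]]
            if w <= 0:
                continue
            vec = np.zeros(4)
            for syn, ts, _ in steps:
                vec[(0 if syn else 2) + (0 if ts else 1)] += 1
            counts += w * vec
            total_w += w
        return counts, total_w

    counts, total_w = accumulate(allow_stops=False)
    if total_w == 0:
        counts, total_w = accumulate(allow_stops=True)
    return counts / total_w


# Cache of equal-weight pathway counts for all codon pairs, built lazily.
_NG86_PAIR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _ng86_pair(c1: int, c2: int) -> np.ndarray:
    key = (min(c1, c2), max(c1, c2))
    out = _NG86_PAIR_CACHE.get(key)
    if out is None:
        out = _pathway_counts(key[0], key[1], 1.0, 1.0, None, equal_weights=True)
        _NG86_PAIR_CACHE[key] = out
    return out


def jc_correction(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN when saturated (p >= 3/4)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * np.log(arg)


def _k80_distance(P: float, Q: float) -> tuple[float, float]:
    """K80 distance and kappa from transition/transversion proportions."""
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return float("nan"), float("nan")
    d = -0.5 * np.log(a) - 0.25 * np.log(b)
    alpha = -0.5 * np.log(a) + 0.25 * np.log(b)
    beta = -0.25 * np.log(b)
    kappa = alpha / beta if beta > 0 else float("nan")
    return float(d), float(kappa)


def ng86_estimate(alignment: CodonAlignment) -> DnDsEstimate:
    """NG86 estimate for one codon-aligned pair."""
    c1, c2 = alignment.codons1, alignment.codons2
    sites = _codon_sites(1.0, np.ones(64))
    S = 0.5 * (sites[c1].sum() + sites[c2].sum())
    N = 3.0 * alignment.n_codons - S
    counts = np.zeros(4)
    for i in np.flatnonzero(c1 != c2):
        counts += _ng86_pair(int(c1[i]), int(c2[i]))
    Sd = counts[0] + counts[1]
    Nd = counts[2] + counts[3]
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jc_correction(pS)
    dN = jc_correction(pN)
    flags = () if np.isfinite(dS) and np.isfinite(dN) else ("SATURATED",)
    return DnDsEstimate(float(S), float(N), float(Sd), float(Nd), float(pS),
                        float(pN), dS, dN, 1.0, "NG86", alignment.n_codons, flags)


def _f3x4(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies over sense codons from the two sequences."""
    pos_freq = np.zeros((3, 4))
    for arr in (c1, c2):
        for codon_idx in arr:
            codon = CODONS[codon_idx]
            for p in range(3):
                pos_freq[p, NT_INDEX[codon[p]]] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freq[0, NT_INDEX[c[0]]] * pos_freq[1, NT_INDEX[c[1]]] * pos_freq[2, NT_INDEX[c[2]]]
        for c in CODONS
    ])
    pi[IS_STOP] = 0.0
    total = pi.sum()
    if total <= 0:
        pi = np.where(IS_STOP, 0.0, 1.0 / len(SENSE))
    else:
        pi /= total
    return pi


_FOLD = np.zeros((64, 3), dtype=np.int64)  # number of synonymous changes per position
for _ci, _codon in enumerate(CODONS):
    if IS_STOP[_ci]:
        continue
    for _pos in range(3):
        nsyn = 0
        for _nb in NT:
            if _nb == _codon[_pos]:
                continue
            _t = _codon[:_pos] + _nb + _codon[_pos + 1:]
            if _t not in STOPS and _CODE[_t] == _CODE[_codon]:
                nsyn += 1
        _FOLD[_ci, _pos] = nsyn


def _estimate_kappa(c1: np.ndarray, c2: np.ndarray) -> float:
    """kappa from fourfold-degenerate and nondegenerate sites (K80 per class).

    Site classes are taken conservatively where both codons agree on the
    degeneracy of the position.  Falls back to 2.0 when neither class yields
    a defined estimate (e.g. identical or extremely short sequences).
    """
    L = {0: 0, 4: 0}
    ts = {0: 0, 4: 0}
    tv = {0: 0, 4: 0}
    for i in range(len(c1)):
        a, b = CODONS[c1[i]], CODONS[c2[i]]
        for pos in range(3):
            fa, fb = _FOLD[c1[i], pos], _FOLD[c2[i], pos]
            if fa == 3 and fb == 3:
                cls = 4
            elif fa == 0 and fb == 0:
                cls = 0
            else:
                continue
            L[cls] += 1
            if a[pos] != b[pos]:
                if _is_transition(a[pos], b[pos]):
                    ts[cls] += 1
                else:
                    tv[cls] += 1
    kappas, weights = [], []
    for cls in (0, 4):
        if L[cls] == 0:
            continue
        _, kap = _k80_distance(ts[cls] / L[cls], tv[cls] / L[cls])
        if np.isfinite(kap) and kap > 0:
            kappas.append(kap)
            weights.append(L[cls])
    if not kappas:
        total_ts = ts[0] + ts[4]
        total_tv = tv[0] + tv[4]
        if total_tv > 0 and total_ts > 0:
            return float(np.clip(2.0 * total_ts / total_tv, 0.05, 50.0))
        return 2.0
    kappa = float(np.average(kappas, weights=weights))
    return float(np.clip(kappa, 0.05, 50.0))


def yn00_estimate(
    alignment: CodonAlignment,
    fix_kappa: float | None = None,
    codon_freqs: str = "f3x4",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> DnDsEstimate:
    """Yang–Nielsen-style approximate dN/dS estimate for one pair.

    ``codon_freqs`` is ``"f3x4"`` (from the pair) or ``"uniform"``.  With
    ``fix_kappa=1`` and uniform frequencies the site counts equal NG86.
    """
    c1, c2 = alignment.codons1, alignment.codons2
    if codon_freqs == "uniform":
        pi = np.where(IS_STOP, 0.0, 1.0 / len(SENSE))
    elif codon_freqs == "f3x4":
        pi = _f3x4(c1, c2)
    else:
        raise ValueError("codon_freqs must be 'f3x4' or 'uniform'")
    kappa = float(fix_kappa) if fix_kappa is not None else _estimate_kappa(c1, c2)

    sites = _codon_sites(kappa, pi)
    S = 0.5 * (sites[c1].sum() + sites[c2].sum())
    N = 3.0 * len(c1) - S
    diff_idx = np.flatnonzero(c1 != c2)
    flags: list[str] = []

    if len(diff_idx) == 0:
        return DnDsEstimate(float(S), float(N), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                            kappa, "YN00", len(c1), ())

    # Count weighted pathway differences, averaging the two directions so the
    # estimate is symmetric in the input sequences.
    pair_counts: dict[tuple[int, int], int] = {}
    for i in diff_idx:
        key = (int(c1[i]), int(c2[i]))
        pair_counts[key] = pair_counts.get(key, 0) + 1

    omega = 0.5
    dS = dN = float("nan")
    Sd = Nd = 0.0
    converged = False
    for _ in range(max_iter):
        counts = np.zeros(4)
        for (a, b), mult in pair_counts.items():
            fwd = _pathway_counts(a, b, kappa, omega, pi, equal_weights=False)
            rev = _pathway_counts(b, a, kappa, omega, pi, equal_weights=False)
            counts += mult * 0.5 * (fwd + rev)
        Sd = counts[0] + counts[1]
        Nd = counts[2] + counts[3]
        dS, _ = _k80_distance(counts[0] / S, counts[1] / S)
        dN, _ = _k80_distance(counts[2] / N, counts[3] / N)
        if not (np.isfinite(dS) and np.isfinite(dN)):
            flags.append("SATURATED")
            break
        if dS <= 0:
            new_omega = 50.0 if dN > 0 else 1.0
        elif dN <= 0:
            new_omega = 1e-4
        else:
            new_omega = dN / dS
        new_omega = float(np.clip(new_omega, 1e-4, 50.0))
        if abs(new_omega - omega) < tol:
            omega = new_omega
            converged = True
            break
        omega = new_omega
    if not converged and "SATURATED" not in flags:
        flags.append("NO_CONVERGENCE")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return DnDsEstimate(float(S), float(N), float(Sd), float(Nd), float(pS),
                        float(pN), float(dS), float(dN), kappa, "YN00",
                        len(c1), tuple(flags))


def filter_ds(estimates: Iterable[DnDsEstimate], max_ds: float = 0.2) -> list[DnDsEstimate]:
    """Drop saturated/undefined estimates and pairs with dS above ``max_ds``.

    The cap guards against mis-assigned orthologs masquerading as highly
    diverged gametologs.
    """
    kept = []
    for est in estimates:
        if not est.defined or est.saturated:
            continue
        if est.dS > max_ds:
            continue
        kept.append(est)
    return kept


def compare_regions(
    estimates_by_region: Mapping[str, Sequence[DnDsEstimate]],
    metric: str = "dS",
    baseline: str = "GENOME",
) -> dict[str, dict[str, float]]:
    """Per-region mean of dS or dN plus Mann–Whitney U p-value vs the genome.

    The baseline group must exclude the sex chromosome.  Two-sided test;
    p is NaN for regions (or a baseline) with fewer than two estimates.
    """
    if metric not in ("dS", "dN"):
        raise ValueError("metric must be 'dS' or 'dN'")
    if baseline not in estimates_by_region:
        raise ValueError(f"baseline group {baseline!r} missing")
    values = {
        region: np.array([getattr(e, metric) for e in ests], dtype=float)
        for region, ests in estimates_by_region.items()
    }
    base = values[baseline]
    out: dict[str, dict[str, float]] = {}
    for region, vals in values.items():
        entry = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "n": float(len(vals)),
            "p": float("nan"),
        }
        if region != baseline and len(vals) >= 2 and len(base) >= 2:
            res = stats.mannwhitneyu(vals, base, alternative="two-sided")
            entry["p"] = float(res.pvalue)
        out[region] = entry
    return out
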