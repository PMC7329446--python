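"""Independent brute-force oracles for the codon-counting machinery.

Deliberately naive: genetic code via Biopython translation, explicit
enumeration of point mutations and mutation pathways, plain math.  Nothing
here imports from stratascan, so agreement is a genuine cross-check.
"""

import itertools
import math

from Bio.Seq import Seq

NTS = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def point_mutants(codon: str):
    for pos in range(3):
        for nb in NTS:
            if nb != codon[pos]:
                yield codon[:pos] + nb + codon[pos + 1:]


def oracle_sites(codon: str) -> tuple[float, float]:
    """Synonymous/non-synonymous sites: mutations to stops excluded,
    remaining opportunities renormalized to 3 per codon."""
    assert codon not in STOPS
    mutants = [m for m in point_mutants(codon) if m not in STOPS]
    syn = sum(1 for m in mutants if translate(m) == translate(codon))
    s = 3.0 * syn / len(mutants)
    return s, 3.0 - s


def is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def oracle_pathways(c1: str, c2: str):
    """Equal-weight pathway enumeration: (Sd, Nd) for one codon pair.

    Pathways through stop codons are skipped; if all are blocked, all
    orderings count with stop-adjacent steps taken as non-synonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS and not allow_stops:
                return None
            if nxt not in STOPS and cur not in STOPS and translate(cur) == translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order, False) for order in itertools.permutations(diff)]
    results = [r for r in results if r is not None]
    if not results:
        results = [walk(order, True) for order in itertools.permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def oracle_ng86(seq1: str, seq2: str):
    """Full NG86 estimate by enumeration; returns (S, N, Sd, Nd, dS, dN)."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    codons1 = [seq1[i:i + 3] for i in range(0, len(seq1), 3)]
    codons2 = [seq2[i:i + 3] for i in range(0, len(seq2), 3)]
    S = sum(oracle_sites(c)[0] for c in codons1 + codons2) / 2.0
    N = 3.0 * len(codons1) - S
    Sd = Nd = 0.0
    for a, b in zip(codons1, codons2):
        sd, nd = oracle_pathways(a, b)
        Sd += sd
        Nd += nd

    def jc(p):
        arg = 1.0 - 4.0 * p / 3.0
        return -0.75 * math.log(arg) if arg > 0 else float("nan")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return S, N, Sd, Nd, jc(pS), jc(pN)
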