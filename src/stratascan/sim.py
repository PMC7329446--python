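"""Truth-labeled synthetic ZW genomes and every downstream analysis input.

The generator emulates the signal structure that a female-heterogametic
(ZW) read-mapping study relies on, for a female reference assembly built
from the heterogametic sex:

* autosomes / PAR — diploid in both sexes, heterozygous sites at ~0.5%
  (1 SNP per 200 bp), equal female and male depth;
* an older Z-linked stratum (stratum I) — the assembly backbone is the Z
  haplotype; the diverged W reads of the female fail to map, so female
  depth is ~half of male depth (log2 F:M near -1) and female SNPs vanish,
  while the male's two Z copies stay ordinarily heterozygous.  Optional
  W-chimeric segments emulate Z-W chimeric assembly scaffolds (female-only
  coverage inside the chimera);
* a younger stratum (stratum II) — Z and W are still similar enough that
  both map, so depth is near-equal but the female accumulates excess
  SNPs (ambient heterozygosity plus post-suppression Z-W divergence);
* W-specific scaffolds — female-only depth at the haploid level, male
  depth at a configurable mismapping background (default 0), and repeat
  enrichment above the genomic background.

All randomness flows from one root seed through per-scaffold,
per-component substreams, so any output can be regenerated independently
and identically.  Sequences follow a Jukes–Cantor substitution process;
divergence parameters are expected substitutions per site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import winstats
from .anchor import AlignmentRecord
from .dnds import CODONS, CODON_INDEX, IS_STOP, SENSE, STOPS

__all__ = [
    "SimulationConfig",
    "GametologDepths",
    "ScaffoldInfo",
    "TrueGenome",
    "OrthologGroup",
    "SimAlignments",
    "ConfigError",
    "AUTOSOME", "PAR", "STRATUM1_Z", "STRATUM2", "W_SPECIFIC",
    "simulate_genome",
    "simulate_profiles",
    "simulate_gametologs",
    "simulate_cds_pairs",
    "simulate_alignments",
]

AUTOSOME = "AUTOSOME"
PAR = "PAR"
STRATUM1_Z = "STRATUM1_Z"
STRATUM2 = "STRATUM2"
W_SPECIFIC = "W_SPECIFIC"

_NT = "TCAG"  # codes 0..3, matching the codon table ordering in dnds


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic ZW genome.

    Defaults describe a ~31 Mb genome (26 scaffolds of 1.2 Mb): 20
    autosomes, one pseudo-autosomal scaffold, two stratum-I Z scaffolds,
    one stratum-II scaffold and two W-specific scaffolds, sequenced at 60x
    per sex, with 0.5% heterozygosity and Z/W divergence of 1.2% (stratum
    I) and 0.2% on top of ambient polymorphism (stratum II).
    """

    n_autosomal_scaffolds: int = 20
    scaffold_length: int = 1_200_000
    n_par: int = 1
    n_stratum1: int = 2
    n_stratum2: int = 1
    n_w_specific: int = 2
    heterozygosity: float = 0.005
    stratum1_zw_divergence: float = 0.012
    stratum2_zw_divergence: float = 0.002
    female_depth: float = 60.0
    male_depth: float = 60.0
    repeat_fraction_genome: float = 0.35
    repeat_fraction_w: float = 0.60
    male_w_mismap_rate: float = 0.0
    chimera_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_autosomal_scaffolds, self.n_par, self.n_stratum1,
                  self.n_stratum2, self.n_w_specific)
        if any(c < 0 for c in counts) or sum(counts) == 0:
            raise ConfigError("scaffold counts must be non-negative with at least one scaffold")
        if self.scaffold_length <= 0:
            raise ConfigError("scaffold_length must be positive")
        for name in ("heterozygosity", "repeat_fraction_genome", "repeat_fraction_w",
                     "male_w_mismap_rate", "chimera_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.female_depth <= 0 or self.male_depth <= 0:
            raise ConfigError("depths must be positive")
        if self.stratum1_zw_divergence < self.stratum2_zw_divergence:
            raise ConfigError("stratum I Z/W divergence must be >= stratum II divergence")


@dataclass(frozen=True)
class ScaffoldInfo:
    name: str
    index: int
    length: int
    label: str
    chimera_intervals: tuple[tuple[int, int], ...] = ()


def _rng(config_seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, *stream]))


# substream tags
_SEQ, _VAR_F, _VAR_M, _REPEAT, _PROF_F, _PROF_M, _ALT = range(7)
_ALT_M = 10


@dataclass
class TrueGenome:
    """Scaffold set with truth labels, variant positions and repeat intervals.

    Sequences are not stored; they are regenerated deterministically from
    the configuration seed on demand.
    """

    config: SimulationConfig
    scaffolds: list[ScaffoldInfo]
    repeat_intervals: dict[str, np.ndarray]          # (n, 2) 0-based half-open
    female_variants: dict[str, np.ndarray]           # positions heterozygous in the female
    male_variants: dict[str, np.ndarray]             # positions heterozygous in the male

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {s.name: s.length for s in self.scaffolds}

    def scaffold(self, name: str) -> ScaffoldInfo:
        for s in self.scaffolds:
            if s.name == name:
                return s
        raise KeyError(name)

    def labels(self) -> dict[str, str]:
        return {s.name: s.label for s in self.scaffolds}

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": [s.name for s in self.scaffolds],
                "length": [s.length for s in self.scaffolds],
                "label": [s.label for s in self.scaffolds],
            }
        )

    def masked_lengths(self) -> dict[str, int]:
        """Scaffold lengths minus repeat-masked bp (dedup denominator)."""
        out = {}
        for s in self.scaffolds:
            iv = self.repeat_intervals[s.name]
            masked = int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0
            out[s.name] = s.length - masked
        return out

    def repeat_fraction(self, name: str) -> float:
        iv = self.repeat_intervals[name]
        rep = int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0
        return rep / self.scaffold(name).length

    # -- sequences ---------------------------------------------------------

    def backbone_sequence(self, name: str) -> np.ndarray:
        """Reference (assembly) haplotype as uint8 codes into 'TCAG'."""
        s = self.scaffold(name)
        rng = _rng(self.config.seed, s.index, _SEQ)
        return rng.integers(0, 4, size=s.length, dtype=np.uint8)

    def alternate_sequence(self, name: str) -> np.ndarray:
        """The individual's other haplotype (W for sex-linked regions).

        Differs from the backbone at the female variant positions; for
        stratum I the backbone is the Z haplotype and the alternate carries
        the full Z-W divergence (heterozygosity + stratum I divergence).
        """
        s = self.scaffold(name)
        seq = self.backbone_sequence(name).copy()
        pos = self.female_variant_positions_full(name)
        if len(pos):
            rng = _rng(self.config.seed, s.index, _ALT)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=len(pos), dtype=np.uint8)) % 4
        return seq

    def female_variant_positions_full(self, name: str) -> np.ndarray:
        """All female Z-W / allelic difference positions, including the
        stratum-I divergence that is invisible in mapped profiles."""
        s = self.scaffold(name)
        if s.label == STRATUM1_Z:
            rate = self.config.heterozygosity + self.config.stratum1_zw_divergence
            rng = _rng(self.config.seed, s.index, _VAR_F)
            return np.flatnonzero(rng.random(s.length) < rate)
        return self.female_variants[name]

    def write_fasta(self, path, width: int = 70) -> None:
        lut = np.frombuffer(_NT.encode(), dtype=np.uint8)
        with open(path, "w") as fh:
            for s in self.scaffolds:
                seq = lut[self.backbone_sequence(s.name)].tobytes().decode()
                fh.write(f">{s.name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_truth_table(self, path) -> None:
        self.truth_table().to_csv(path, sep="\t", index=False)

    def write_repeats_gff(self, path) -> None:
        """Repeat intervals as GFF3 (1-based, closed intervals)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for s in self.scaffolds:
                for start, end in self.repeat_intervals[s.name]:
                    fh.write(
                        f"{s.name}\tstratascan-sim\trepeat_region\t{start + 1}\t{end}\t"
                        f".\t+\t.\tID=rep_{s.name}_{start}\n"
                    )

    def write_genes_gff(self, path, spacing: int = 20_000, gene_length: int = 1_500) -> None:
        """Regularly spaced placeholder gene models as GFF3 (1-based, closed).

        The analysis itself consumes gene structure only through alignment
        and CDS records; these models exist so downstream consumers of the
        simulated genome have a coherent annotation to lift over.
        """
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for s in self.scaffolds:
                for k, start in enumerate(range(0, s.length - gene_length, spacing)):
                    gid = f"gene_{s.name}_{k + 1:03d}"
                    fh.write(f"{s.name}\tstratascan-sim\tgene\t{start + 1}\t"
                             f"{start + gene_length}\t.\t+\t.\tID={gid}\n")

    def default_reference_map(self) -> dict[str, tuple[str, int, str]]:
        """Scaffold -> (chromosome, offset, strand) for the anchoring truth.

        Autosomes are placed consecutively on autosomal chromosomes; the
        sex chromosome carries PAR, then stratum II, then stratum I (the
        strata expand away from the recombining region).  W-specific
        scaffolds have no place in the reference and are omitted.
        """
        out: dict[str, tuple[str, int, str]] = {}
        for s in self.scaffolds:
            if s.label == AUTOSOME:
                out[s.name] = (f"chrA{s.index:02d}", 0, "+")
        sex = ([s for s in self.scaffolds if s.label == PAR]
               + [s for s in self.scaffolds if s.label == STRATUM2]
               + [s for s in self.scaffolds if s.label == STRATUM1_Z])
        offset = 0
        for s in sex:
            out[s.name] = ("chrS", offset, "+")
            offset += s.length
        return out


def _repeat_intervals(rng: np.random.Generator, length: int, fraction: float,
                      tile: int = 1000) -> np.ndarray:
    """Random repeat annotation: 1-kb tiles marked at the target fraction,
    adjacent marked tiles merged."""
    n_tiles = (length + tile - 1) // tile
    marked = rng.random(n_tiles) < fraction
    if not marked.any():
        return np.empty((0, 2), dtype=np.int64)
    idx = np.flatnonzero(marked)
    starts = [int(idx[0])]
    ends = []
    for prev, cur in zip(idx[:-1], idx[1:]):
        if cur != prev + 1:
            ends.append(int(prev) + 1)
            starts.append(int(cur))
    ends.append(int(idx[-1]) + 1)
    out = np.array([[s * tile, min(e * tile, length)] for s, e in zip(starts, ends)],
                   dtype=np.int64)
    return out


def simulate_genome(config: SimulationConfig) -> TrueGenome:
    """Generate the truth-labeled scaffold set for one configuration."""
    names_labels: list[tuple[str, str]] = []
    names_labels += [(f"aut{i + 1:02d}", AUTOSOME) for i in range(config.n_autosomal_scaffolds)]
    names_labels += [(f"par{i + 1}", PAR) for i in range(config.n_par)]
    names_labels += [(f"str2_{i + 1}", STRATUM2) for i in range(config.n_stratum2)]
    names_labels += [(f"str1_{i + 1}", STRATUM1_Z) for i in range(config.n_stratum1)]
    names_labels += [(f"w{i + 1}", W_SPECIFIC) for i in range(config.n_w_specific)]

    scaffolds: list[ScaffoldInfo] = []
    repeats: dict[str, np.ndarray] = {}
    var_f: dict[str, np.ndarray] = {}
    var_m: dict[str, np.ndarray] = {}
    L = config.scaffold_length
    for idx, (name, label) in enumerate(names_labels):
        chimeras: tuple[tuple[int, int], ...] = ()
        if label == STRATUM1_Z and config.chimera_fraction > 0:
            span = int(round(config.chimera_fraction * L))
            start = int(_rng(config.seed, idx, 99).integers(0, max(L - span, 1)))
            chimeras = ((start, start + span),)
        info = ScaffoldInfo(name, idx, L, label, chimeras)
        scaffolds.append(info)

        rep_frac = config.repeat_fraction_w if label == W_SPECIFIC else config.repeat_fraction_genome
        repeats[name] = _repeat_intervals(_rng(config.seed, idx, _REPEAT), L, rep_frac)

        # Mapped heterozygous positions per sex.  Stratum I: the female's W
        # reads do not map, so her profile is effectively haploid there; the
        # full Z-W variant set is still realized in the written haplotype
        # sequences (female_variant_positions_full).
        if label == AUTOSOME or label == PAR:
            f_rate = config.heterozygosity
            m_rate = config.heterozygosity
        elif label == STRATUM2:
            f_rate = config.heterozygosity + config.stratum2_zw_divergence
            m_rate = config.heterozygosity
        elif label == STRATUM1_Z:
            f_rate = 0.0
            m_rate = config.heterozygosity
        else:  # W_SPECIFIC: haploid in the female, absent in the male
            f_rate = 0.0
            m_rate = 0.0
        rng_f = _rng(config.seed, idx, _VAR_F)
        rng_m = _rng(config.seed, idx, _VAR_M)
        if label == STRATUM1_Z:
            # consume the stream identically to female_variant_positions_full
            full_rate = config.heterozygosity + config.stratum1_zw_divergence
            _ = rng_f.random(L) < full_rate
            var_f[name] = np.empty(0, dtype=np.int64)
        else:
            var_f[name] = np.flatnonzero(rng_f.random(L) < f_rate) if f_rate > 0 else np.empty(0, dtype=np.int64)
        var_m[name] = np.flatnonzero(rng_m.random(L) < m_rate) if m_rate > 0 else np.empty(0, dtype=np.int64)

    return TrueGenome(config, scaffolds, repeats, var_f, var_m)


# ---------------------------------------------------------------------------
# read-profile simulation
# ---------------------------------------------------------------------------


@dataclass
class SiteVectors:
    """Per-site depth plus sparse allele-1 counts at heterozygous sites."""

    scaffold: str
    depth: np.ndarray
    var_pos: np.ndarray
    allele1: np.ndarray

    def snp_pass(self, min_depth: int = 5, min_maf: float = 0.30) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (snp, passing) per-site vectors under the calling rule."""
        passing = self.depth >= min_depth
        snp = np.zeros(len(self.depth), dtype=bool)
        if len(self.var_pos):
            d = self.depth[self.var_pos].astype(float)
            a = self.allele1.astype(float)
            minor = np.minimum(a, d - a)
            with np.errstate(invalid="ignore", divide="ignore"):
                ok = (d >= min_depth) & (a > 0) & (a < d) & (minor / np.maximum(d, 1) >= min_maf)
            snp[self.var_pos[ok]] = True
        return snp, passing


class SimulatedProfiles:
    """Lazy, deterministic per-sex read-count profiles for a genome.

    Every scaffold/sex combination is regenerated from its own substream,
    so repeated access (or re-running a single module) gives identical
    values without holding the whole genome's profiles in memory.
    """

    def __init__(self, genome: TrueGenome, config: SimulationConfig | None = None):
        config = config or genome.config
        if config is not genome.config and config != genome.config:
            raise ConfigError("profile config does not match the genome's config")
        self.genome = genome
        self.config = config

    def scaffold_sites(self, name: str, sex: str) -> SiteVectors:
        cfg = self.config
        s = self.genome.scaffold(name)
        if sex == "female":
            tag, mean, variants = _PROF_F, cfg.female_depth, self.genome.female_variants[name]
        elif sex == "male":
            tag, mean, variants = _PROF_M, cfg.male_depth, self.genome.male_variants[name]
        else:
            raise ValueError("sex must be 'female' or 'male'")
        rng = _rng(cfg.seed, s.index, tag)

        if s.label in (STRATUM1_Z, W_SPECIFIC) and sex == "female":
            mean = mean / 2.0          # single mapped haplotype
        if s.label == W_SPECIFIC and sex == "male":
            mean = mean * cfg.male_w_mismap_rate
        depth = (rng.poisson(mean, size=s.length) if mean > 0
                 else np.zeros(s.length, dtype=np.int64))

        if s.label == STRATUM1_Z and s.chimera_intervals:
            # chimeric W segments: female-only material inside a Z backbone
            for start, end in s.chimera_intervals:
                if sex == "male":
                    seg = (rng.poisson(cfg.male_depth * cfg.male_w_mismap_rate, size=end - start)
                           if cfg.male_w_mismap_rate > 0 else 0)
                    depth[start:end] = seg
        if len(variants):
            d = depth[variants]
            allele1 = rng.binomial(d, 0.5)
        else:
            allele1 = np.empty(0, dtype=np.int64)
        if s.label == STRATUM1_Z and s.chimera_intervals and sex == "male" and len(variants):
            inside = np.zeros(s.length, dtype=bool)
            for start, end in s.chimera_intervals:
                inside[start:end] = True
            keep = ~inside[variants]
            variants, allele1 = variants[keep], allele1[keep]
        return SiteVectors(name, depth, variants, allele1)

    def counts_matrix(self, name: str, sex: str) -> np.ndarray:
        """Dense (L, 4) A/C/G/T count matrix (for writing sam2pro-style TSV)."""
        sv = self.scaffold_sites(name, sex)
        backbone = self.genome.backbone_sequence(name)
        if sex == "female":
            alternate = self.genome.alternate_sequence(name)
        else:
            # the male's other Z haplotype differs at his own variant sites
            alternate = backbone.copy()
            if len(sv.var_pos):
                s = self.genome.scaffold(name)
                rng_alt = _rng(self.config.seed, s.index, _ALT_M)
                alternate[sv.var_pos] = (
                    alternate[sv.var_pos]
                    + rng_alt.integers(1, 4, size=len(sv.var_pos), dtype=np.uint8)
                ) % 4
        # base codes are indices into TCAG; profiles are written A,C,G,T
        tcag_to_acgt = np.array([3, 1, 0, 2])  # T,C,A,G -> column in ACGT
        counts = np.zeros((len(sv.depth), 4), dtype=np.int64)
        cols = tcag_to_acgt[backbone]
        counts[np.arange(len(sv.depth)), cols] = sv.depth
        if len(sv.var_pos):
            pos = sv.var_pos
            a1 = sv.allele1
            d = sv.depth[pos]
            counts[pos, tcag_to_acgt[backbone[pos]]] = a1
            counts[pos, tcag_to_acgt[alternate[pos]]] += d - a1
        return counts

    def write_tsv(self, sex: str, path) -> None:
        """Write one sample's profile as ``scaffold  pos(1-based)  A C G T``.

        Zero-depth sites are omitted (absent positions imply depth 0)."""
        with open(path, "w") as fh:
            for s in self.genome.scaffolds:
                counts = self.counts_matrix(s.name, sex)
                nz = np.flatnonzero(counts.sum(axis=1) > 0)
                for p in nz:
                    a, c, g, t = counts[p]
                    fh.write(f"{s.name}\t{p + 1}\t{a}\t{c}\t{g}\t{t}\n")

    def iter_profiles(self, sex: str) -> Iterator[winstats.SiteProfile]:
        for s in self.genome.scaffolds:
            counts = self.counts_matrix(s.name, sex)
            for p in np.flatnonzero(counts.sum(axis=1) > 0):
                yield winstats.SiteProfile(s.name, int(p) + 1, tuple(int(x) for x in counts[p]))

    def window_table(self, window: int = winstats.DEFAULT_WINDOW,
                     min_depth: int = 5, min_maf: float = 0.30) -> pd.DataFrame:
        """Normalized window statistics for both sexes over the whole genome."""
        frames = []
        for s in self.genome.scaffolds:
            f = self.scaffold_sites(s.name, "female")
            m = self.scaffold_sites(s.name, "male")
            snp_f, pass_f = f.snp_pass(min_depth, min_maf)
            snp_m, pass_m = m.snp_pass(min_depth, min_maf)
            frames.append(
                winstats.scaffold_window_stats(
                    s.name, s.length, f.depth, snp_f, pass_f, m.depth, snp_m, pass_m,
                    window=window,
                )
            )
        return winstats.add_ratio_columns(pd.concat(frames, ignore_index=True))


def simulate_profiles(genome: TrueGenome, config: SimulationConfig | None = None) -> SimulatedProfiles:
    """Per-site read-count profiles for the female and male samples."""
    return SimulatedProfiles(genome, config)


# ---------------------------------------------------------------------------
# gametolog / ortholog-group simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GametologDepths:
    """Node depths of the gametolog species tree, in substitutions/site per
    lineage from the present.

    The stratum-I W lineage splits before the congener species (recombination
    suppressed before speciation); the stratum-II W joins the female Z inside
    the within-species clade (suppressed after speciation).
    """

    outgroup: float = 0.06
    congener1: float = 0.03
    congener2: float = 0.02
    within_species_root: float = 0.004
    w_stratum1: float = 0.035
    w_stratum2: float = 0.0035
    coalescent: float = 0.0025

    def __post_init__(self):
        ordered = (self.outgroup >= self.w_stratum1 >= self.congener1 >= self.congener2
                   >= self.within_species_root >= self.w_stratum2 >= self.coalescent >= 0)
        if not ordered:
            raise ConfigError(
                "gametolog depths must satisfy outgroup >= stratum-I W >= congeners "
                ">= within-species root >= stratum-II W >= coalescent >= 0"
            )


@dataclass
class OrthologGroup:
    """One gene's sequences across haplotypes, congeners and the outgroup."""

    gene_id: str
    sequences: dict[str, str]
    true_stratum: str             # STRATUM1 | STRATUM2 | AUTOSOME
    w_label: str | None = None    # which female haplotype is the true W

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ConfigError("ortholog group sequences must share one length")
        (length,) = lengths
        if length % 3:
            raise ConfigError("ortholog group sequence length must be a codon multiple")

    def alignment(self) -> tuple[list[str], list[str]]:
        labels = sorted(self.sequences)
        return labels, [self.sequences[t] for t in labels]


def _random_sense_codons(rng: np.random.Generator, n_codons: int,
                         start_atg: bool = False) -> np.ndarray:
    idx = rng.choice(SENSE, size=n_codons)
    if start_atg:
        idx[0] = CODON_INDEX["ATG"]
    return idx


def _codons_to_nt(codon_idx: np.ndarray) -> np.ndarray:
    nt = np.empty(3 * len(codon_idx), dtype=np.uint8)
    for k in range(3):
        nt[k::3] = (codon_idx // (4 ** (2 - k))) % 4
    return nt


def _nt_to_codons(nt: np.ndarray) -> np.ndarray:
    return nt[0::3] * 16 + nt[1::3] * 4 + nt[2::3]


def _evolve(nt: np.ndarray, distance: float, rng: np.random.Generator,
            frozen_codons: int = 0) -> np.ndarray:
    """Jukes–Cantor evolution over one branch; codons mutating into stops
    revert (the substitution is rejected), keeping all sequences coding."""
    if distance < 0:
        raise ConfigError("negative branch length")
    if distance == 0:
        return nt.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    out = nt.copy()
    mask = rng.random(len(nt)) < p
    if frozen_codons:
        mask[: 3 * frozen_codons] = False
    hit = np.flatnonzero(mask)
    if len(hit) == 0:
        return out
    out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit), dtype=np.uint8)) % 4
    codons = _nt_to_codons(out)
    bad = np.flatnonzero(IS_STOP[codons])
    for b in bad:
        out[3 * b: 3 * b + 3] = nt[3 * b: 3 * b + 3]
    return out


def _gene_tree(stratum: str, d: GametologDepths):
    """Nested (depth, children) topology; leaves are (depth=0, label)."""
    tip = lambda lab: (0.0, lab)
    if stratum == "STRATUM1":
        zclade = (d.coalescent, [tip("Z_f"), tip("male_h1"), tip("male_h2")])
        inner = (d.congener2, [tip("congener2"), zclade])
        inner = (d.congener1, [tip("congener1"), inner])
        inner = (d.w_stratum1, [tip("W_f"), inner])
    else:
        if stratum == "STRATUM2":
            fpair = (d.w_stratum2, [tip("W_f"), tip("Z_f")])
        else:
            fpair = (d.coalescent, [tip("female_h1"), tip("female_h2")])
        mpair = (d.coalescent, [tip("male_h1"), tip("male_h2")])
        sv = (d.within_species_root, [fpair, mpair])
        inner = (d.congener2, [tip("congener2"), sv])
        inner = (d.congener1, [tip("congener1"), inner])
    return (d.outgroup, [tip("outgroup"), inner])


def simulate_gametologs(
    genome: TrueGenome | None,
    n_genes: Mapping[str, int],
    branch_lengths: GametologDepths | None = None,
    seed: int = 0,
    n_codons: int = 500,
) -> list[OrthologGroup]:
    """Ortholog groups with seven labeled sequences per gene.

    ``n_genes`` maps stratum labels (STRATUM1, STRATUM2, AUTOSOME) to gene
    counts.  Which female haplotype carries the W copy is randomized per
    gene.  ``genome`` fixes the seed context when given (its config seed is
    combined with ``seed``); pass None for standalone use.
    """
    depths = branch_lengths or GametologDepths()
    base_seed = (genome.config.seed if genome is not None else 0)
    groups: list[OrthologGroup] = []
    counter = 0
    for stratum in ("STRATUM1", "STRATUM2", "AUTOSOME"):
        for g in range(int(n_genes.get(stratum, 0))):
            rng = _rng(base_seed, 7, seed, counter)
            counter += 1
            root = _random_sense_codons(rng, n_codons)
            tree = _gene_tree(stratum, depths)
            seqs: dict[str, np.ndarray] = {}

            def walk(node, parent_nt, parent_depth):
                depth, payload = node
                branch = parent_depth - depth
                child_nt = _evolve(parent_nt, branch, rng)
                if isinstance(payload, str):
                    seqs[payload] = child_nt
                else:
                    for sub in payload:
                        walk(sub, child_nt, depth)

            root_nt = _codons_to_nt(root)
            depth0, children = tree
            for child in children:
                walk(child, root_nt, depth0)

            w_is_h1 = bool(rng.integers(0, 2))
            rename = {}
            if stratum in ("STRATUM1", "STRATUM2"):
                rename["W_f"] = "female_h1" if w_is_h1 else "female_h2"
                rename["Z_f"] = "female_h2" if w_is_h1 else "female_h1"
                w_label = rename["W_f"]
            else:
                w_label = None
            lut = _NT
            sequences = {
                rename.get(lab, lab): "".join(lut[b] for b in nt)
                for lab, nt in seqs.items()
            }
            groups.append(OrthologGroup(f"gene_{stratum.lower()}_{g + 1:04d}",
                                        sequences, stratum, w_label))
    return groups


def simulate_cds_pairs(
    n_genes: int,
    divergence: float,
    n_codons: int = 300,
    seed: int = 0,
    label: str = "GENOME",
) -> list[tuple[str, str, str]]:
    """Phased haplotype CDS pairs at a given pairwise divergence.

    Each gene yields (gene_id, haplotype1, haplotype2): a random coding
    sequence (ATG start kept fixed so the pairs pass CDS QC) with each copy
    evolved half the pairwise distance from the ancestor.
    """
    if divergence < 0:
        raise ConfigError("divergence must be non-negative")
    out = []
    for g in range(n_genes):
        rng = _rng(seed, 8, g)
        root = _codons_to_nt(_random_sense_codons(rng, n_codons, start_atg=True))
        h1 = _evolve(root, divergence / 2.0, rng, frozen_codons=1)
        h2 = _evolve(root, divergence / 2.0, rng, frozen_codons=1)
        to_str = lambda nt: "".join(_NT[b] for b in nt)
        out.append((f"{label.lower()}_{g + 1:04d}", to_str(h1), to_str(h2)))
    return out


def write_ortholog_fastas(groups: Sequence[OrthologGroup], outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    for grp in groups:
        with open(os.path.join(outdir, f"{grp.gene_id}.fa"), "w") as fh:
            for label in sorted(grp.sequences):
                fh.write(f">{label}\n{grp.sequences[label]}\n")


def write_cds_fasta(pairs: Sequence[tuple[str, str, str]], path) -> None:
    """Paired haplotype CDS records, suffixed _h1/_h2."""
    with open(path, "w") as fh:
        for gene, h1, h2 in pairs:
            fh.write(f">{gene}_h1\n{h1}\n>{gene}_h2\n{h2}\n")


# ---------------------------------------------------------------------------
# alignment-record simulation (anchoring + dedup inputs)
# ---------------------------------------------------------------------------


@dataclass
class SimAlignments:
    reference_records: list[AlignmentRecord]
    self_records: list[AlignmentRecord]
    duplicate_truth: dict[str, str]          # duplicate scaffold -> original
    masked_lengths: dict[str, int]
    shuffled: tuple[str, ...] = ()

    @property
    def records(self) -> list[AlignmentRecord]:
        return list(self.reference_records)


def simulate_alignments(
    genome: TrueGenome,
    reference_map: Mapping[str, tuple[str, int, str]] | None = None,
    seed: int = 0,
    block: int = 60_000,
    within_gap: int = 2_000,
    identity: float = 0.95,
    n_duplicates: int = 2,
    duplicate_identity: float = 0.95,
    duplicate_overlap: float = 1.0,
    shuffled_scaffolds: Sequence[str] = (),
) -> SimAlignments:
    """Scaffold-to-reference and self-alignment records with planted truth.

    Reference records follow ``reference_map`` (scaffold -> chromosome,
    offset, strand) as chains of ~``block`` bp alignments separated by
    ``within_gap`` bp gaps (linkable into one tiling path).  Scaffolds in
    ``shuffled_scaffolds`` instead get a minority contiguous path on their
    own chromosome and a majority of scattered alignments elsewhere, so the
    longest tiling path disagrees with the overall alignment placement.
    Allelic duplicates are planted as half-length copies of the first
    ``n_duplicates`` autosomal scaffolds with one self-alignment record each
    at the requested identity and (masked-length) overlap.
    """
    ref_map = dict(reference_map) if reference_map is not None else genome.default_reference_map()
    # reject overlapping reference intervals
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for name, (chrom, offset, strand) in ref_map.items():
        L = genome.scaffold_lengths[name]
        by_chrom.setdefault(chrom, []).append((offset, offset + L, name))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs[:-1], ivs[1:]):
            if s2 < e1:
                raise ConfigError(
                    f"overlapping reference offsets on {chrom}: {n1} and {n2}"
                )

    rng = _rng(genome.config.seed, 9, seed)
    chroms = sorted({c for c, _, _ in ref_map.values()})
    ref_records: list[AlignmentRecord] = []
    shuffled = tuple(shuffled_scaffolds)

    for name, (chrom, offset, strand) in sorted(ref_map.items()):
        L = genome.scaffold_lengths[name]
        tlen = offset + L + block
        starts = np.arange(0, L - within_gap, block)
        if name in shuffled:
            other = next((c for c in chroms if c != chrom), f"{chrom}_alt")
            n_own = max(1, int(round(len(starts) * 0.3)))
            scatter_gap = 50_000
            for i, qs in enumerate(starts):
                qe = min(int(qs) + block - within_gap, L)
                alen = qe - qs
                if alen <= 0:
                    continue
                if i < n_own:
                    ts = offset + int(qs)
                    rec_chrom, tl = chrom, tlen
                else:
                    ts = i * (block + scatter_gap)
                    rec_chrom, tl = other, (len(starts) + 1) * (block + scatter_gap)
                ref_records.append(AlignmentRecord(
                    name, L, int(qs), qe, "+", rec_chrom, tl, ts, ts + alen,
                    int(round(identity * alen)), alen))
            continue
        for qs in starts:
            qe = min(int(qs) + block - within_gap, L)
            alen = qe - int(qs)
            if alen <= 0:
                continue
            if strand == "+":
                ts = offset + int(qs)
            else:
                ts = offset + (L - qe)
            ref_records.append(AlignmentRecord(
                name, L, int(qs), qe, strand, chrom, tlen, ts, ts + alen,
                int(round(identity * alen)), alen))

    masked = genome.masked_lengths()
    self_records: list[AlignmentRecord] = []
    dup_truth: dict[str, str] = {}
    autosomes = [s for s in genome.scaffolds if s.label == AUTOSOME]
    for i in range(min(n_duplicates, len(autosomes))):
        orig = autosomes[i]
        dup_name = f"dup{i + 1}_{orig.name}"
        dup_len = orig.length // 2
        dup_masked = int(round(dup_len * (1.0 - genome.config.repeat_fraction_genome)))
        masked[dup_name] = dup_masked
        span = int(round(duplicate_overlap * dup_masked))
        span = min(span, dup_len)
        if span > 0:
            self_records.append(AlignmentRecord(
                dup_name, dup_len, 0, span, "+", orig.name, orig.length, 0, span,
                int(round(duplicate_identity * span)), span))
        dup_truth[dup_name] = orig.name
    return SimAlignments(ref_records, self_records, dup_truth, masked, shuffled)
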