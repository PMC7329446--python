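# stratascan

Discovery and characterization of nascent ZW sex chromosomes from
male/female resequencing data mapped to a female genome assembly.

In species with very young sex chromosomes — willows and poplars being the
canonical plant examples — the W chromosome has barely diverged from the
Z, so the sex-determining region (SDR) cannot be found by sequence
divergence alone.  stratascan implements the window-scan approach that
works at this stage: per-site nucleotide profiles (A/C/G/T read counts)
from one female (ZW) and one male (ZZ) are summarized in 10-kb windows as
normalized read depth and SNP density, and the log2 female:male ratios of
both are tested against autosomal null envelopes.  An old stratum shows a
female coverage deficit (log2 ≈ −1: only her single Z still maps); a
young stratum shows near-equal coverage but excess female SNP density
(W-specific polymorphism accumulating on a still-mappable W); W-specific
scaffolds show female-only coverage over their entire length.  Downstream
modules quantify W degeneration (repeat enrichment, pseudogenization
calls at 80% query coverage), deduplicate and anchor the assembly through
generic pairwise-alignment records, estimate gametolog divergence at
synonymous and non-synonymous sites (d_S, d_N; Nei–Gojobori counting and a
Yang–Nielsen-2000-style approximate method with F3×4 frequencies and
iterated kappa/omega), and date recombination suppression relative to
speciation from neighbor-joining gene-tree topologies of the phased
Z/W/congener/outgroup haplotypes.

A first-class synthetic-data module generates truth-labeled ZW genomes
with exactly this signal structure (heterozygosity 0.5%, configurable
stratum divergences, Poisson depths, repeat-enriched W scaffolds,
gametolog trees), so every decision rule in the pipeline is validated by
parameter-recovery tests rather than by eye.

## Worked example

Run the default simulation study (≈31 Mb: 20 autosomes, 1
pseudo-autosomal, 2 stratum-I, 1 stratum-II, 2 W-specific scaffolds at
60× per sex) through classification and delimitation:

```python
from stratascan import pipeline

cfg = pipeline.RunConfig(seed=1)
genome, windows, calls, segments, _ = pipeline.run_classification(cfg)
truth = genome.labels()
for name in sorted(calls):
    if calls[name].call != "AUTOSOMAL_LIKE":
        c = calls[name]
        print(name, truth[name], "->", c.call, round(c.mean_log2_cov, 3))
for s in segments:
    print("stratum", s.stratum, s.start, s.end, s.scaffolds)
```

prints

```
str1_1 STRATUM1_Z -> Z_DIVERGED -0.874
str1_2 STRATUM1_Z -> Z_DIVERGED -0.874
str2_1 STRATUM2 -> RECENT_SDR 0.0
w1 W_SPECIFIC -> W_SPECIFIC 2.585
w2 W_SPECIFIC -> W_SPECIFIC 2.585
stratum II 1200000 2400000 ('str2_1',)
stratum I 2400000 4800000 ('str1_1', 'str1_2')
```

Reading the numbers: the stratum-I scaffolds sit at a mean log2 F:M
coverage ratio of −0.874 = log2(0.6/1.1) — the female retains one mapped
Z copy, exactly half the male's depth after the 0.1 pseudocount — while
the W-specific scaffolds sit at +2.585 = log2(0.6/0.1), female-only
coverage.  The young stratum is invisible in coverage (0.0) and is called
from its female SNP excess instead.  Both strata are recovered with
boundaries at the planted scaffold limits, PAR and autosomes stay
unflagged, and the SDR spans 3.6 Mb.

The same run through the sequence-level stages (`pipeline.run_all(cfg)`)
adds gametolog divergence — mean d_S 0.0128 in stratum I vs 0.0048 in the
genome background, Mann–Whitney p = 2.1e-08 — and gene-tree topology
calls: 100% of stratum-I genes show the W haplotype branching outside the
other three within-species haplotypes at bootstrap support > 75%
(suppression before speciation), while 100% of stratum-II genes keep all
four haplotypes monophyletic (suppression after speciation).

The command-line interface exposes each stage over standard formats
(profiles TSV, PAF, GFF3, FASTA, Newick):

```bash
stratascan simulate --seed 1 --outdir simdata/
stratascan windows --female simdata/female.pro --male simdata/male.pro \
    --lengths simdata/lengths.tsv --out windows.tsv
stratascan run-all --seed 1 --outdir results/
```

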