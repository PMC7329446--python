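# Methods

stratascan implements the read-mapping approach to discovering a nascent
sex-determining region (SDR) in a female-heterogametic (ZW) species whose
reference assembly comes from the heterogametic sex, together with the
downstream analyses of W-specific sequence, its degeneration, and the
relative age of recombination suppression.  This note documents the model
behind each stage, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## The signal model

When female and male short reads are mapped to a female (ZW) assembly,
regions of the genome separate into characteristic signatures of the log2
female:male ratios of normalized read depth and normalized SNP density:

| region | log2 F:M coverage | log2 F:M SNP density | reason |
|---|---|---|---|
| autosome / PAR | ~0 | ~0 | diploid in both sexes |
| old stratum (Z backbone) | ~−1 | strongly negative | female W reads too diverged to map; her single Z gives half depth and no heterozygosity |
| young stratum | ~0 | positive | W still maps to the Z backbone; female accumulates W-specific SNPs before divergence reduces mapping |
| W-specific scaffold | strongly positive | undefined in males | sequence present only in females |

Depth at a profiled site is the sum of the four base counts; the profiles
are assumed to be produced from alignments already filtered for mapping
quality and duplicates (that filtering is upstream of this package).  A
site enters SNP calling at depth ≥ 5 and is a SNP iff exactly two bases
have non-zero counts and the minor allele frequency is ≥ 0.30.  "Exactly
two" is deliberate: a third allele at any count disqualifies the site,
which is conservative and deterministic.  Window coverage is the mean over
*all* positions of a window (absent profile positions count as depth 0);
SNP density is SNPs per *passing* site and is undefined in windows with no
passing site.  Windows are 10 kb, non-overlapping, 0-based half-open
internally; the trailing partial window keeps its true size.

Both statistics are normalized per individual by the genome-wide median
window value before forming `log2((f + 0.1)/(m + 0.1))`; the 0.1
pseudocount bounds the ratio when one sex has no signal (log2(0.1/1.1) =
−3.459 is the floor for f = 0, m = 1).  Normalizing SNP density by the
individual's median window density (rather than only by passing-site
counts) is a documented choice; it makes the two sexes' densities
comparable when their sequencing depths differ.

## Null envelopes and scaffold calls

The null class is the autosomal window set, excluding the entire sex
chromosome including the PAR (linkage to the SDR would contaminate the
null).  Two layers of evidence are required for a scaffold-level call,
both at their default levels:

* a **bootstrap envelope**: 1000 resamples of 25 windows, each averaged;
  the 2.5/97.5 percentiles of those 1000 means form the 95% CI that a
  scaffold's mean log2 ratio must breach;
* a **permutation test**: the scaffold's mean is compared with 10,000
  draws of the same number of windows from the autosomal pool without
  replacement, one-sided, with the add-one estimator
  p = (1 + #extreme)/(1 + 10,000), so p is never 0.

Requiring the conjunction keeps the per-scaffold false-positive rate at or
below the permutation level (measured ≈ 0 in pure-autosome simulations,
bounded by α = 0.05).  The decision table: coverage deficit ⇒ old-stratum
signature (Z_DIVERGED), SNP excess without a coverage anomaly ⇒
young-stratum signature (RECENT_SDR), otherwise autosome-like.  Scaffolds
of equal window count share one permutation null distribution (identical
pool and statistic), which is a pure caching optimization.

W-specific detection runs first: scaffolds whose normalized female
coverage is below 10% of the genome average are set aside as unmappable
(LOW_COVERAGE_EXCLUDED — repeat-dense W candidates are expected to hide
here, so the W census is conservative), and a scaffold is W-specific iff
its scaffold-level log2 coverage ratio exceeds the CI upper bound *and*
every 25-window-smoothed window stays above it — the whole-length rule
that rejects Z-W chimeric scaffolds.  The "excess over the genome
average" rule is operationalized as breaching the bootstrap CI, since a
literal "> 95% of the average" is not a defined statistic.

## SDR delimitation

Strata are delimited on sex-chromosome scaffolds ordered by their anchored
position.  Scaffold calls project onto chromosome coordinates; adjacent
same-stratum segments merge.  Delimitation is at scaffold resolution
because scaffold boundaries are the natural resolution of the call (window
SNP ratios carry ~0.3 bits of noise per window at 60× depth, far too noisy
for window-level stratum-II calls), with one refinement: inside
Z_DIVERGED scaffolds, runs of windows below the autosomal *window-level*
0.1% quantile delimit the Z-backbone portion, which trims W-chimeric
insertions (female-only material assembled into a Z scaffold) out of
stratum I.  In simulation, recovered boundaries coincide with the planted
truth to within one window.

## W degeneration

Repeat enrichment on W-specific scaffolds is tested with one-sided
Mann–Whitney rank-sum tests of per-10-kb-window repeat fractions: W vs the
genomic background and W vs the Z-linked SDR portion.  Gene loss is called
from translated-search records of Z-linked proteins against the homologous
W scaffold: with best-hit query coverage ≥ 80%, one or more frame
disruptions (premature stop, frameshift) ⇒ pseudogenized, none ⇒ present;
below 80% coverage the gene is simply not recovered.  The disruption flag
must be provided by the upstream search; coverage alone never calls a
pseudogene.

## Assembly dedup and anchoring

A scaffold is an allelic variant (haplotig) iff its alignments at identity
strictly above 0.80 to a strictly longer scaffold cover strictly more than
25% of its repeat-masked length; "longer" is compared on masked lengths so
a single input serves both roles.  The removal set is computed on the full
record set before any removal, so it is independent of input order.

Anchoring chains a scaffold's reference alignments into tiling paths:
neighboring records on one chromosome link when both the target gap *and*
the query gap are under 10 kb (requiring both prevents chaining across
large query insertions).  The longest path (by aligned query bp) assigns
the chromosome; orientation is FORWARD/REVERSE when one strand holds
strictly more than 70% of the path's aligned bp, otherwise the original
orientation is kept.  Scaffolds with under 10% of their length aligned are
discarded (and never receive an assignment).  A scaffold is *unlocalized*
when the longest path's chromosome does not hold the majority of total
aligned bp, or the path's target span overlaps less than half of the
scaffold's overall aligned span there — an explicit operationalization of
"the longest tiling path disagrees with the overall alignment path",
which has no canonical formula.

The annotation lift-over filter bootstraps the mean per-gene count of
aligned haplotypes (1000 resamples over genes; two haplotypes expected in
fully phased diploid regions) and excludes genes falling below the lower
2.5% bound of the bootstrap means (≈1.6× in a mostly-diploid set) as
likely paralogous placements.

## Gametolog divergence (dS/dN)

Input CDS pass QC iff they start with ATG, contain no internal stop, are
≥ 120 nt and a codon multiple (the triplet requirement is enforced here
because codon counting needs frame; non-triplet input fails QC rather than
being trimmed).  Terminal stops are stripped; aligned codon columns
containing a gap or ambiguity in either sequence are dropped pairwise
(dropping single columns would break frame).

**NG86.**  Sites per codon: over the nine point mutations, those creating
stops are excluded and the synonymous fraction of the remainder is scaled
to 3 sites, so S + N = 3·codons exactly.  This per-codon normalization is
chosen (over per-position variants that differ only at stop-adjacent
codons) because it is precisely the kappa = 1, uniform-frequency limit of
the weighted counter below, making the reduction property exact.
Differences are averaged over all minimal mutation pathways with equal
weights, pathways through stops excluded (if all pathways are blocked they
are weighted equally with stop-adjacent steps counted non-synonymous — a
degenerate case that essentially never arises in QC-passed data).
Distances use the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3),
flagged SATURATED (not raised) when undefined.

**YN00-style.**  Codon frequencies are F3×4 from the pair; kappa is
estimated once from fourfold-degenerate and nondegenerate site classes
(conservatively, positions whose degeneracy class agrees in both codons)
via the Kimura two-parameter formulas, weighted by class size, clamped to
[0.05, 50] with a fallback of 2 when no class is informative (e.g.
identical pairs, where kappa is irrelevant).  Site counting weights each
non-stop mutation by kappa (transitions) and the target codon frequency.
Pathways are weighted by kappa^(transitions) · omega^(non-synonymous) ·
Π frequency(target); the two directions are averaged so the estimate is
exactly symmetric in the input sequences.  dS and dN are corrected with
K80 applied separately to the transition/transversion proportions at
synonymous and non-synonymous sites, and omega = dN/dS is iterated to
convergence (tolerance 1e-8, bound 100 iterations; NO_CONVERGENCE flagged
otherwise).  Exhaustive-enumeration tests pin the NG86 counts, and the
kappa = 1/uniform reduction plus parameter-recovery simulations validate
the weighted path.

Pairs with dS > 0.2 are excluded before region comparison (such divergence
at these time scales indicates ortholog mis-assignment, not gametolog
divergence).  Region comparison reports per-region means and two-sided
Mann–Whitney U p-values against the genome background (which must exclude
the sex chromosome); regions with fewer than two genes report a mean only.

## Gene trees and the age of suppression

Ortholog-group alignments are filtered by removing columns with > 40%
gaps, then taxa with > 40% missing data, then re-checking columns once
(the fixed order is a documented choice; the thresholds do not prescribe
one).  Trees are built by neighbor joining on JC69 distances over pairwise
comparable columns, with support from a 100-replicate column-resampling
bootstrap — a deliberate, validated stand-in for maximum-likelihood
inference: NJ is consistent on additive matrices (tested exactly), and on
simulated gametologs at willow-like depths it recovers every planted
pattern.  Precomputed Newick trees with support labels are accepted
directly.

Classification reads the tree rooted on the outgroup and works on
bipartitions.  For each candidate female haplotype, the smallest clade
containing the other three within-species haplotypes is found; if it
excludes the candidate and its bipartition is supported above 0.75, the
gene shows the **W-divergent** pattern (suppression before speciation) and
the candidate is the inferred W.  When congener taxa are present, a
supported monophyly of all four within-species haplotypes is classified
**W-recent** *before* the divergent test is tried: a slightly diverged W
can be placed basal within the species clade by long-branch attraction
with deceptively high support, and supported species-clade monophyly is
direct evidence that the W joined after speciation.  Without congeners the
two patterns cannot be distinguished this way and the divergent test runs
first.  Genes missing either female haplotype are skipped; everything
else is unresolved.  A supplementary flag records whether the W attaches
outside the species + congener clade (pre-congener-split divergence).

## The synthetic genome generator

`sim.SimulationConfig` defaults define the study conditions: 26 scaffolds
of 1.2 Mb (≈31 Mb) — 20 autosomes, 1 PAR, 2 stratum-I, 1 stratum-II, 2
W-specific — heterozygosity 0.005 (1 SNP per 200 bp), stratum-I Z/W
divergence 0.012, stratum-II divergence 0.002 *on top of* ambient
polymorphism (a recently suppressed W differs from its Z by the ancestral
coalescent heterozygosity plus post-suppression divergence; the raw
increment alone would place female SNP density below the male's and
invert the signal), 60× depth per sex, repeat fractions 0.35
genome-wide / 0.60 on the W.  Per-site depths are Poisson; heterozygous
sites split reads Binomial(depth, 1/2).  Female stratum-I profiles are
haploid at half depth (the diverged W reads are modelled as unmapped);
male depth on W scaffolds defaults to 0 with a configurable mismapping
rate, since the real mismapping background is not quantified.  Stratum-I
scaffolds can carry configurable W-chimeric segments (female-only
coverage inside a Z backbone) to emulate Z-W chimeric assembly.  Repeat
annotations are 1-kb tiles marked at the target fraction and merged.

Sequences follow Jukes–Cantor; in coding simulations a substitution that
creates a stop codon is rejected, which depresses realized divergence by
roughly 4% relative to nominal (visible in parameter-recovery runs, e.g.
mean estimated dS ≈ 0.0093 at nominal 0.01, well inside the 10%
recovery band).  Gametolog trees use fixed node depths
(substitutions/site per lineage): outgroup 0.06, congener1 0.03,
congener2 0.02, within-species
root 0.004, coalescent 0.0025, stratum-I W split 0.035 (before the
congener splits), stratum-II W join 0.0035 (inside the species clade,
sister to the female Z).  These are chosen once as willow-plausible
magnitudes that make 1500-nt alignments informative.  Which female
haplotype carries the W is randomized per gene, so classification cannot
exploit labels.

All randomness derives from one root seed through per-scaffold,
per-component substreams: any output (a FASTA, one sample's profile, one
gene's alignment) can be regenerated independently and is byte-identical
across runs.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: read-level artifacts (sequencing error,
mapping-quality structure, duplicates), indels and structural variants,
linked-read barcodes, rate variation among sites and lineages,
selection on codon usage (kappa ≈ 1 in simulated data), assembly
fragmentation beyond planted haplotigs, and annotation errors.  The
simulator validates the statistical machinery and decision rules, not the
upstream bioinformatics.

## Problem sizes and degenerate inputs

Default analysis runs use the ≈31 Mb genome, 100–150 gametolog pairs of
300 codons, and 50 tree genes of 500 codons with 100 bootstrap
replicates — sizes at which every stage's signal is comfortably resolved
and a full end-to-end run takes well under a minute on one CPU.
Degenerate inputs are handled explicitly: all-zero coverage refuses to
normalize with a pointer to the input; saturation and non-convergence are
flags, not exceptions; empty window sets, empty gene sets and missing
outgroups raise informative errors; three-taxon trees yield an empty
support set rather than fabricated supports.

## Known limitations

* The classifier assumes the sex chromosome is known a priori (from
  linkage evidence) so the autosomal null can exclude it; it does not
  discover the sex chromosome de novo.
* Scaffold-level calls assume one dominant signature per scaffold; heavily
  interleaved chimeras are reported via window refinement but the
  scaffold-level call remains the majority signature.
* The YN00-style estimator is an approximate counting method; at dS
  below ~0.001 per-gene estimates are dominated by discreteness (0 or 1
  synonymous differences in a 300-codon gene), and for short genes at low
  divergence the per-gene kappa estimate is noisy, giving region means a
  mild downward bias (~10–15% at 300 codons and dS 0.005 in simulation).
  Region *contrasts* — the quantity the analysis reports — are rank-based
  and unaffected by this shared bias.
* NJ + JC69 + column bootstrap approximates ML tree inference; its
  adequacy is demonstrated on the simulator, not proven for arbitrary
  real alignments (precomputed ML trees are accepted as input for that
  reason).
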