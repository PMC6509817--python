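# Methods

## The screening model

The pipeline assumes a strain lineage in which a focal mutant and its
relatives were resequenced against one reference genome and their
variants called by a GATK-like caller that emits per-site quality
metrics (QD, MQ, FS, HaplotypeScore, MQRankSum, ReadPosRankSum, DP) and
a single-sample genotype. A locus counts as a variant when the sample's
genotype differs from the reference base, whether heterozygous or
homozygous-alt; reference-matching and uncalled genotypes are dropped on
ingest. The screen's premise is genetic: variants shared with the parent
or a sibling cannot explain a phenotype that distinguishes the focal
strain from both, so only the focal-exclusive ("unique") variants are
carried forward, and the unit of follow-up is the *gene* — any gene
whose promoter, exon, intron or terminator is touched by a unique
variant becomes a knockout candidate.

## Coordinates and variant representation

Everything internal is 1-based with fully closed intervals, matching
GFF3 and VCF; no half-open conversion happens anywhere. Indels use the
VCF anchored representation (first base shared). The affected reference
span used for all interval overlap is: the single base for SNPs and
insertions (an insertion sits between bases, so only its anchor base can
witness an overlap), and `[pos+1, pos+len(ref)-1]` for deletions.
Multi-allelic records are split into one record per alt allele actually
carried by the genotype before any downstream stage. VCF INFO floats are
stored as 32-bit by htslib, so metric values are rounded to 4 decimals on
ingest; with that convention write→read round-trips are exact.

## Hard filter

Thresholds are strict inequalities exactly as configured (DP = 4 and
DP = 200 pass the default depth window of 4–200). The SNP rule set is
{QD < 2.0, MQ < 40.0, FS > 60.0, HaplotypeScore > 13.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0}; the indel set is {QD < 2.0,
ReadPosRankSum < −20.0, FS > 200.0}; the depth window applies to both
classes. This grouping follows the long-standing GATK hard-filter
convention: HaplotypeScore and the mapping-quality statistics are
SNP-filter metrics, and the looser rank-sum/FS pair is the indel set.
A rule whose metric is absent from a record is skipped and logged, never
failed — callers routinely omit rank-sum statistics at homozygous sites,
and failing on absence would discard valid homozygous calls. A verdict
lists every rule a record fails, not just the first.

The clustered-SNP rule marks a SNP as failed when at least one window of
10 consecutive reference bases on its contig contains 3 or more SNPs
(window length and count are configurable; indels neither trigger nor
receive the rule). The implementation anchors candidate windows at each
SNP and marks everything inside a qualifying window; a test proves it
equivalent to exhaustive enumeration of all windows.

## Elements and effects

Gene models are CDS-based: there is no UTR category, "exon" means coding
exon, and the promoter/terminator windows are anchored on the start and
stop codons (not a TSS). Defaults are 1000 bp and 500 bp, the windows a
practitioner would scan for cis-regulatory and 3′-processing mutations
in a compact fungal genome; both are parameters of
`build_element_index`. Windows are clipped at contig edges and the base
immediately adjacent to the start codon is promoter position 1. All
overlaps are reported with no precedence: a variant between two close
genes hits one's terminator and the other's promoter, and a
boundary-spanning deletion reports both exon and intron. Suppressing any
of these would silently lose table rows downstream, and the double-count
semantics of the cross-tab (element columns may sum past the variant
totals) is deliberate and documented in the table.

Effect calling mutates the affected codon of the spliced CDS (exons
concatenated in reference order, reverse-complemented for − genes, alt
base complemented likewise) and translates with the standard genetic
code — all genes here are nuclear. Residues are numbered from the
initiator Met = 1. Stop-gains are reported as nonsynonymous with alt
residue `Ter` and start-losses as nonsynonymous at position 1; there are
no separate nonsense/start-loss categories. Exonic indels are classified
by the net coding-length change mod 3; for a deletion straddling an
exon/intron boundary only the exonic bases count and the label is
flagged `splice-adjacent`. Codons carrying several SNPs are evaluated
one variant at a time, matching per-variant reporting. Gene models whose
CDS length is not divisible by 3 are accepted with a warning and their
effect calls marked unreliable.

## Lineage subtraction and candidates

Variant identity is the exact (contig, pos, ref, alt) key; genotype
class is ignored, and a different alt at the same site stays distinct.
When a genome is supplied, indels are left-aligned (trim shared trailing
bases, extend left when an allele would empty, trim shared leading bases
back to one anchor) before matching, which prevents differently
normalized comparison lists from manufacturing spurious unique indels.
Comparison strains are listed explicitly; there is no transitive
pedigree traversal. Candidate genes are the distinct gene ids hit by
unique variants, each reported once (even when hit in two elements),
sorted by gene id for a stable order.

## What the generator emulates — and what it does not

The synthetic module generates random ACGT contigs, packs them with
non-overlapping gene bodies (every CDS starts ATG, ends with a stop,
has length divisible by 3 and no internal stop; about half the genes on
each strand; 2–4 exons separated by short introns), and plants variants
by construction: a nonsynonymous planting picks an internal codon and an
alt base whose translation differs, a frameshift planting a 1–2 bp
exonic indel away from boundaries, and so on. Quality metrics are drawn
uniformly from passing ranges except for planted failures, which violate
exactly their designated rule; rank-sum metrics are omitted from a
fraction of homozygous records to exercise the absent-metric path. Three
geometric guarantees make the ledger's truth exact rather than merely
probable: intergenic gaps exceed two facing promoter windows, so no
element of one gene overlaps an element of another; genes keep a margin
from contig ends, so windows are never clipped; and planted variants are
spaced more than a cluster window apart (deliberate cluster triplets
excepted). The default fixture is therefore ~72 kb for 20 genes — the
window-disjointness constraint, not gene size, sets the footprint.

The pedigree is two generations deep: an ancestor that *is* the
reference (empty variant set), a parent, and two children who inherit a
seeded random subset of the parent's passing variants and add their own.
The study-scale configuration (`SimConfig.study`) encodes the published
lineage counts as budgets: parent 126 SNPs + 22 indels; one child adding
97 + 11; the focal child inheriting 107 + 10 and adding 77 + 30, whose
in-element subset is spread over exactly 57 distinct genes (unique-subset
element budgets: SNPs 18 promoter / 22 terminator / 5 intron / 4
synonymous + 13 nonsynonymous exonic / 15 intergenic; indels 5 / 11 / 5 /
1 frameshift / 8 intergenic). The focal strain's element hits are planted
first, one per chosen gene, which is what makes the distinct-gene count
exact; later plantings that find a gene's small introns crowded simply
move elsewhere.

The generator does not model read-level noise, sequencing error,
realistic metric distributions (the filter is threshold-based, so only
the side of the threshold matters), GC content or repeats, linked
haplotypes, or genuine false-positive calls. Passing tests therefore
show that the *logic* — interval arithmetic, codon accounting, rule
evaluation, set algebra — is correct, not that the thresholds are well
chosen for any particular sequencing run.

## Problem sizes and numerical choices

The test suite runs the small fixture (two 36 kb contigs, 20 genes,
~90 variants across strains) for unit and property tests, seven seeds of
it for the label-recovery check (>500 planted rows), and two seeds of
the study-scale fixture (four 68 kb contigs, 70 genes, ~630 variant
rows) for the end-to-end totals; the acceptance script uses one
study-scale replicate plus 100 random instances for the cluster-filter
oracle. These sizes keep the whole suite in a few seconds while every
count being asserted is still recomputed from scratch. Ties and
degenerate inputs: empty variant sets are valid everywhere and produce
empty reports; genes flush against a contig edge have no promoter (or a
shortened one); candidate tables are sorted by gene id; per-gene
mutation labels are joined in variant-coordinate order.

## Known limitations

No UTR or TSS inference, no splice-site strength model, no
deleteriousness scores — the element scheme is deliberately the coarse
promoter/exon/intron/terminator vocabulary of a knockout pre-screen.
Multi-sample VCFs and phased genotypes are out of scope (one VCF per
strain). Candidate genes are not ranked; the screen's output order is
alphabetical, because any ranking would import assumptions (expression,
conservation) the variant data alone cannot support.
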