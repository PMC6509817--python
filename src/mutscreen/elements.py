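"""Genomic-element intervals and variant-to-element classification.

Each gene contributes four element kinds, all 1-based closed reference
intervals clipped to contig bounds:

* promoter — the 1 kb immediately upstream of the start codon on the coding
  strand (``[cds_start-1000, cds_start-1]`` for ``+`` genes, mirrored for
  ``-``);
* exon — the CDS segments themselves (the gene models are CDS-based, so
  exon means coding exon and there is no UTR category);
* intron — the gaps between consecutive CDS segments;
* terminator — the 500 bp immediately downstream of the stop codon.

A variant may overlap elements of several genes and several elements of one
gene; every overlap is reported, none suppressed.  That over-count is
deliberate: per-gene tallies of promoter and terminator hits can otherwise
silently lose a variant sitting between two adjacent genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .formats import GeneModel, GenomeSequence, VariantRecord, genome_index

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
TERMINATOR = "terminator"
ELEMENT_KINDS = (PROMOTER, TERMINATOR, INTRON, EXON)

DEFAULT_PROMOTER_BP = 1000
DEFAULT_TERMINATOR_BP = 500


@dataclass(frozen=True)
class GeneElements:
    """Element intervals of one gene (1-based closed; windows may be empty
    at contig edges, encoded as None)."""

    gene_id: str
    contig_id: str
    strand: str
    promoter: tuple[int, int] | None
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]
    terminator: tuple[int, int] | None

    def intervals(self):
        if self.promoter:
            yield PROMOTER, self.promoter
        for e in self.exons:
            yield EXON, e
        for i in self.introns:
            yield INTRON, i
        if self.terminator:
            yield TERMINATOR, self.terminator


@dataclass(frozen=True)
class ElementHit:
    variant: VariantRecord
    gene_id: str
    element: str
    strand_of_gene: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_KINDS:
            raise ValidationError(f"unknown element kind {self.element!r}")


class ElementIndex:
    """Interval index over every gene's elements, one tree per contig."""

    def __init__(
        self,
        genes: Mapping[str, GeneElements],
        trees: Mapping[str, IntervalTree],
        promoter_bp: int,
        terminator_bp: int,
    ):
        self.genes = dict(genes)
        self._trees = dict(trees)
        self.promoter_bp = promoter_bp
        self.terminator_bp = terminator_bp

    def overlapping(self, contig_id: str, start: int, end: int):
        """(gene_id, element, strand) tuples overlapping [start, end]."""
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})


def _window(start: int, end: int, contig_len: int) -> tuple[int, int] | None:
    start, end = max(start, 1), min(end, contig_len)
    return (start, end) if start <= end else None


def gene_elements(
    gene: GeneModel,
    contig_len: int,
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    terminator_bp: int = DEFAULT_TERMINATOR_BP,
) -> GeneElements:
    """Derive the four element interval sets of one gene, strand-aware."""
    low, high = gene.span
    if gene.strand == "+":
        promoter = _window(low - promoter_bp, low - 1, contig_len)
        terminator = _window(high + 1, high + terminator_bp, contig_len)
    else:
        promoter = _window(high + 1, high + promoter_bp, contig_len)
        terminator = _window(low - terminator_bp, low - 1, contig_len)
    introns = tuple(
        (e1_end + 1, e2_start - 1)
        for (_, e1_end), (e2_start, _) in zip(gene.cds_exons, gene.cds_exons[1:])
        if e2_start - e1_end > 1
    )
    return GeneElements(
        gene_id=gene.gene_id,
        contig_id=gene.contig_id,
        strand=gene.strand,
        promoter=promoter,
        exons=gene.cds_exons,
        introns=introns,
        terminator=terminator,
    )


def build_element_index(
    models: Sequence[GeneModel],
    genome: Iterable[GenomeSequence],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    terminator_bp: int = DEFAULT_TERMINATOR_BP,
) -> ElementIndex:
    contigs = genome_index(genome)
    genes: dict[str, GeneElements] = {}
    trees: dict[str, IntervalTree] = {}
    for gene in models:
        if gene.contig_id not in contigs:
            raise ValidationError(
                f"gene {gene.gene_id}: unknown contig {gene.contig_id}"
            )
        elems = gene_elements(
            gene, len(contigs[gene.contig_id]), promoter_bp, terminator_bp
        )
        genes[gene.gene_id] = elems
        tree = trees.setdefault(gene.contig_id, IntervalTree())
        for kind, (start, end) in elems.intervals():
            tree[start : end + 1] = (gene.gene_id, kind, gene.strand)
    return ElementIndex(genes, trees, promoter_bp, terminator_bp)


def classify_variant(variant: VariantRecord, index: ElementIndex) -> list[ElementHit]:
    """All (gene, element) overlaps of the variant's affected span.

    An empty result means the variant is intergenic.  A deletion spanning an
    exon/intron boundary reports both elements.
    """
    start, end = variant.affected_span()
    return [
        ElementHit(variant, gene_id, element, strand)
        for gene_id, element, strand in index.overlapping(
            variant.contig_id, start, end
        )
    ]


def classify_all(
    variants: Iterable[VariantRecord], index: ElementIndex
) -> list[ElementHit]:
    hits: list[ElementHit] = []
    for v in variants:
        hits.extend(classify_variant(v, index))
    return hits


@dataclass
class ElementCrosstab:
    """Counts per (variant class x element kind) with intergenic and
    genes-affected tallies.  A variant hitting two elements contributes to
    both cells, so element columns can sum past the variant count."""

    counts: pd.DataFrame
    intergenic: dict[str, int] = field(default_factory=dict)
    genes_affected: dict[str, int] = field(default_factory=dict)
    n_variants: dict[str, int] = field(default_factory=dict)


def tabulate_elements(
    hits: Sequence[ElementHit], variants: Sequence[VariantRecord]
) -> ElementCrosstab:
    classes = ("SNP", "indel")
    counts = pd.DataFrame(0, index=list(ELEMENT_KINDS), columns=list(classes))
    genes: dict[str, set[str]] = {c: set() for c in classes}
    hit_keys: set[tuple] = set()
    for h in hits:
        cls = "SNP" if h.variant.is_snp else "indel"
        counts.loc[h.element, cls] += 1
        genes[cls].add(h.gene_id)
        hit_keys.add(h.variant.key)
    intergenic = {c: 0 for c in classes}
    n_variants = {c: 0 for c in classes}
    for v in variants:
        cls = "SNP" if v.is_snp else "indel"
        n_variants[cls] += 1
        if v.key not in hit_keys:
            intergenic[cls] += 1
    genes_affected = {c: len(genes[c]) for c in classes}
    genes_affected["any"] = len(genes["SNP"] | genes["indel"])
    return ElementCrosstab(
        counts=counts,
        intergenic=intergenic,
        genes_affected=genes_affected,
        n_variants=n_variants,
    )
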