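"""Coding-consequence calls for variants hitting gene elements.

Exonic SNPs are classified synonymous/nonsynonymous by mutating the
affected codon of the spliced CDS and translating with the standard genetic
code (all genes here are nuclear); exonic indels are frameshift or in-frame
by the net coding-length change mod 3; promoter/terminator/intron hits are
noncoding.  Labels follow a compact dialect: ``"T -> C"`` style base
changes with the element in parentheses, e.g.

* ``T -> C (exon: Cys193 -> Arg)``   nonsynonymous SNP
* ``A -> G (exon: synonymous variant)``
* ``- 16: GATGACGATGATTTTC (terminator)``  16 bp deletion
* ``+ 3: TCT (exon)``                in-frame insertion

Protein positions are 1-based with the initiator Met as residue 1; a SNP
creating a stop codon is nonsynonymous with alt residue ``Ter`` (there is
no separate nonsense category).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .elements import EXON, ElementHit
from .errors import MutscreenError, ValidationError
from .formats import (
    DELETION,
    GeneModel,
    GenomeSequence,
    VariantRecord,
    genome_index,
    reverse_complement,
)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
FRAMESHIFT = "frameshift"
INFRAME_INDEL = "inframe_indel"
NONCODING = "noncoding"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class EffectCall:
    variant: VariantRecord
    gene_id: str
    kind: str
    label: str
    aa_ref: Optional[str] = None
    aa_pos: Optional[int] = None
    aa_alt: Optional[str] = None
    reliable: bool = True


def spliced_cds(
    gene: GeneModel, genome: Iterable[GenomeSequence] | Mapping[str, GenomeSequence]
) -> str:
    """Concatenated CDS in coding orientation, starting at the start codon."""
    contigs = genome if isinstance(genome, Mapping) else genome_index(genome)
    contig = contigs[gene.contig_id]
    seq = "".join(contig.slice(s, e) for s, e in gene.cds_exons)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate_cds(cds: str) -> str:
    """Standard-code translation; trailing stop kept as ``*``."""
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def cds_offset(gene: GeneModel, ref_pos: int) -> int:
    """0-based offset of a reference position within the spliced CDS."""
    seen = 0
    plus_offset = None
    for start, end in gene.cds_exons:
        if start <= ref_pos <= end:
            plus_offset = seen + (ref_pos - start)
            break
        seen += end - start + 1
    if plus_offset is None:
        raise MutscreenError(
            f"position {ref_pos} not exonic in gene {gene.gene_id}"
        )
    if gene.strand == "-":
        return gene.cds_length - 1 - plus_offset
    return plus_offset


def _aa3(residue: str) -> str:
    return "Ter" if residue == "*" else seq3(residue)


def _exonic_overlap(gene: GeneModel, span: tuple[int, int]) -> int:
    """Number of CDS bases inside the (closed) reference span."""
    a, b = span
    total = 0
    for start, end in gene.cds_exons:
        lo, hi = max(a, start), min(b, end)
        if lo <= hi:
            total += hi - lo + 1
    return total


def _indel_label(variant: VariantRecord, element: str, extra: str = "") -> str:
    if variant.variant_class == DELETION:
        seq = variant.ref_allele[len(variant.alt_allele) :]
        sign = "-"
    else:
        seq = variant.alt_allele[len(variant.ref_allele) :]
        sign = "+"
    suffix = f" ({element}{extra})"
    return f"{sign} {len(seq)}: {seq}{suffix}"


def call_effect(
    variant: VariantRecord,
    hit: ElementHit,
    gene: GeneModel,
    genome: Iterable[GenomeSequence] | Mapping[str, GenomeSequence],
) -> EffectCall:
    """Consequence of one (variant, element hit) pair."""
    if hit.gene_id != gene.gene_id:
        raise MutscreenError("hit does not belong to the supplied gene")
    contigs = genome if isinstance(genome, Mapping) else genome_index(genome)

    if hit.element != EXON:
        if variant.is_snp:
            label = f"{variant.ref_allele} -> {variant.alt_allele} ({hit.element})"
        else:
            label = _indel_label(variant, hit.element)
        return EffectCall(variant, gene.gene_id, NONCODING, label)

    reliable = gene.cds_length % 3 == 0
    if variant.is_snp:
        cds = spliced_cds(gene, contigs)
        off = cds_offset(gene, variant.pos)
        alt = (
            variant.alt_allele.translate(_COMPLEMENT)
            if gene.strand == "-"
            else variant.alt_allele
        )
        codon_i = off // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon) < 3:
            # trailing partial codon of a length%3!=0 model: uncallable
            return EffectCall(
                variant,
                gene.gene_id,
                NONSYNONYMOUS,
                f"{variant.ref_allele} -> {variant.alt_allele} (exon: partial codon)",
                reliable=False,
            )
        mutated = codon[: off % 3] + alt + codon[off % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        aa_pos = codon_i + 1
        if aa_ref == aa_alt:
            kind = SYNONYMOUS
            detail = "synonymous variant"
        else:
            kind = NONSYNONYMOUS
            detail = f"{_aa3(aa_ref)}{aa_pos} -> {_aa3(aa_alt)}"
        label = f"{variant.ref_allele} -> {variant.alt_allele} (exon: {detail})"
        return EffectCall(
            variant,
            gene.gene_id,
            kind,
            label,
            aa_ref=_aa3(aa_ref),
            aa_pos=aa_pos,
            aa_alt=_aa3(aa_alt),
            reliable=reliable,
        )

    # exonic indel: frame class decided by the net change in coding length.
    # For a deletion straddling an exon boundary only the exonic part of the
    # removed span counts, and the call is flagged splice-adjacent.
    span = variant.affected_span()
    if variant.variant_class == DELETION:
        removed = variant.ref_allele[len(variant.alt_allele) :]
        exonic_removed = _exonic_overlap(gene, span)
        net = -exonic_removed
        boundary = exonic_removed != len(removed)
    else:
        net = variant.net_length_change
        boundary = False
    kind = INFRAME_INDEL if net % 3 == 0 else FRAMESHIFT
    extra = ", splice-adjacent" if boundary else ""
    label = _indel_label(variant, EXON, extra)
    return EffectCall(variant, gene.gene_id, kind, label, reliable=reliable)


def call_effects(
    hits: Sequence[ElementHit],
    models: Sequence[GeneModel] | Mapping[str, GeneModel],
    genome: Iterable[GenomeSequence] | Mapping[str, GenomeSequence],
) -> list[EffectCall]:
    """Effect call for every element hit, one call per hit."""
    by_id = models if isinstance(models, Mapping) else {m.gene_id: m for m in models}
    contigs = genome if isinstance(genome, Mapping) else genome_index(genome)
    calls = []
    for hit in hits:
        gene = by_id.get(hit.gene_id)
        if gene is None:
            raise ValidationError(f"hit references unknown gene {hit.gene_id}")
        calls.append(call_effect(hit.variant, hit, gene, contigs))
    return calls


@dataclass
class EffectSummary:
    n_synonymous: int
    n_nonsynonymous: int
    n_frameshift: int
    n_inframe: int
    n_noncoding: int
    per_gene_labels: dict[str, str]


def count_effects(calls: Iterable[EffectCall]) -> EffectSummary:
    """Tally effect kinds and render per-gene mutation strings.

    Multiple mutations of one gene are semicolon-joined in variant
    coordinate order, one entry per effect call.
    """
    counts = {SYNONYMOUS: 0, NONSYNONYMOUS: 0, FRAMESHIFT: 0, INFRAME_INDEL: 0, NONCODING: 0}
    per_gene: dict[str, list[tuple[tuple, str]]] = {}
    for call in calls:
        counts[call.kind] += 1
        per_gene.setdefault(call.gene_id, []).append((call.variant.key, call.label))
    labels = {
        gene: "; ".join(label for _, label in sorted(entries))
        for gene, entries in per_gene.items()
    }
    return EffectSummary(
        n_synonymous=counts[SYNONYMOUS],
        n_nonsynonymous=counts[NONSYNONYMOUS],
        n_frameshift=counts[FRAMESHIFT],
        n_inframe=counts[INFRAME_INDEL],
        n_noncoding=counts[NONCODING],
        per_gene_labels=labels,
    )
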