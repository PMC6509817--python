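"""Pedigree-aware variant-set algebra and candidate-gene selection.

A focal strain's *unique* variants are those whose exact
(contig, pos, ref, alt) key is absent from every comparison strain —
typically the parent and a sibling derived from the same parent.  Genotype
class is ignored for matching.  Because comparison lists can come from
differently normalized callers, indels are left-aligned before matching
when a genome is supplied, which prevents representation drift from
manufacturing spurious "unique" indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .effects import EffectCall
from .elements import ElementHit
from .errors import ConfigurationError, ValidationError
from .formats import GeneModel, GenomeSequence, VariantRecord, genome_index


@dataclass
class StrainVariantSet:
    strain_id: str
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValidationError(
                f"strain {self.strain_id}: duplicate variant keys"
            )

    def keys(self) -> set[tuple]:
        return {v.key for v in self.variants}


@dataclass(frozen=True)
class Pedigree:
    """Focal strain plus the explicit list of strains to subtract."""

    focal: str
    comparison_strains: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "comparison_strains", tuple(self.comparison_strains)
        )
        if self.focal in self.comparison_strains:
            raise ConfigurationError("focal strain listed among comparisons")


def left_normalize(
    variant: VariantRecord, contigs: Mapping[str, GenomeSequence]
) -> VariantRecord:
    """Shift an indel to its smallest equivalent coordinate (left-align).

    Standard trim-and-extend: drop shared trailing bases, extending to the
    left with the reference base before the site whenever an allele would
    empty; finally drop shared leading bases keeping the one-base anchor.
    SNPs are returned unchanged.
    """
    if variant.is_snp:
        return variant
    contig = contigs[variant.contig_id]
    pos, ref, alt = variant.pos, variant.ref_allele, variant.alt_allele
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                base = contig.slice(pos - 1, pos - 1)
                ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
            else:
                ref, alt = ref[:-1], alt[:-1]
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if (pos, ref, alt) == (variant.pos, variant.ref_allele, variant.alt_allele):
        return variant
    return VariantRecord(
        contig_id=variant.contig_id,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        genotype_class=variant.genotype_class,
        metrics=dict(variant.metrics),
    )


def _normalized_keys(
    variants: Iterable[VariantRecord],
    contigs: Optional[Mapping[str, GenomeSequence]],
) -> set[tuple]:
    if contigs is None:
        return {v.key for v in variants}
    return {left_normalize(v, contigs).key for v in variants}


def unique_variants(
    sets: Sequence[StrainVariantSet],
    pedigree: Pedigree,
    genome: Optional[Iterable[GenomeSequence]] = None,
) -> StrainVariantSet:
    """Focal variants present in no comparison strain (allele-exact)."""
    by_id = {s.strain_id: s for s in sets}
    missing = [
        s
        for s in (pedigree.focal, *pedigree.comparison_strains)
        if s not in by_id
    ]
    if missing:
        raise ConfigurationError(f"pedigree strains not supplied: {missing}")
    contigs = genome_index(genome) if genome is not None else None
    seen: set[tuple] = set()
    for sid in pedigree.comparison_strains:
        seen |= _normalized_keys(by_id[sid].variants, contigs)
    focal = by_id[pedigree.focal]
    kept = [
        v
        for v in focal.variants
        if (left_normalize(v, contigs).key if contigs else v.key) not in seen
    ]
    return StrainVariantSet(strain_id=focal.strain_id, variants=kept)


@dataclass
class CandidateGene:
    """A gene hit by at least one focal-unique variant — the unit taken
    forward to knockout screening."""

    gene_id: str
    annotation: str
    mutations: list[str]
    elements_hit: set[str]
    n_unique_variants: int


def select_candidate_genes(
    unique: StrainVariantSet,
    hits: Sequence[ElementHit],
    effects: Sequence[EffectCall],
    models: Sequence[GeneModel] | Mapping[str, GeneModel],
) -> list[CandidateGene]:
    """Group unique-variant element hits into per-gene candidates.

    ``hits``/``effects`` must be computed over exactly the unique set;
    intergenic-only variants contribute nothing.  Output is sorted by
    gene_id for a stable, documented order.
    """
    by_id = models if isinstance(models, Mapping) else {m.gene_id: m for m in models}
    unique_keys = unique.keys()
    # a variant hitting two elements of one gene has two effect calls with
    # distinct labels (the label names the element); keep them all
    labels: dict[tuple[tuple, str], list[str]] = {}
    for c in effects:
        bucket = labels.setdefault((c.variant.key, c.gene_id), [])
        if c.label not in bucket:
            bucket.append(c.label)
    grouped: dict[str, dict] = {}
    for h in hits:
        if h.variant.key not in unique_keys:
            continue
        entry = grouped.setdefault(
            h.gene_id, {"mutations": {}, "elements": set(), "variants": set()}
        )
        entry["elements"].add(h.element)
        entry["variants"].add(h.variant.key)
        entry["mutations"][h.variant.key] = labels.get(
            (h.variant.key, h.gene_id), []
        )
    out = []
    for gene_id in sorted(grouped):
        entry = grouped[gene_id]
        model = by_id.get(gene_id)
        mutations = [
            label
            for key in sorted(entry["mutations"])
            for label in entry["mutations"][key]
        ]
        out.append(
            CandidateGene(
                gene_id=gene_id,
                annotation=model.annotation if model else "",
                mutations=mutations,
                elements_hit=set(entry["elements"]),
                n_unique_variants=len(entry["variants"]),
            )
        )
    return out
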