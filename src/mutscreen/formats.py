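"""Readers, writers and the internal data model for FASTA, GFF3 and VCF.

Coordinate convention: everything internal is 1-based with fully closed
intervals, matching both GFF3 and VCF, so no half-open conversion happens
anywhere in the pipeline.  Indels use the VCF anchored representation (first
base shared between REF and ALT); the reference span a deletion actually
removes is ``[pos+1, pos+len(ref)-1]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

#: INFO keys understood by the pipeline, with their VCF types.
METRIC_KEYS: tuple[str, ...] = (
    "QD",
    "MQ",
    "FS",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
    "DP",
)

_ALLOWED_BASES = frozenset("ACGTN")

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS_ALT = "homozygous_alt"


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig: an id and its uppercase DNA sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"contig {self.contig_id!r} has empty sequence")
        bad = set(self.sequence) - _ALLOWED_BASES
        if bad:
            raise ValidationError(
                f"contig {self.contig_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Return the 1-based closed-interval slice [start, end]."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A CDS-based gene model.

    ``cds_exons`` are 1-based closed intervals stored in ascending reference
    order regardless of strand; the strand decides which end carries the
    start codon (lowest coordinate for ``+``, highest for ``-``).
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.cds_exons:
            raise ValidationError(f"gene {self.gene_id}: no CDS exons")
        exons = tuple(tuple(e) for e in self.cds_exons)
        object.__setattr__(self, "cds_exons", exons)
        for start, end in exons:
            if start > end or start < 1:
                raise ValidationError(
                    f"gene {self.gene_id}: malformed CDS interval [{start},{end}]"
                )
        for (s1, e1), (s2, e2) in itertools.pairwise(exons):
            if s2 <= e1:
                raise ValidationError(
                    f"gene {self.gene_id}: CDS intervals not sorted/non-overlapping"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Reference interval covered by the gene body (first to last CDS base)."""
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class as a pure function of the REF/ALT allele pair."""
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            raise ValidationError(f"ref and alt identical: {ref}")
        return SNP
    if len(alt) > len(ref):
        return INSERTION
    if len(ref) > len(alt):
        return DELETION
    raise ValidationError(f"unsupported allele pair {ref}>{alt} (MNP?)")


@dataclass
class VariantRecord:
    """One called variant flowing through every pipeline stage."""

    contig_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype_class: str
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.genotype_class not in (HETEROZYGOUS, HOMOZYGOUS_ALT):
            raise ValidationError(
                f"{self.contig_id}:{self.pos}: bad genotype class {self.genotype_class!r}"
            )
        self.variant_class = classify_alleles(self.ref_allele, self.alt_allele)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for cross-strain matching: (contig, pos, ref, alt)."""
        return (self.contig_id, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_snp(self) -> bool:
        return self.variant_class == SNP

    @property
    def is_indel(self) -> bool:
        return self.variant_class in (INSERTION, DELETION)

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def affected_span(self) -> tuple[int, int]:
        """Reference interval the variant touches (1-based, closed).

        SNPs and insertions touch only the anchor base; a deletion removes
        ``[pos+1, pos+len(ref)-1]``.
        """
        if self.variant_class == DELETION:
            return self.pos + 1, self.pos + len(self.ref_allele) - 1
        return self.pos, self.pos


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence objects.

    Lowercase input is uppercased; any IUPAC ambiguity code other than N is
    rejected; duplicate contig ids are a validation error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return out


def genome_index(genome: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    return {g.contig_id: g for g in genome}


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Assemble one GeneModel per mRNA from a GFF3 of gene/mRNA/CDS features."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            from_string=False,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc

    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise FormatError(
                f"{path}: CDS at {cds.seqid}:{cds.start}-{cds.end} lacks a Parent"
            )

    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds_list = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds_list:
            continue
        strands = {c.strand for c in cds_list} | {mrna.strand}
        if len(strands) != 1:
            raise ValidationError(f"{path}: mixed strands within model {mrna.id}")
        annotation = ""
        for attr in ("product", "Note", "description"):
            if attr in mrna.attributes:
                annotation = mrna.attributes[attr][0]
                break
        models.append(
            GeneModel(
                gene_id=mrna.id,
                contig_id=mrna.seqid,
                strand=mrna.strand,
                cds_exons=tuple((c.start, c.end) for c in cds_list),
                annotation=annotation,
            )
        )
    if not models:
        raise FormatError(f"{path}: no mRNA/CDS gene models found")
    return models


def validate_gene_models(
    models: Iterable[GeneModel], genome: Iterable[GenomeSequence]
) -> list[str]:
    """Check models against a genome; returns human-readable warnings.

    Contig-bound violations raise; a CDS length not divisible by 3 is only
    flagged (real annotation sets contain such models and the effect caller
    marks them unreliable rather than refusing them).
    """
    contigs = genome_index(genome)
    warnings: list[str] = []
    for m in models:
        if m.contig_id not in contigs:
            raise ValidationError(f"gene {m.gene_id}: unknown contig {m.contig_id}")
        if m.span[1] > len(contigs[m.contig_id]):
            raise ValidationError(f"gene {m.gene_id}: CDS extends past contig end")
        if m.cds_length % 3 != 0:
            warnings.append(
                f"gene {m.gene_id}: CDS length {m.cds_length} not divisible by 3"
            )
    return warnings


def _genotype_class_for_alt(gt: tuple, allele_index: int) -> Optional[str]:
    """Genotype class of one alt allele, or None if the sample lacks it."""
    called = [a for a in gt if a is not None]
    if not called or allele_index not in called:
        return None
    if all(a == allele_index for a in called):
        return HOMOZYGOUS_ALT
    return HETEROZYGOUS


def _scalar(value) -> float:
    if isinstance(value, (tuple, list)):
        value = value[0]
    return float(value)


def read_variants(
    path: str | Path,
    genome: Optional[Iterable[GenomeSequence]] = None,
) -> list[VariantRecord]:
    """Read a single-sample VCF into VariantRecords.

    Multi-allelic lines are split into one record per alt allele the sample
    actually carries; 0/0 and ./. genotypes are dropped (a locus matching the
    reference is not a variant).  Metric floats are rounded to 4 decimals to
    absorb the float32 storage of VCF INFO fields.  When a genome is given,
    every REF allele is verified against it.
    """
    contigs = genome_index(genome) if genome is not None else None
    out: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot open as VCF ({exc})") from exc
    with vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            try:
                gt = rec.samples[samples[0]]["GT"] if samples else None
            except (KeyError, IndexError):
                gt = None
            if rec.alts is None:
                continue
            metrics: dict[str, float] = {}
            for key in METRIC_KEYS:
                if key in rec.info:
                    value = _scalar(rec.info[key])
                    metrics[key] = float(value) if key == "DP" else round(value, 4)
            for i, alt in enumerate(rec.alts, start=1):
                if gt is not None:
                    gclass = _genotype_class_for_alt(tuple(gt), i)
                    if gclass is None:
                        continue
                else:
                    gclass = HOMOZYGOUS_ALT
                if contigs is not None:
                    contig = contigs.get(rec.contig)
                    if contig is None:
                        raise ValidationError(
                            f"{path}: {rec.contig}:{rec.pos} on unknown contig"
                        )
                    expected = contig.slice(rec.pos, rec.pos + len(rec.ref) - 1)
                    if expected != rec.ref.upper():
                        raise ValidationError(
                            f"{path}: REF mismatch at {rec.contig}:{rec.pos} "
                            f"(VCF {rec.ref!r}, genome {expected!r})"
                        )
                out.append(
                    VariantRecord(
                        contig_id=rec.contig,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        genotype_class=gclass,
                        metrics=dict(metrics),
                    )
                )
    return out


_INFO_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand-bias Fisher score (phred)">',
    '##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype consistency score">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping-quality rank-sum statistic">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read-position rank-sum statistic">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_variants(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_name: str = "SAMPLE",
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write records as a sorted single-sample VCF v4.2.

    Metrics are re-emitted in INFO (absent metrics stay absent), genotype
    class as GT 0/1 or 1/1.  Duplicate (contig, pos, ref, alt) keys are a
    validation error.  ``read_variants(write_variants(x))`` is the identity.
    """
    ordered = sorted(records, key=lambda v: v.key)
    for a, b in itertools.pairwise(ordered):
        if a.key == b.key:
            raise ValidationError(f"duplicate variant key {a.key}")

    header = pysam.VariantHeader()
    for line in _INFO_HEADER_LINES:
        header.add_line(line)
    contig_ids = dict.fromkeys(v.contig_id for v in ordered)
    for cid in contig_ids:
        if contig_lengths and cid in contig_lengths:
            header.contigs.add(cid, length=contig_lengths[cid])
        else:
            header.contigs.add(cid)
    header.add_sample(sample_name)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.contig_id,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            for key, value in v.metrics.items():
                rec.info[key] = int(value) if key == "DP" else float(value)
            gt = (1, 1) if v.genotype_class == HOMOZYGOUS_ALT else (0, 1)
            rec.samples[sample_name]["GT"] = gt
            out.write(rec)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
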