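"""Synthetic lineage generator: toy genome, gene models and a pedigree of
variant sets with a ground-truth ledger.

The generator emulates the inputs of a comparative resequencing screen of a
mutagenesis lineage: a reference genome, stranded multi-exon CDS gene
models, and per-strain variant sets shaped like a two-generation pedigree
(ancestor -> parent -> two sibling children).  Every variant is *planted*
with a known element / coding-effect class, GATK-like quality metrics drawn
from passing ranges (or deliberately violating exactly one filter rule),
and a known carrying-strain set — all recorded in a ledger so each pipeline
stage can be checked against construction truth.

Geometry guarantees that make ledger truth exact:

* gene bodies are separated by at least ``intergenic_gap[0]`` bases, which
  is kept larger than two facing 1 kb windows, so no element interval of
  one gene ever overlaps an element of another;
* genes stay ``contig_margin`` away from contig ends, so promoter and
  terminator windows are never clipped;
* planted variants are spaced more than one cluster window apart, so no
  accidental SNP cluster forms (deliberate cluster triplets excepted).

The default configuration is a small fixture (two ~29 kb contigs, 20
genes, 4 strains) that builds in well under a second; :meth:`SimConfig.study`
scales the same machinery to the mutant-screen study conditions: a parent
carrying 126 SNPs + 22 indels relative to the ancestor reference, one
child adding 97 SNPs + 11 indels, and a focal child inheriting 107 SNPs +
10 indels and adding 77 SNPs + 30 indels of its own, whose in-element
subset hits exactly 57 distinct genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .elements import (
    DEFAULT_PROMOTER_BP,
    DEFAULT_TERMINATOR_BP,
    EXON,
    INTRON,
    PROMOTER,
    TERMINATOR,
    GeneElements,
    gene_elements,
)
from .effects import (
    FRAMESHIFT,
    INFRAME_INDEL,
    NONCODING,
    NONSYNONYMOUS,
    SYNONYMOUS,
)
from .errors import ConfigurationError
from .formats import (
    HETEROZYGOUS,
    HOMOZYGOUS_ALT,
    GeneModel,
    GenomeSequence,
    VariantRecord,
    reverse_complement,
    write_variants,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
_CODON_TABLE = {}
from Bio.Seq import Seq as _Seq  # local import kept near its single use

for _c in (a + b + c for a in _BASES for b in _BASES for c in _BASES):
    _CODON_TABLE[_c] = str(_Seq(_c).translate())

_ANNOTATIONS = (
    "hypothetical protein",
    "zinc-dependent alcohol dehydrogenase",
    "MFS general substrate transporter",
    "C2H2 zinc finger transcription factor",
    "serine/threonine protein phosphatase",
    "S-adenosyl-methionine-dependent methyltransferase",
    "P-loop nucleoside triphosphate hydrolase",
    "ABC transporter",
    "glycosyltransferase family protein",
    "carbohydrate kinase",
    "NAD(P)-binding oxidoreductase",
    "clathrin adaptor complex subunit",
    "amino acid transporter",
    "thioredoxin",
    "GTP-binding protein",
    "histone methyltransferase",
    "amidase signature enzyme",
    "WD40 repeat-like protein",
    "RNA helicase",
    "ubiquitin family protein",
)

# element classes a planted variant can be aimed at
_SNP_CLASSES = ("promoter", "terminator", "intron", "exon_synonymous",
                "exon_nonsynonymous", "intergenic")
_INDEL_CLASSES = ("promoter_indel", "terminator_indel", "intron_indel",
                  "exon_frameshift", "exon_inframe", "intergenic_indel")

# filter-failure planting specs: rule key -> (is_snp, metric, sampler kind)
_FAILURE_SPECS = {
    "QD": (True, "QD", (0.1, 1.9), "QD"),
    "MQ": (True, "MQ", (10.0, 39.5), "MQ"),
    "FS": (True, "FS", (60.5, 150.0), "FS"),
    "HaplotypeScore": (True, "HaplotypeScore", (13.5, 30.0), "HaplotypeScore"),
    "MQRankSum": (True, "MQRankSum", (-25.0, -12.6), "MQRankSum"),
    "ReadPosRankSum": (True, "ReadPosRankSum", (-15.0, -8.1), "ReadPosRankSum"),
    "DP_low": (True, "DP", (1, 3), "DP"),
    "DP_high": (True, "DP", (201, 400), "DP"),
    "QD_indel": (False, "QD", (0.1, 1.9), "QD"),
    "ReadPosRankSum_indel": (False, "ReadPosRankSum", (-35.0, -20.1), "ReadPosRankSum"),
    "FS_indel": (False, "FS", (200.5, 400.0), "FS"),
}

_PASSING_RANGES = {
    "QD": (15.0, 35.0),
    "MQ": (50.0, 60.0),
    "FS": (0.0, 10.0),
    "HaplotypeScore": (0.0, 5.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
    "DP": (20, 120),
}

LEDGER_COLUMNS = (
    "strain",
    "contig",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "genotype_class",
    "gene_id",
    "element",
    "effect_kind",
    "filter_fate",
    "unique",
)


@dataclass
class StrainBudget:
    """Planting budget of one strain (its variants *relative to the
    reference*, beyond anything inherited from ``inherit_from``)."""

    promoter_snps: int = 0
    terminator_snps: int = 0
    intron_snps: int = 0
    exon_synonymous: int = 0
    exon_nonsynonymous: int = 0
    intergenic_snps: int = 0
    promoter_indels: int = 0
    terminator_indels: int = 0
    intron_indels: int = 0
    exon_frameshift: int = 0
    exon_inframe: int = 0
    intergenic_indels: int = 0
    filter_failures: dict[str, int] = field(default_factory=dict)
    cluster_triplets: int = 0
    inherit_from: Optional[str] = None
    inherited_snps: int = 0
    inherited_indels: int = 0

    @property
    def n_pass_snps(self) -> int:
        return (self.promoter_snps + self.terminator_snps + self.intron_snps
                + self.exon_synonymous + self.exon_nonsynonymous
                + self.intergenic_snps)

    @property
    def n_pass_indels(self) -> int:
        return (self.promoter_indels + self.terminator_indels
                + self.intron_indels + self.exon_frameshift
                + self.exon_inframe + self.intergenic_indels)

    def element_hit_count(self) -> int:
        """Plantings that land inside some gene's element."""
        return (self.n_pass_snps - self.intergenic_snps
                + self.n_pass_indels - self.intergenic_indels)


def _default_strains() -> dict[str, StrainBudget]:
    return {
        "QM6a": StrainBudget(),
        "NG14": StrainBudget(
            promoter_snps=3, terminator_snps=2, intron_snps=1,
            exon_synonymous=2, exon_nonsynonymous=2, intergenic_snps=4,
            promoter_indels=1, terminator_indels=1, exon_frameshift=1,
            intergenic_indels=1,
        ),
        "RUT-C30": StrainBudget(
            promoter_snps=1, terminator_snps=1, exon_nonsynonymous=1,
            intergenic_snps=1, terminator_indels=1, intergenic_indels=1,
            inherit_from="NG14", inherited_snps=6, inherited_indels=2,
        ),
        "SS-II": StrainBudget(
            promoter_snps=6, terminator_snps=5, intron_snps=3,
            exon_synonymous=3, exon_nonsynonymous=5, intergenic_snps=4,
            promoter_indels=2, terminator_indels=2, intron_indels=1,
            exon_frameshift=2, exon_inframe=1, intergenic_indels=2,
            filter_failures={
                "QD": 1, "MQ": 1, "FS": 1, "HaplotypeScore": 1,
                "MQRankSum": 1, "ReadPosRankSum": 1, "DP_low": 1,
                "DP_high": 1, "QD_indel": 1, "ReadPosRankSum_indel": 1,
                "FS_indel": 1,
            },
            cluster_triplets=1,
            inherit_from="NG14", inherited_snps=6, inherited_indels=2,
        ),
    }


@dataclass
class SimConfig:
    """Everything that determines a synthetic fixture (seed included)."""

    seed: int = 0
    n_contigs: int = 2
    contig_length_bp: int = 36_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    codons_per_gene: tuple[int, int] = (60, 120)
    intron_length: tuple[int, int] = (40, 90)
    intergenic_gap: tuple[int, int] = (2_100, 2_500)
    contig_margin: int = 1_100
    promoter_bp: int = DEFAULT_PROMOTER_BP
    terminator_bp: int = DEFAULT_TERMINATOR_BP
    focal: str = "SS-II"
    comparison_strains: tuple[str, ...] = ("NG14", "RUT-C30")
    focal_candidate_genes: Optional[int] = 12
    het_fraction: float = 0.15
    ranksum_absent_fraction: float = 0.2
    strains: dict[str, StrainBudget] = field(default_factory=_default_strains)

    def __post_init__(self) -> None:
        if self.exons_per_gene[0] < 2:
            raise ConfigurationError(
                "exons_per_gene minimum must be >= 2 so every gene has an intron"
            )
        if self.intergenic_gap[0] < 2 * self.promoter_bp + 50:
            raise ConfigurationError(
                "intergenic gap too small: two facing promoter windows could "
                "overlap and element ground truth would become ambiguous"
            )
        if self.contig_margin < self.promoter_bp + 50:
            raise ConfigurationError("contig margin must exceed the promoter window")
        for sid in (self.focal, *self.comparison_strains):
            if sid not in self.strains:
                raise ConfigurationError(f"pedigree strain {sid!r} has no budget")
        if self.focal_candidate_genes is not None:
            hits = self.strains[self.focal].element_hit_count()
            if self.focal_candidate_genes > hits:
                raise ConfigurationError(
                    "cannot spread fewer element hits over more candidate genes"
                )
            if self.focal_candidate_genes > self.n_genes:
                raise ConfigurationError("more candidate genes than genes")

    @classmethod
    def study(cls, seed: int = 0) -> "SimConfig":
        """Study-scale conditions for the hyper-cellulolytic mutant screen.

        Variant budgets mirror the published lineage: parent NG14 carries
        126 SNPs + 22 indels relative to the QM6a reference; sibling
        RUT-C30 adds 97 SNPs + 11 indels of its own; the focal strain
        SS-II inherits 107 SNPs + 10 indels from NG14 and carries 77 SNPs
        + 30 indels found in neither relative, whose in-element subset
        falls in exactly 57 distinct genes.
        """
        strains = {
            "QM6a": StrainBudget(),
            "NG14": StrainBudget(
                promoter_snps=20, terminator_snps=15, intron_snps=8,
                exon_synonymous=10, exon_nonsynonymous=15, intergenic_snps=58,
                promoter_indels=3, terminator_indels=3, intron_indels=2,
                exon_frameshift=2, exon_inframe=1, intergenic_indels=11,
            ),
            "RUT-C30": StrainBudget(
                promoter_snps=15, terminator_snps=10, intron_snps=5,
                exon_synonymous=8, exon_nonsynonymous=12, intergenic_snps=47,
                promoter_indels=2, terminator_indels=2, intron_indels=1,
                exon_frameshift=1, intergenic_indels=5,
                inherit_from="NG14", inherited_snps=107, inherited_indels=10,
            ),
            "SS-II": StrainBudget(
                promoter_snps=18, terminator_snps=22, intron_snps=5,
                exon_synonymous=4, exon_nonsynonymous=13, intergenic_snps=15,
                promoter_indels=5, terminator_indels=11, intron_indels=5,
                exon_frameshift=1, intergenic_indels=8,
                filter_failures={
                    "QD": 2, "MQ": 2, "FS": 2, "HaplotypeScore": 2,
                    "MQRankSum": 2, "ReadPosRankSum": 2, "DP_low": 2,
                    "DP_high": 2, "QD_indel": 2, "ReadPosRankSum_indel": 2,
                    "FS_indel": 2,
                },
                cluster_triplets=2,
                inherit_from="NG14", inherited_snps=107, inherited_indels=10,
            ),
        }
        return cls(
            seed=seed,
            n_contigs=4,
            contig_length_bp=68_000,
            n_genes=70,
            codons_per_gene=(120, 260),
            focal_candidate_genes=57,
            strains=strains,
        )


# ----------------------------------------------------------------------
# genome construction


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    codons.extend(_SENSE_CODONS[i] for i in idx)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of `total` into `parts` parts, each >= minimum."""
    if parts * minimum > total:
        raise ConfigurationError("CDS too short to split into that many exons")
    free = total - parts * minimum
    cuts = sorted(rng.integers(0, free + 1, size=parts - 1))
    sizes = []
    prev = 0
    for c in [*cuts, free]:
        sizes.append(minimum + (c - prev))
        prev = c
    return sizes


def simulate_genome(
    config: SimConfig,
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Generate contigs and packed gene models; deterministic in the seed.

    Every CDS starts with ATG, ends with a stop, has length divisible by 3
    and no internal stop codon; roughly half the genes are on each strand.
    Raises :class:`ConfigurationError` when the genes do not fit.
    """
    rng = np.random.default_rng(config.seed)
    contigs = [
        list(rng.choice(list(_BASES), size=config.contig_length_bp))
        for _ in range(config.n_contigs)
    ]
    models: list[GeneModel] = []
    gene_serial = 0
    for ci, contig in enumerate(contigs):
        cursor = config.contig_margin + int(rng.integers(0, 200))
        while gene_serial < config.n_genes:
            n_codons = int(rng.integers(*config.codons_per_gene, endpoint=True))
            cds = _random_cds(rng, n_codons)
            n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
            exon_sizes = _partition(rng, len(cds), n_exons, minimum=15)
            intron_sizes = [
                int(rng.integers(*config.intron_length, endpoint=True))
                for _ in range(n_exons - 1)
            ]
            body_len = len(cds) + sum(intron_sizes)
            if cursor + body_len + config.contig_margin > len(contig):
                break
            strand = "+" if rng.random() < 0.5 else "-"
            # local layout in coding orientation
            local: list[str] = []
            local_exons: list[tuple[int, int]] = []  # 0-based local, closed
            off = 0
            pos_in_cds = 0
            for i, size in enumerate(exon_sizes):
                local.append(cds[pos_in_cds : pos_in_cds + size])
                local_exons.append((off, off + size - 1))
                off += size
                pos_in_cds += size
                if i < n_exons - 1:
                    intron = "".join(rng.choice(list(_BASES), size=intron_sizes[i]))
                    local.append(intron)
                    off += intron_sizes[i]
            local_seq = "".join(local)
            ref_seq = local_seq if strand == "+" else reverse_complement(local_seq)
            start = cursor  # 0-based contig offset of the gene body
            contig[start : start + body_len] = list(ref_seq)
            if strand == "+":
                ref_exons = [
                    (start + a + 1, start + b + 1) for a, b in local_exons
                ]
            else:
                last = body_len - 1
                ref_exons = [
                    (start + (last - b) + 1, start + (last - a) + 1)
                    for a, b in local_exons
                ]
                ref_exons.reverse()
            gene_serial += 1
            models.append(
                GeneModel(
                    gene_id=f"sg{gene_serial:04d}",
                    contig_id=f"contig{ci + 1}",
                    strand=strand,
                    cds_exons=tuple(ref_exons),
                    annotation=_ANNOTATIONS[(gene_serial - 1) % len(_ANNOTATIONS)],
                )
            )
            cursor += body_len + int(rng.integers(*config.intergenic_gap, endpoint=True))
        if gene_serial >= config.n_genes:
            break
    if gene_serial < config.n_genes:
        raise ConfigurationError(
            f"could not pack {config.n_genes} genes into "
            f"{config.n_contigs} x {config.contig_length_bp} bp contigs"
        )
    genome = [
        GenomeSequence(f"contig{i + 1}", "".join(c)) for i, c in enumerate(contigs)
    ]
    return genome, models


# ----------------------------------------------------------------------
# variant planting


@dataclass
class _Planted:
    record: VariantRecord
    gene_id: str  # "" for intergenic
    element: str  # element kind or "intergenic"
    effect_kind: str  # effects vocabulary or "" for intergenic
    filter_fate: str  # "pass" or failing rule name


class _Planter:
    """Stateful helper that picks fresh, well-separated positions."""

    #: reserve this many bases on either side of a planted span so that no
    #: unintended 10 bp SNP cluster can form
    PAD = 11

    def __init__(self, rng, genome: list[GenomeSequence],
                 models: list[GeneModel], config: SimConfig):
        self.rng = rng
        self.config = config
        self.contigs = {g.contig_id: g.sequence for g in genome}
        self.models = {m.gene_id: m for m in models}
        self.elements: dict[str, GeneElements] = {
            m.gene_id: gene_elements(
                m, len(self.contigs[m.contig_id]),
                config.promoter_bp, config.terminator_bp,
            )
            for m in models
        }
        self.reserved: dict[str, set[int]] = {c: set() for c in self.contigs}
        self.free_zones = self._intergenic_zones()
        self.cds_cache: dict[str, str] = {}

    def _intergenic_zones(self) -> dict[str, list[tuple[int, int]]]:
        zones: dict[str, list[tuple[int, int]]] = {}
        for cid, seq in self.contigs.items():
            occupied: list[tuple[int, int]] = []
            for elems in self.elements.values():
                if elems.contig_id != cid:
                    continue
                for _, (a, b) in elems.intervals():
                    occupied.append((a, b))
            occupied.sort()
            free: list[tuple[int, int]] = []
            prev_end = 0
            for a, b in occupied:
                if a - 1 > prev_end + 1:
                    free.append((prev_end + 1, a - 1))
                prev_end = max(prev_end, b)
            if prev_end + 1 <= len(seq):
                free.append((prev_end + 1, len(seq)))
            # keep a safety margin inside each free zone so indel spans
            # cannot leak into a neighbouring element interval
            zones[cid] = [
                (a + 20, b - 20) for a, b in free if b - a >= 60
            ]
        return zones

    # -- reservation ---------------------------------------------------

    def _is_free(self, contig: str, a: int, b: int) -> bool:
        res = self.reserved[contig]
        return all(p not in res for p in range(a - self.PAD, b + self.PAD + 1))

    def _reserve(self, contig: str, a: int, b: int) -> None:
        self.reserved[contig].update(range(a - self.PAD, b + self.PAD + 1))

    def base(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1]

    def _alt_base(self, ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[self.rng.integers(0, len(choices))]

    def _genotype(self) -> str:
        return (
            HETEROZYGOUS
            if self.rng.random() < self.config.het_fraction
            else HOMOZYGOUS_ALT
        )

    def passing_metrics(self, genotype: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, (lo, hi) in _PASSING_RANGES.items():
            if key == "DP":
                out[key] = float(self.rng.integers(lo, hi, endpoint=True))
            else:
                out[key] = round(float(self.rng.uniform(lo, hi)), 3)
        if (genotype == HOMOZYGOUS_ALT
                and self.rng.random() < self.config.ranksum_absent_fraction):
            out.pop("MQRankSum")
            out.pop("ReadPosRankSum")
        return out

    # -- position pickers ----------------------------------------------

    def _pick_in_interval(self, contig: str, interval: tuple[int, int],
                          span_len: int = 1, tries: int = 200) -> int:
        a, b = interval
        if b - a + 1 < span_len:
            raise ConfigurationError("interval too small for requested span")
        for _ in range(tries):
            pos = int(self.rng.integers(a, b - span_len + 2))
            if self._is_free(contig, pos, pos + span_len - 1):
                self._reserve(contig, pos, pos + span_len - 1)
                return pos
        raise ConfigurationError(
            f"no free position of span {span_len} left in {contig}:{a}-{b}; "
            "budget exceeds available positions"
        )

    def _pick_intergenic(self, span_len: int = 1, tries: int = 400) -> tuple[str, int]:
        contigs = list(self.free_zones)
        for _ in range(tries):
            cid = contigs[self.rng.integers(0, len(contigs))]
            zones = self.free_zones[cid]
            if not zones:
                continue
            weights = np.array([b - a + 1 for a, b in zones], dtype=float)
            zi = int(self.rng.choice(len(zones), p=weights / weights.sum()))
            try:
                pos = self._pick_in_interval(cid, zones[zi], span_len, tries=20)
            except ConfigurationError:
                continue
            return cid, pos
        raise ConfigurationError("no intergenic space left; budget too large")

    # -- per-class planting --------------------------------------------

    def snp_in_window(self, gene_id: str, element: str) -> _Planted:
        elems = self.elements[gene_id]
        if element == PROMOTER:
            interval = elems.promoter
        elif element == TERMINATOR:
            interval = elems.terminator
        else:
            # a gene may have several introns; try them all before giving up
            introns = list(elems.introns)
            self.rng.shuffle(introns)
            last_error: Exception | None = None
            for intron in introns:
                try:
                    pos = self._pick_in_interval(
                        elems.contig_id, tuple(intron), tries=60
                    )
                    break
                except ConfigurationError as exc:
                    last_error = exc
            else:
                raise ConfigurationError(
                    f"no intron space left in gene {gene_id}: {last_error}"
                )
            ref = self.base(elems.contig_id, pos)
            genotype = self._genotype()
            rec = VariantRecord(elems.contig_id, pos, ref, self._alt_base(ref),
                                genotype, self.passing_metrics(genotype))
            return _Planted(rec, gene_id, element, NONCODING, "pass")
        pos = self._pick_in_interval(elems.contig_id, interval)
        ref = self.base(elems.contig_id, pos)
        genotype = self._genotype()
        rec = VariantRecord(elems.contig_id, pos, ref, self._alt_base(ref),
                            genotype, self.passing_metrics(genotype))
        return _Planted(rec, gene_id, element, NONCODING, "pass")

    def cds(self, gene_id: str) -> str:
        if gene_id not in self.cds_cache:
            from .effects import spliced_cds

            gene = self.models[gene_id]
            self.cds_cache[gene_id] = spliced_cds(
                gene, {c: GenomeSequence(c, s) for c, s in self.contigs.items()}
            )
        return self.cds_cache[gene_id]

    def _ref_pos_for_offset(self, gene: GeneModel, off: int) -> int:
        plus_off = off if gene.strand == "+" else gene.cds_length - 1 - off
        seen = 0
        for start, end in gene.cds_exons:
            size = end - start + 1
            if plus_off < seen + size:
                return start + (plus_off - seen)
            seen += size
        raise ConfigurationError("CDS offset outside gene")

    def coding_snp(self, gene_id: str, synonymous: bool) -> _Planted:
        gene = self.models[gene_id]
        cds = self.cds(gene_id)
        n_codons = len(cds) // 3
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(300):
            codon_i = int(self.rng.integers(1, n_codons - 1))  # skip start & stop
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            pos_in_codon = int(self.rng.integers(0, 3))
            alts = [b for b in _BASES if b != codon[pos_in_codon]]
            self.rng.shuffle(alts)
            for alt_coding in alts:
                mutated = (codon[:pos_in_codon] + alt_coding
                           + codon[pos_in_codon + 1 :])
                same = _CODON_TABLE[codon] == _CODON_TABLE[mutated]
                if same != synonymous:
                    continue
                off = codon_i * 3 + pos_in_codon
                ref_pos = self._ref_pos_for_offset(gene, off)
                if not self._is_free(gene.contig_id, ref_pos, ref_pos):
                    continue
                ref = self.base(gene.contig_id, ref_pos)
                alt = alt_coding if gene.strand == "+" else alt_coding.translate(comp)
                self._reserve(gene.contig_id, ref_pos, ref_pos)
                genotype = self._genotype()
                rec = VariantRecord(gene.contig_id, ref_pos, ref, alt,
                                    genotype, self.passing_metrics(genotype))
                kind = SYNONYMOUS if synonymous else NONSYNONYMOUS
                return _Planted(rec, gene_id, EXON, kind, "pass")
        raise ConfigurationError(
            f"could not plant a {'synonymous' if synonymous else 'nonsynonymous'} "
            f"SNP in gene {gene_id}; budget exceeds available positions"
        )

    def _make_indel(self, contig: str, pos: int, length: int,
                    deletion: bool, genotype: str,
                    metrics: dict[str, float]) -> VariantRecord:
        seq = self.contigs[contig]
        anchor = seq[pos - 1]
        if deletion:
            ref = seq[pos - 1 : pos + length]
            alt = anchor
        else:
            ins = "".join(self.rng.choice(list(_BASES), size=length))
            ref = anchor
            alt = anchor + ins
        return VariantRecord(contig, pos, ref, alt, genotype, metrics)

    def indel_in_window(self, gene_id: str, element: str) -> _Planted:
        elems = self.elements[gene_id]
        last_error: Exception | None = None
        for _ in range(30):
            if element == PROMOTER:
                interval = elems.promoter
            elif element == TERMINATOR:
                interval = elems.terminator
            else:
                introns = elems.introns
                interval = tuple(introns[self.rng.integers(0, len(introns))])
            ilen = interval[1] - interval[0] + 1
            max_len = max(1, min(16, ilen // 4))
            deletion = bool(self.rng.random() < 0.6)
            length = int(self.rng.integers(1, max_len, endpoint=True))
            span = length + 1 if deletion else 1
            try:
                pos = self._pick_in_interval(
                    elems.contig_id, interval, span_len=span, tries=50
                )
            except ConfigurationError as exc:
                last_error = exc
                continue
            genotype = self._genotype()
            rec = self._make_indel(elems.contig_id, pos, length, deletion,
                                   genotype, self.passing_metrics(genotype))
            return _Planted(rec, gene_id, element, NONCODING, "pass")
        raise ConfigurationError(
            f"could not plant a {element} indel in gene {gene_id}: {last_error}"
        )

    def coding_indel(self, gene_id: str, inframe: bool) -> _Planted:
        gene = self.models[gene_id]
        elems = self.elements[gene_id]
        if inframe:
            length = 3
        else:
            length = int(self.rng.integers(1, 2, endpoint=True))
        deletion = bool(self.rng.random() < 0.5)
        # pick an exon big enough to hold the whole span away from its edges
        exon_list = [e for e in elems.exons if e[1] - e[0] + 1 >= length + 6]
        if not exon_list:
            raise ConfigurationError(f"gene {gene_id}: exons too small for indel")
        span = length + 1 if deletion else 1
        last_error: Exception | None = None
        for _ in range(30):
            exon = exon_list[self.rng.integers(0, len(exon_list))]
            inner = (exon[0] + 2, exon[1] - 2)
            try:
                pos = self._pick_in_interval(
                    elems.contig_id, inner, span_len=span, tries=50
                )
            except ConfigurationError as exc:
                last_error = exc
                continue
            genotype = self._genotype()
            rec = self._make_indel(elems.contig_id, pos, length, deletion,
                                   genotype, self.passing_metrics(genotype))
            kind = INFRAME_INDEL if inframe else FRAMESHIFT
            return _Planted(rec, gene_id, EXON, kind, "pass")
        raise ConfigurationError(
            f"could not plant an exonic indel in gene {gene_id}: {last_error}"
        )

    def intergenic_variant(self, indel: bool) -> _Planted:
        if indel:
            deletion = bool(self.rng.random() < 0.6)
            length = int(self.rng.integers(1, 8, endpoint=True))
            span = length + 1 if deletion else 1
        else:
            deletion, length, span = False, 0, 1
        contig, pos = self._pick_intergenic(span_len=span)
        genotype = self._genotype()
        metrics = self.passing_metrics(genotype)
        if indel:
            rec = self._make_indel(contig, pos, length, deletion, genotype, metrics)
        else:
            ref = self.base(contig, pos)
            rec = VariantRecord(contig, pos, ref, self._alt_base(ref),
                                genotype, metrics)
        return _Planted(rec, "", "intergenic", "", "pass")

    def failure_variant(self, rule: str) -> _Planted:
        is_snp, metric, rng_range, fate = _FAILURE_SPECS[rule]
        span = 1 if is_snp else 3
        contig, pos = self._pick_intergenic(span_len=span)
        genotype = HOMOZYGOUS_ALT
        metrics = self.passing_metrics(genotype)
        # rank-sum failure needs the metric present
        if metric in ("MQRankSum", "ReadPosRankSum"):
            metrics.setdefault("MQRankSum",
                               round(float(self.rng.uniform(-3, 3)), 3))
            metrics.setdefault("ReadPosRankSum",
                               round(float(self.rng.uniform(-3, 3)), 3))
        lo, hi = rng_range
        if metric == "DP":
            metrics[metric] = float(self.rng.integers(int(lo), int(hi), endpoint=True))
        else:
            metrics[metric] = round(float(self.rng.uniform(lo, hi)), 3)
        if is_snp:
            ref = self.base(contig, pos)
            rec = VariantRecord(contig, pos, ref, self._alt_base(ref),
                                genotype, metrics)
        else:
            rec = self._make_indel(contig, pos, 2, True, genotype, metrics)
        return _Planted(rec, "", "intergenic", "", fate)

    def cluster_triplet(self) -> list[_Planted]:
        contig, pos = self._pick_intergenic(span_len=9)
        out = []
        for offset in (0, 4, 8):
            p = pos + offset
            ref = self.base(contig, p)
            genotype = HOMOZYGOUS_ALT
            rec = VariantRecord(contig, p, ref, self._alt_base(ref),
                                genotype, self.passing_metrics(genotype))
            out.append(_Planted(rec, "", "intergenic", "", "SNPcluster"))
        return out


def _hit_specs(budget: StrainBudget) -> list[str]:
    """Element-hit planting classes of one strain, in a fixed order."""
    spec = []
    spec += ["promoter"] * budget.promoter_snps
    spec += ["terminator"] * budget.terminator_snps
    spec += ["intron"] * budget.intron_snps
    spec += ["exon_synonymous"] * budget.exon_synonymous
    spec += ["exon_nonsynonymous"] * budget.exon_nonsynonymous
    spec += ["promoter_indel"] * budget.promoter_indels
    spec += ["terminator_indel"] * budget.terminator_indels
    spec += ["intron_indel"] * budget.intron_indels
    spec += ["exon_frameshift"] * budget.exon_frameshift
    spec += ["exon_inframe"] * budget.exon_inframe
    return spec


def _plant_hit(planter: _Planter, kind: str, gene_id: str) -> _Planted:
    if kind == "promoter":
        return planter.snp_in_window(gene_id, PROMOTER)
    if kind == "terminator":
        return planter.snp_in_window(gene_id, TERMINATOR)
    if kind == "intron":
        return planter.snp_in_window(gene_id, INTRON)
    if kind == "exon_synonymous":
        return planter.coding_snp(gene_id, synonymous=True)
    if kind == "exon_nonsynonymous":
        return planter.coding_snp(gene_id, synonymous=False)
    if kind == "promoter_indel":
        return planter.indel_in_window(gene_id, PROMOTER)
    if kind == "terminator_indel":
        return planter.indel_in_window(gene_id, TERMINATOR)
    if kind == "intron_indel":
        return planter.indel_in_window(gene_id, INTRON)
    if kind == "exon_frameshift":
        return planter.coding_indel(gene_id, inframe=False)
    if kind == "exon_inframe":
        return planter.coding_indel(gene_id, inframe=True)
    raise ConfigurationError(f"unknown planting class {kind!r}")


def simulate_pedigree_variants(
    config: SimConfig,
    genome: list[GenomeSequence],
    models: list[GeneModel],
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame]:
    """Plant every strain's variants and build the ground-truth ledger.

    Returns a map strain -> variant records (pre-filter, i.e. including
    planted filter failures) and a ledger with one row per (variant,
    carrying strain).
    """
    rng = np.random.default_rng(config.seed + 1)
    planter = _Planter(rng, genome, models, config)
    gene_ids = [m.gene_id for m in models]

    order = list(config.strains)
    for sid in order:
        parent = config.strains[sid].inherit_from
        if parent is not None and (
            parent not in config.strains or order.index(parent) >= order.index(sid)
        ):
            raise ConfigurationError(
                f"strain {sid} inherits from {parent}, "
                "which is defined later or missing"
            )

    # Plant the focal strain first: on a fresh genome every one of its
    # first-round hits (one per chosen gene) is guaranteed to fit, which is
    # what makes the distinct candidate-gene count exact.  Other strains'
    # plantings can then crowd a gene and simply retry elsewhere.
    plant_order = sorted(order, key=lambda s: s != config.focal)
    own_by_strain: dict[str, list[_Planted]] = {}
    for sid in plant_order:
        budget = config.strains[sid]
        own: list[_Planted] = []
        specs = _hit_specs(budget)
        if sid == config.focal and config.focal_candidate_genes is not None:
            # exactly this many distinct genes receive the focal strain's
            # element hits: one hit per chosen gene first (guaranteeing the
            # distinct count), then the remainder spread among them
            pool = list(rng.choice(gene_ids, size=config.focal_candidate_genes,
                                   replace=False))
            rng.shuffle(specs)
            assignments = []
            for i, kind in enumerate(specs):
                if i < len(pool):
                    assignments.append((kind, pool[i]))
                else:
                    assignments.append(
                        (kind, pool[int(rng.integers(0, len(pool)))])
                    )
        else:
            pool = gene_ids
            assignments = [
                (kind, gene_ids[int(rng.integers(0, len(gene_ids)))])
                for kind in specs
            ]
        for kind, gid in assignments:
            # a crowded gene (tiny introns, many hits) can run out of
            # well-separated positions; move the hit to another pool gene
            last_error: Exception | None = None
            for _ in range(60):
                try:
                    own.append(_plant_hit(planter, kind, gid))
                    break
                except ConfigurationError as exc:
                    last_error = exc
                    gid = pool[int(rng.integers(0, len(pool)))]
            else:
                raise ConfigurationError(
                    f"strain {sid}: cannot place a {kind} planting anywhere; "
                    f"budget exceeds available positions ({last_error})"
                )
        for _ in range(budget.intergenic_snps):
            own.append(planter.intergenic_variant(indel=False))
        for _ in range(budget.intergenic_indels):
            own.append(planter.intergenic_variant(indel=True))
        for rule, count in budget.filter_failures.items():
            if rule not in _FAILURE_SPECS:
                raise ConfigurationError(f"unknown filter-failure rule {rule!r}")
            for _ in range(count):
                own.append(planter.failure_variant(rule))
        for _ in range(budget.cluster_triplets):
            own.extend(planter.cluster_triplet())
        own_by_strain[sid] = own

    # second pass, in pedigree (definition) order: resolve inheritance from
    # the parent's full variant list (its own plantings plus what it
    # inherited itself)
    planted_by_strain: dict[str, list[_Planted]] = {}
    for sid in order:
        budget = config.strains[sid]
        inherited: list[_Planted] = []
        if budget.inherit_from is not None:
            parent = planted_by_strain[budget.inherit_from]
            pass_snps = [p for p in parent
                         if p.filter_fate == "pass" and p.record.is_snp]
            pass_indels = [p for p in parent
                           if p.filter_fate == "pass" and p.record.is_indel]
            if (budget.inherited_snps > len(pass_snps)
                    or budget.inherited_indels > len(pass_indels)):
                raise ConfigurationError(
                    f"strain {sid}: inherited budget exceeds parent's "
                    "passing variants"
                )
            snp_idx = rng.choice(len(pass_snps), size=budget.inherited_snps,
                                 replace=False)
            ind_idx = rng.choice(len(pass_indels), size=budget.inherited_indels,
                                 replace=False)
            inherited = [pass_snps[i] for i in sorted(snp_idx)]
            inherited += [pass_indels[i] for i in sorted(ind_idx)]
        planted_by_strain[sid] = inherited + own_by_strain[sid]

    # uniqueness relative to the configured pedigree
    comparison_keys: set[tuple] = set()
    for sid in config.comparison_strains:
        comparison_keys |= {p.record.key for p in planted_by_strain[sid]}

    strains: dict[str, list[VariantRecord]] = {}
    rows = []
    for sid in order:
        records = []
        for p in planted_by_strain[sid]:
            records.append(p.record)
            rows.append(
                {
                    "strain": sid,
                    "contig": p.record.contig_id,
                    "pos": p.record.pos,
                    "ref": p.record.ref_allele,
                    "alt": p.record.alt_allele,
                    "variant_class": p.record.variant_class,
                    "genotype_class": p.record.genotype_class,
                    "gene_id": p.gene_id,
                    "element": p.element,
                    "effect_kind": p.effect_kind,
                    "filter_fate": p.filter_fate,
                    "unique": (sid == config.focal
                               and p.record.key not in comparison_keys),
                }
            )
        strains[sid] = sorted(records, key=lambda v: v.key)
    ledger = pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))
    return strains, ledger


def emit_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture to disk; returns the paths written.

    Produces ``ref.fa``, ``models.gff3``, one ``<strain>.vcf`` per strain,
    ``ledger.tsv`` and ``config.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, models = simulate_genome(config)
    strains, ledger = simulate_pedigree_variants(config, genome, models)

    paths: dict[str, Path] = {}
    fasta = out / "ref.fa"
    with open(fasta, "w") as fh:
        for g in genome:
            fh.write(f">{g.contig_id}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i : i + 80] + "\n")
    paths["genome"] = fasta

    gff = out / "models.gff3"
    write_gff3(models, gff)
    paths["models"] = gff

    lengths = {g.contig_id: len(g.sequence) for g in genome}
    for sid, records in strains.items():
        vcf = out / f"{sid}.vcf"
        write_variants(records, vcf, sample_name=sid, contig_lengths=lengths)
        paths[sid] = vcf

    ledger_path = out / "ledger.tsv"
    ledger.to_csv(ledger_path, sep="\t", index=False)
    paths["ledger"] = ledger_path

    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(dataclasses.asdict(config), indent=2,
                                   default=str))
    paths["config"] = cfg_path
    return paths


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/CDS rows with correct phase, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            low, high = m.span
            attrs = f"ID={m.gene_id}.g;product={m.annotation}"
            fh.write(f"{m.contig_id}\tmutscreen\tgene\t{low}\t{high}\t.\t"
                     f"{m.strand}\t.\t{attrs}\n")
            fh.write(f"{m.contig_id}\tmutscreen\tmRNA\t{low}\t{high}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id};Parent={m.gene_id}.g;"
                     f"product={m.annotation}\n")
            exons = list(m.cds_exons)
            coding_order = exons if m.strand == "+" else exons[::-1]
            phase = 0
            phases = {}
            for s, e in coding_order:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(exons, start=1):
                fh.write(f"{m.contig_id}\tmutscreen\tCDS\t{s}\t{e}\t.\t"
                         f"{m.strand}\t{phases[(s, e)]}\t"
                         f"ID={m.gene_id}.cds{i};Parent={m.gene_id}\n")
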