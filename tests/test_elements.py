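"""Element window arithmetic, variant classification, and the cross-tab."""

import numpy as np
import pytest

from mutscreen import (
    GeneModel,
    GenomeSequence,
    VariantRecord,
    build_element_index,
    classify_variant,
    gene_elements,
    tabulate_elements,
)
from mutscreen.elements import classify_all
from mutscreen.formats import HOMOZYGOUS_ALT, reverse_complement


def make_genome(length=10_000, contig="c1", base="A"):
    return [GenomeSequence(contig, base * length)]


def snp(pos, contig="c1", ref="A", alt="G"):
    return VariantRecord(contig, pos, ref, alt, HOMOZYGOUS_ALT)


class TestWindows:
    def test_plus_strand_windows(self):
        gene = GeneModel("g", "c1", "+", ((1000, 1999),))
        elems = gene_elements(gene, contig_len=10_000)
        assert elems.promoter == (1, 999)  # clipped by 1 at the contig start
        assert elems.terminator == (2000, 2499)

    def test_minus_strand_windows(self):
        gene = GeneModel("g", "c1", "-", ((5000, 5999),))
        elems = gene_elements(gene, contig_len=10_000)
        assert elems.promoter == (6000, 6999)
        assert elems.terminator == (4500, 4999)

    def test_window_lengths_exact_away_from_edges(self):
        gene = GeneModel("g", "c1", "+", ((3000, 3599),))
        elems = gene_elements(gene, contig_len=10_000)
        assert elems.promoter[1] - elems.promoter[0] + 1 == 1000
        assert elems.terminator[1] - elems.terminator[0] + 1 == 500

    def test_clipping_at_contig_edges(self):
        gene = GeneModel("g", "c1", "+", ((400, 699),))
        elems = gene_elements(gene, contig_len=800)
        assert elems.promoter == (1, 399)
        assert elems.terminator == (700, 800)
        # a gene flush at the start has no promoter at all
        gene2 = GeneModel("g2", "c1", "+", ((1, 300),))
        assert gene_elements(gene2, contig_len=800).promoter is None

    def test_intron_tiling(self):
        gene = GeneModel("g", "c1", "+", ((100, 199), (300, 350)))
        elems = gene_elements(gene, contig_len=1000)
        assert elems.introns == ((200, 299),)

    def test_exons_and_introns_partition_gene_body(self, small_world):
        _, models, _, _ = small_world
        for gene in models:
            elems = gene_elements(gene, contig_len=10**9)
            pieces = sorted(list(elems.exons) + list(elems.introns))
            low, high = gene.span
            assert pieces[0][0] == low and pieces[-1][1] == high
            for (_, e1), (s2, _) in zip(pieces, pieces[1:]):
                assert s2 == e1 + 1  # no gap, no overlap

    def test_strand_mirror_oracle(self):
        """Mirroring the contig maps promoter to promoter, etc."""
        contig_len = 4000
        gene = GeneModel("g", "c1", "+", ((1500, 1799), (1900, 2199)))
        mirrored_exons = tuple(
            sorted(
                (contig_len - e + 1, contig_len - s + 1)
                for s, e in gene.cds_exons
            )
        )
        mirror = GeneModel("g", "c1", "-", mirrored_exons)
        fwd = gene_elements(gene, contig_len)
        rev = gene_elements(mirror, contig_len)

        def mirror_iv(iv):
            s, e = iv
            return (contig_len - e + 1, contig_len - s + 1)

        assert mirror_iv(fwd.promoter) == rev.promoter
        assert mirror_iv(fwd.terminator) == rev.terminator
        assert sorted(mirror_iv(i) for i in fwd.introns) == sorted(rev.introns)


class TestClassify:
    @pytest.fixture()
    def index(self):
        genome = make_genome(12_000)
        models = [
            GeneModel("gA", "c1", "+", ((3000, 3599),), annotation="a"),
            # gB promoter [4400, 5399] overlaps gA terminator [3600, 4099]? no:
            # adjacent but windows here are disjoint except where stated below
            GeneModel("gB", "c1", "+", ((5400, 5999),), annotation="b"),
        ]
        return build_element_index(models, genome)

    def test_promoter_snp_single_hit(self, index):
        (hit,) = classify_variant(snp(2500), index)
        assert (hit.gene_id, hit.element) == ("gA", "promoter")

    def test_terminator_and_promoter_double_hit_between_adjacent_genes(self, index):
        # gA terminator is [3600, 4099]; gB promoter is [4400, 5399]; a SNP
        # at 4450 sits in gB's promoter only, but one at 4400..4099 boundary
        # cannot double-hit here — build a closer pair instead
        genome = make_genome(12_000)
        models = [
            GeneModel("gA", "c1", "+", ((3000, 3599),)),
            GeneModel("gB", "c1", "+", ((4500, 5099),)),
        ]
        idx = build_element_index(models, genome)
        hits = classify_variant(snp(3700), idx)
        assert {(h.gene_id, h.element) for h in hits} == {
            ("gA", "terminator"),
            ("gB", "promoter"),
        }

    def test_intergenic_is_empty(self, index):
        assert classify_variant(snp(11_500), index) == []

    def test_deletion_inside_terminator_window(self, index):
        # 16 bp deletion wholly inside gA's terminator [3600, 4099]
        v = VariantRecord("c1", 3700, "A" * 17, "A", HOMOZYGOUS_ALT)
        (hit,) = classify_variant(v, index)
        assert (hit.gene_id, hit.element) == ("gA", "terminator")

    def test_boundary_spanning_deletion_reports_both_elements(self):
        genome = make_genome(5000)
        gene = GeneModel("g", "c1", "+", ((1000, 1199), (1300, 1499)))
        idx = build_element_index([gene], genome)
        # deletion spanning the exon1/intron junction at 1199|1200
        v = VariantRecord("c1", 1195, "A" * 10, "A", HOMOZYGOUS_ALT)
        hits = {(h.gene_id, h.element) for h in classify_variant(v, idx)}
        assert hits == {("g", "exon"), ("g", "intron")}

    def test_brute_force_membership_equivalence(self, small_world):
        genome, models, strains, _ = small_world
        index = build_element_index(models, genome)
        contig_lens = {g.contig_id: len(g) for g in genome}

        def brute(variant):
            hits = set()
            a, b = variant.affected_span()
            for gene in models:
                if gene.contig_id != variant.contig_id:
                    continue
                elems = gene_elements(gene, contig_lens[gene.contig_id])
                for kind, (s, e) in elems.intervals():
                    if a <= e and s <= b:
                        hits.add((gene.gene_id, kind))
            return hits

        records = [v for recs in strains.values() for v in recs]
        assert records
        for v in records:
            got = {(h.gene_id, h.element) for h in classify_variant(v, index)}
            assert got == brute(v), f"mismatch at {v.key}"

    def test_strand_symmetry_of_classification(self, small_world):
        """Classification is invariant under reverse-complementing the world."""
        genome, models, strains, _ = small_world
        index = build_element_index(models, genome)
        lens = {g.contig_id: len(g) for g in genome}
        flipped_genome = [
            GenomeSequence(g.contig_id, reverse_complement(g.sequence))
            for g in genome
        ]
        flipped_models = [
            GeneModel(
                m.gene_id,
                m.contig_id,
                "-" if m.strand == "+" else "+",
                tuple(
                    sorted(
                        (lens[m.contig_id] - e + 1, lens[m.contig_id] - s + 1)
                        for s, e in m.cds_exons
                    )
                ),
                m.annotation,
            )
            for m in models
        ]
        flipped_index = build_element_index(flipped_models, flipped_genome)
        rng = np.random.default_rng(3)
        snps = [v for recs in strains.values() for v in recs if v.is_snp]
        for v in rng.choice(len(snps), size=min(40, len(snps)), replace=False):
            v = snps[int(v)]
            mirror = VariantRecord(
                v.contig_id,
                lens[v.contig_id] - v.pos + 1,
                reverse_complement(v.ref_allele),
                reverse_complement(v.alt_allele),
                v.genotype_class,
            )
            got = {
                (h.gene_id, h.element)
                for h in classify_variant(mirror, flipped_index)
            }
            want = {
                (h.gene_id, h.element) for h in classify_variant(v, index)
            }
            assert got == want


class TestTabulate:
    def test_double_hit_counts_in_both_cells(self):
        genome = make_genome(12_000)
        models = [
            GeneModel("gA", "c1", "+", ((3000, 3599),)),
            GeneModel("gB", "c1", "+", ((4500, 5099),)),
        ]
        idx = build_element_index(models, genome)
        v = snp(3700)
        hits = classify_variant(v, idx)
        tab = tabulate_elements(hits, [v])
        assert tab.counts.loc["terminator", "SNP"] == 1
        assert tab.counts.loc["promoter", "SNP"] == 1
        assert tab.genes_affected["SNP"] == 2
        assert tab.intergenic["SNP"] == 0

    def test_no_hits_means_all_intergenic(self):
        variants = [snp(10), snp(20), snp(30)]
        tab = tabulate_elements([], variants)
        assert tab.intergenic["SNP"] == 3
        assert int(tab.counts.values.sum()) == 0

    def test_fixture_crosstab_matches_ledger(self, small_world):
        genome, models, strains, ledger = small_world
        focal = "SS-II"
        index = build_element_index(models, genome)
        records = strains[focal]
        hits = classify_all(records, index)
        tab = tabulate_elements(hits, records)
        truth = ledger[ledger.strain == focal]
        for element in ("promoter", "terminator", "intron", "exon"):
            for cls, classes in (("SNP", {"SNP"}), ("indel", {"insertion", "deletion"})):
                expected = int(
                    (
                        (truth.element == element)
                        & truth.variant_class.isin(classes)
                    ).sum()
                )
                assert tab.counts.loc[element, cls] == expected
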