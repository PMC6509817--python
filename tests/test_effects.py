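"""Codon-aware effect calling: synonymy, frameshifts, labels, strand."""

import numpy as np
import pytest

from mutscreen import (
    GeneModel,
    GenomeSequence,
    VariantRecord,
    build_element_index,
    call_effect,
    call_effects,
    classify_variant,
    count_effects,
    spliced_cds,
    translate_cds,
)
from mutscreen.effects import (
    FRAMESHIFT,
    INFRAME_INDEL,
    NONCODING,
    NONSYNONYMOUS,
    SYNONYMOUS,
)
from mutscreen.elements import ElementHit
from mutscreen.formats import HOMOZYGOUS_ALT, reverse_complement


def embed_gene(cds, strand="+", start=2001, contig_len=8000, gene_id="g1"):
    """Place a single-exon CDS into an A-filled contig; returns (genome, model)."""
    body = cds if strand == "+" else reverse_complement(cds)
    seq = "A" * (start - 1) + body + "A" * (contig_len - start + 1 - len(body))
    genome = [GenomeSequence("c1", seq)]
    model = GeneModel(
        gene_id, "c1", strand, ((start, start + len(cds) - 1),), annotation="x"
    )
    return genome, model


def exon_hit(variant, model):
    return ElementHit(variant, model.gene_id, "exon", model.strand)


class TestSplicedCds:
    def test_two_exon_plus_gene_translates(self):
        seq = "TT" + "ATGGCT" + "GGGG" + "TAA" + "TT"
        genome = [GenomeSequence("c1", seq)]
        model = GeneModel("g", "c1", "+", ((3, 8), (13, 15)))
        cds = spliced_cds(model, genome)
        assert cds == "ATGGCTTAA"
        assert translate_cds(cds) == "MA*"

    def test_minus_gene_reverse_complemented(self):
        # coding sequence ATGGCTTAA on the minus strand
        cds = "ATGGCTTAA"
        genome, model = embed_gene(cds, strand="-", start=101, contig_len=400)
        assert spliced_cds(model, genome) == cds
        # independent route: translate the reverse-complemented raw slice
        raw = genome[0].slice(101, 101 + len(cds) - 1)
        assert reverse_complement(raw) == cds

    def test_single_exon_identity(self):
        cds = "ATGAAATAA"
        genome, model = embed_gene(cds, start=51, contig_len=300)
        assert spliced_cds(model, genome) == genome[0].slice(51, 59)


def build_cys193_gene(strand):
    """195-codon CDS whose codon 193 reads TGT (Cys)."""
    codons = ["ATG"] + ["GCT"] * 191 + ["TGT", "GAA", "TAA"]
    cds = "".join(codons)
    assert cds[576:579] == "TGT"
    return embed_gene(cds, strand=strand, start=1501, contig_len=6000)


class TestSnpEffects:
    def test_cys193_to_arg_plus_strand(self):
        genome, model = build_cys193_gene("+")
        pos = 1501 + 576  # first base of codon 193
        v = VariantRecord("c1", pos, "T", "C", HOMOZYGOUS_ALT)
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == NONSYNONYMOUS
        assert (call.aa_ref, call.aa_pos, call.aa_alt) == ("Cys", 193, "Arg")
        assert call.label == "T -> C (exon: Cys193 -> Arg)"

    def test_cys193_to_arg_minus_strand_mirror(self):
        genome, model = build_cys193_gene("-")
        # codon 193 first base has CDS offset 576; on the minus strand that
        # maps to reference position start + (L-1-576)
        length = model.cds_length
        pos = 1501 + (length - 1 - 576)
        v = VariantRecord("c1", pos, "A", "G", HOMOZYGOUS_ALT)  # revcomp T->C
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == NONSYNONYMOUS
        assert (call.aa_ref, call.aa_pos, call.aa_alt) == ("Cys", 193, "Arg")

    def test_synonymous_third_position(self):
        cds = "ATG" + "GCT" + "TAA"
        genome, model = embed_gene(cds, start=901)
        v = VariantRecord("c1", 901 + 5, "T", "C", HOMOZYGOUS_ALT)  # GCT->GCC
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == SYNONYMOUS
        assert call.label.endswith("(exon: synonymous variant)")

    def test_stop_gained_is_nonsynonymous_ter(self):
        cds = "ATG" + "TGC" + "AAA" + "TAA"
        genome, model = embed_gene(cds, start=701)
        # TGC -> TGA at codon 2
        v = VariantRecord("c1", 701 + 5, "C", "A", HOMOZYGOUS_ALT)
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == NONSYNONYMOUS
        assert call.aa_alt == "Ter"

    def test_synonymy_symmetric_under_allele_swap(self, small_world):
        genome, models, strains, ledger = small_world
        index = build_element_index(models, genome)
        models_by = {m.gene_id: m for m in models}
        exonic = ledger[
            (ledger.effect_kind.isin([SYNONYMOUS, NONSYNONYMOUS]))
            & (ledger.filter_fate == "pass")
        ].drop_duplicates(subset=["contig", "pos", "ref", "alt"])
        assert len(exonic) >= 10
        # swapping ref/alt needs the alt genome; emulate by patching the contig
        contigs = {g.contig_id: g for g in genome}
        for row in exonic.itertuples():
            v = VariantRecord(row.contig, row.pos, row.ref, row.alt, HOMOZYGOUS_ALT)
            (hit,) = classify_variant(v, index)
            fwd = call_effect(v, hit, models_by[hit.gene_id], genome)
            seq = contigs[row.contig].sequence
            patched = seq[: row.pos - 1] + row.alt + seq[row.pos :]
            alt_genome = [
                GenomeSequence(c, patched if c == row.contig else g.sequence)
                for c, g in contigs.items()
            ]
            w = VariantRecord(row.contig, row.pos, row.alt, row.ref, HOMOZYGOUS_ALT)
            rev = call_effect(w, hit, models_by[hit.gene_id], alt_genome)
            assert rev.kind == fwd.kind
            assert (rev.aa_ref, rev.aa_alt) == (fwd.aa_alt, fwd.aa_ref)

    def test_full_retranslation_oracle(self, small_world):
        """Codon-level call equals brute-force re-translation of the whole
        mutated spliced CDS, residue by residue."""
        genome, models, strains, ledger = small_world
        index = build_element_index(models, genome)
        models_by = {m.gene_id: m for m in models}
        contigs = {g.contig_id: g for g in genome}
        exonic = ledger[
            ledger.effect_kind.isin([SYNONYMOUS, NONSYNONYMOUS])
        ].drop_duplicates(subset=["contig", "pos", "ref", "alt"])
        assert len(exonic) >= 10
        for row in exonic.itertuples():
            v = VariantRecord(row.contig, row.pos, row.ref, row.alt, HOMOZYGOUS_ALT)
            (hit,) = classify_variant(v, index)
            gene = models_by[hit.gene_id]
            call = call_effect(v, hit, gene, genome)
            seq = contigs[row.contig].sequence
            patched = seq[: row.pos - 1] + row.alt + seq[row.pos :]
            alt_genome = [
                GenomeSequence(c, patched if c == row.contig else g.sequence)
                for c, g in contigs.items()
            ]
            ref_protein = translate_cds(spliced_cds(gene, genome))
            alt_protein = translate_cds(spliced_cds(gene, alt_genome))
            diffs = [
                (i + 1, a, b)
                for i, (a, b) in enumerate(zip(ref_protein, alt_protein))
                if a != b
            ]
            if call.kind == SYNONYMOUS:
                assert diffs == []
            else:
                assert len(diffs) == 1
                pos, ref_aa, alt_aa = diffs[0]
                assert pos == call.aa_pos


class TestIndelEffects:
    def test_one_base_deletion_is_frameshift(self):
        cds = "ATG" + "GCTGCA" + "TAA"
        genome, model = embed_gene(cds, start=501)
        v = VariantRecord("c1", 501 + 3, "GC", "G", HOMOZYGOUS_ALT)
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == FRAMESHIFT

    def test_three_base_insertion_is_inframe_with_label(self):
        cds = "ATG" + "GCTGCA" + "TAA"
        genome, model = embed_gene(cds, start=501)
        v = VariantRecord("c1", 501 + 4, "C", "CTCT", HOMOZYGOUS_ALT)
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == INFRAME_INDEL
        assert call.label == "+ 3: TCT (exon)"

    def test_boundary_spanning_deletion_counts_exonic_bases_only(self):
        # exon1 [1001,1100], intron [1101,1160], exon2 [1161,1240];
        # deleting [1098,1104] removes 3 exonic + 4 intronic bases -> in-frame
        seq = "A" * 3000
        genome = [GenomeSequence("c1", seq)]
        model = GeneModel("g", "c1", "+", ((1001, 1100), (1161, 1240)))
        v = VariantRecord("c1", 1097, "A" * 8, "A", HOMOZYGOUS_ALT)
        call = call_effect(v, exon_hit(v, model), model, genome)
        assert call.kind == INFRAME_INDEL
        assert "splice-adjacent" in call.label

    def test_noncoding_labels_name_the_element(self):
        cds = "ATGTAA"
        genome, model = embed_gene(cds, start=3001)
        v = VariantRecord("c1", 2500, "A" * 17, "A", HOMOZYGOUS_ALT)
        hit = ElementHit(v, model.gene_id, "promoter", model.strand)
        call = call_effect(v, hit, model, genome)
        assert call.kind == NONCODING
        assert call.label == "- 16: AAAAAAAAAAAAAAAA (promoter)"


class TestCountEffects:
    def test_counts_match_ledger(self, small_world):
        genome, models, strains, ledger = small_world
        index = build_element_index(models, genome)
        focal = "SS-II"
        records = [
            v
            for v in strains[focal]
            if any(True for _ in classify_variant(v, index))
        ]
        from mutscreen.elements import classify_all

        hits = classify_all(records, index)
        summary = count_effects(call_effects(hits, models, genome))
        truth = ledger[(ledger.strain == focal) & (ledger.filter_fate == "pass")]
        assert summary.n_synonymous == int((truth.effect_kind == SYNONYMOUS).sum())
        assert summary.n_nonsynonymous == int(
            (truth.effect_kind == NONSYNONYMOUS).sum()
        )
        assert summary.n_frameshift == int((truth.effect_kind == FRAMESHIFT).sum())
        assert summary.n_inframe == int((truth.effect_kind == INFRAME_INDEL).sum())

    def test_multiple_mutations_one_gene_joined(self):
        cds = "ATG" + "GCTGCAGGT" + "TAA"
        genome, model = embed_gene(cds, start=401)
        v1 = VariantRecord("c1", 401 + 3, "G", "T", HOMOZYGOUS_ALT)
        v2 = VariantRecord("c1", 401 + 6, "G", "T", HOMOZYGOUS_ALT)
        calls = [
            call_effect(v, exon_hit(v, model), model, genome) for v in (v1, v2)
        ]
        summary = count_effects(calls)
        joined = summary.per_gene_labels[model.gene_id]
        assert joined.count(";") == 1
        assert joined.index(calls[0].label) < joined.index(calls[1].label)

    def test_empty_input_all_zero(self):
        summary = count_effects([])
        assert (
            summary.n_synonymous
            == summary.n_nonsynonymous
            == summary.n_frameshift
            == summary.n_inframe
            == 0
        )
        assert summary.per_gene_labels == {}
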