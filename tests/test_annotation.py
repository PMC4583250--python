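"""Annotation: variant typing, the vertebrate mitochondrial code, codon
context on both strands, homopolymer context, predictor concordance."""

import pytest

from mitoburden.annotation import (
    annotate,
    classify_variant_type,
    codon_context,
    concordance_filter,
    conservation_flag,
    homopolymer_flag,
    mitomap_status,
    reverse_complement,
    translate_codon,
)
from mitoburden.core_model import GeneRecord, MitoGenome, MitoGeneModel
from mitoburden.errors import ValidationError
from mitoburden.filtering import AggregatedVariant
from mitoburden.io_formats import VariantKey


class TestClassifyVariantType:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("C", "A", "substitution"),
            ("T", "TA", "insertion"),
            ("GA", "G", "deletion"),
            ("AC", "GT", "complex"),
            ("A", "TG", "complex"),
        ],
    )
    def test_allele_pairs(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_empty_allele_rejected(self):
        with pytest.raises(ValidationError):
            classify_variant_type("", "A")

    def test_printed_unknown_list_has_exactly_three_indels(self, paper_fixture):
        types = [
            classify_variant_type(r["ref"], r["alt"])
            for _, r in paper_fixture.unknown.iterrows()
        ]
        assert sum(t == "substitution" for t in types) == 32
        assert sum(t in ("insertion", "deletion") for t in types) == 3


class TestGeneticCode:
    @pytest.mark.parametrize(
        "codon,aa",
        [("ATA", "M"), ("TGA", "W"), ("AGA", "*"), ("AGG", "*"),
         ("ATG", "M"), ("TTA", "L"), ("TAA", "*")],
    )
    def test_mitochondrial_specific_codons(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_printed_codon_changes_all_translate(self, paper_fixture):
        # every printed codon pair must reproduce its printed amino-acid pair
        for _, row in paper_fixture.concordant.iterrows():
            ref_codon, alt_codon = row["codon_change"].split("/")
            ref_aa, alt_aa = row["aa_change"].split("/")
            assert translate_codon(ref_codon) == ref_aa, row["codon_change"]
            assert translate_codon(alt_codon) == alt_aa, row["codon_change"]

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValidationError):
            translate_codon("ANN")


class TestCodonContext:
    def test_plus_strand_first_position(self, toy_model):
        # PCP starts at 10 with codon CTA; C→A gives ATA: L→M missense
        cc = codon_context(VariantKey(10, "C", "A"), toy_model)
        assert cc.codon_change == "Cta/Ata"
        assert cc.aa_change == "L/M"
        assert cc.effect == "missense"

    def test_minus_strand_first_position(self, toy_model):
        # PCM coding codon at its 3' heavy-strand end is ATG; heavy T→C reads
        # coding A→G: M→V missense, rendered in coding orientation
        cc = codon_context(VariantKey(79, "T", "C"), toy_model)
        assert cc.codon_change == "Atg/Gtg"
        assert cc.aa_change == "M/V"
        assert cc.effect == "missense"

    def test_synonymous_third_position(self, toy_genome):
        genome = MitoGenome(name="g", length=12, circular=True, sequence="ATGCTTAAATAG")
        gene = GeneRecord("G1", "protein_coding", 1, 12, "+", 12)
        model = MitoGeneModel(genome=genome, genes=[gene])
        # CTT→CTG both leucine
        cc = codon_context(VariantKey(6, "T", "G"), model)
        assert cc.effect == "synonymous"
        assert cc.aa_change == "L/L"
        assert cc.codon_change == "ctT/ctG"

    def test_nonsense_and_stop_loss(self):
        genome = MitoGenome(name="g", length=6, circular=True, sequence="TGGTAA")
        gene = GeneRecord("G1", "protein_coding", 1, 6, "+", 6)
        model = MitoGeneModel(genome=genome, genes=[gene])
        assert codon_context(VariantKey(2, "G", "A"), model).effect == "nonsense"  # TGG→TAG
        assert codon_context(VariantKey(5, "A", "T"), model).effect == "stop_loss"  # TAA→TTA

    def test_reference_mismatch_detected(self, toy_model):
        with pytest.raises(ValidationError, match="does not match"):
            codon_context(VariantKey(10, "G", "A"), toy_model)

    def test_strand_equivalence_oracle(self, toy_genome, toy_model):
        """Annotating a light-strand gene must equal annotating its
        reverse-complement as a + gene on the reverse-complemented genome."""
        L = toy_genome.length
        gene = toy_model["PCM"]  # 50..79 on '-'
        rc_seq = reverse_complement(toy_genome.sequence)
        rc_genome = MitoGenome(name="rc", length=L, circular=True, sequence=rc_seq)
        rc_gene = GeneRecord("PCMrc", "protein_coding",
                             L - gene.end + 1, L - gene.start + 1, "+", 30)
        rc_model = MitoGeneModel(genome=rc_genome, genes=[rc_gene])
        for pos in range(gene.start, gene.end + 1):
            ref = toy_genome.base(pos)
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            cc = codon_context(VariantKey(pos, ref, alt), toy_model, gene=gene)
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            rc_pos = L - pos + 1
            cc_rc = codon_context(
                VariantKey(rc_pos, comp[ref], comp[alt]), rc_model, gene=rc_gene
            )
            assert cc == cc_rc, pos


class TestMembershipFlags:
    def test_mitomap_status(self, paper_fixture):
        assert mitomap_status(VariantKey(15218, "A", "G"), paper_fixture.catalog) == "Known"
        assert mitomap_status(VariantKey(9500, "C", "A"), paper_fixture.catalog) == "Unknown"
        assert mitomap_status(VariantKey(15218, "A", "G"), set()) == "Unknown"

    def test_conservation_flag(self):
        assert conservation_flag(6489, {6489, 100})
        assert not conservation_flag(6490, {6489})
        assert not conservation_flag(6489, set())


class TestHomopolymerFlag:
    def test_inside_run_of_four(self, toy_genome):
        for pos in range(90, 94):  # the planted AAAA run
            assert homopolymer_flag(pos, toy_genome, min_run=4)

    def test_adjacent_to_run(self, toy_genome):
        assert homopolymer_flag(89, toy_genome, min_run=4)
        assert homopolymer_flag(94, toy_genome, min_run=4)
        assert not homopolymer_flag(87, toy_genome, min_run=4)

    def test_no_runs_anywhere(self):
        genome = MitoGenome(name="g", length=8, circular=True, sequence="ACGTACGT")
        assert not any(homopolymer_flag(p, genome, 4) for p in range(1, 9))

    def test_circular_run_across_origin(self):
        genome = MitoGenome(name="g", length=12, circular=True, sequence="AACGTACGTCAA")
        # A run A(11) A(12) A(1) A(2) wraps the origin
        for pos in (11, 12, 1, 2):
            assert homopolymer_flag(pos, genome, min_run=4)
        assert not homopolymer_flag(6, genome, min_run=4)


def _variant(pos, ref, alt, carriers=("S1",)):
    return AggregatedVariant(key=VariantKey(pos, ref, alt), carriers=tuple(carriers))


class TestConcordanceFilter:
    def test_keeps_only_double_damaging(self, toy_model):
        variants = annotate(
            [_variant(41, "A", "G"), _variant(42, "C", "T"), _variant(43, "G", "A")],
            toy_model,
            predictions={
                VariantKey(41, "A", "G"): ("deleterious", "probably_damaging"),
                VariantKey(42, "C", "T"): ("deleterious", "possibly_damaging"),
            },
        )
        kept = concordance_filter(variants)
        assert [v.key.position for v in kept] == [41]

    def test_idempotent_subset(self, toy_model):
        variants = annotate(
            [_variant(41, "A", "G")],
            toy_model,
            predictions={VariantKey(41, "A", "G"): ("deleterious", "probably_damaging")},
        )
        once = concordance_filter(variants)
        assert concordance_filter(once) == once
        assert set(v.key for v in once) <= set(v.key for v in variants)


class TestAnnotate:
    def test_intergenic_variant(self, toy_model):
        (v,) = annotate([_variant(45, "A", "G")], toy_model)
        a = v.annotations
        assert a.region_class == "intergenic"
        assert a.effect == "intergenic"
        assert a.genes == () and a.codon_change is None

    def test_rrna_variant_non_coding(self, toy_model):
        (v,) = annotate([_variant(100, "A", "G")], toy_model)
        assert v.annotations.region_class == "non_coding_exon"
        assert v.annotations.effect == "non_coding"
        assert v.annotations.genes == ("RNR",)

    def test_coding_substitution_gets_codon_fields(self, toy_model):
        (v,) = annotate([_variant(10, "C", "A")], toy_model)
        a = v.annotations
        assert a.region_class == "coding_exon"
        assert (a.codon_change, a.aa_change, a.effect) == ("Cta/Ata", "L/M", "missense")

    def test_coding_indel_is_frameshift_candidate(self, toy_model):
        ref = toy_model.genome.base(15)
        (v,) = annotate([_variant(15, ref, ref + "A")], toy_model)
        assert v.annotations.variant_type == "insertion"
        assert v.annotations.effect == "frameshift_candidate"
        assert v.annotations.codon_change is None

    def test_annotations_consistent_with_translation(self, toy_model):
        """Property: translate(ref codon) / translate(alt codon) equal the two
        letters of aa_change for every coding substitution."""
        genome = toy_model.genome
        variants = []
        for pos in range(10, 40):
            ref = genome.base(pos)
            variants.append(_variant(pos, ref, {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]))
        for v in annotate(variants, toy_model):
            a = v.annotations
            ref_codon, alt_codon = a.codon_change.split("/")
            assert translate_codon(ref_codon) == a.aa_change[0]
            assert translate_codon(alt_codon) == a.aa_change[-1]
            upper_ref = [i for i, ch in enumerate(ref_codon) if ch.isupper()]
            upper_alt = [i for i, ch in enumerate(alt_codon) if ch.isupper()]
            assert upper_ref == upper_alt and len(upper_ref) == 1
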