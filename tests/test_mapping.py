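"""Genomic-to-protein mapping, checked against independent full-CDS
translation."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from mutbind import io as mio
from mutbind.mapping import (
    build_reference_set,
    map_mutation_to_isoform,
    reference_sequences,
    select_isoform,
    spliced_cds,
)
from mutbind.types import GenomicMutation, ReferenceMismatchError, TranscriptModel

from conftest import make_genome

CDS = "ATGGCCAAA"  # Met-Ala-Lys


def plus_tx():
    return TranscriptModel("G1", "G1.1", 1, "chrT", "+", ((101, 109),))


def minus_tx():
    # top strand holds the reverse complement; transcript reads 109 -> 101
    return TranscriptModel("G1", "G1.1", 1, "chrT", "-", ((101, 109),))


@pytest.fixture()
def plus_genome(tmp_path):
    return make_genome(tmp_path, {"chrT": "N" * 100 + CDS})


@pytest.fixture()
def minus_genome(tmp_path):
    rc = str(Seq(CDS).reverse_complement())
    return make_genome(tmp_path, {"chrT": "N" * 100 + rc})


class TestSingleMutation:
    def test_missense_call(self, plus_genome):
        mut = GenomicMutation("chrT", 104, "G", "A", "S1", "C", "missense")
        pm = map_mutation_to_isoform(mut, plus_tx(), plus_genome)
        assert (pm.protein_pos, pm.ref_aa, pm.alt_aa, pm.var_class) == (2, "A", "T", "missense")

    def test_synonymous_call(self, plus_genome):
        mut = GenomicMutation("chrT", 106, "C", "A", "S1", "C", "missense")
        pm = map_mutation_to_isoform(mut, plus_tx(), plus_genome)
        assert (pm.protein_pos, pm.ref_aa, pm.alt_aa, pm.var_class) == (2, "A", "A", "synonymous")

    def test_minus_strand_matches_plus(self, minus_genome):
        # same CDS on the minus strand: the top-strand record is
        # complemented, codon 2 position 1 sits at genomic 106
        mut = GenomicMutation("chrT", 106, "C", "T", "S1", "C", "missense")
        pm = map_mutation_to_isoform(mut, minus_tx(), minus_genome)
        assert (pm.protein_pos, pm.ref_aa, pm.alt_aa, pm.var_class) == (2, "A", "T", "missense")
        # oracle: translate the full mutated spliced sequence
        mutated = spliced_cds(minus_tx(), minus_genome)
        assert str(Seq(mutated).translate()) == "MAK"

    def test_intron_returns_none(self, tmp_path):
        genome = make_genome(tmp_path, {"chrT": "N" * 100 + "ATGXXXGCCAAA".replace("X", "T")})
        tx = TranscriptModel("G1", "G1.1", 1, "chrT", "+", ((101, 103), (107, 112)))
        mut = GenomicMutation("chrT", 105, "T", "A", "S1", "C", "missense")
        assert map_mutation_to_isoform(mut, tx, genome) is None

    def test_reference_mismatch_raises(self, plus_genome):
        mut = GenomicMutation("chrT", 104, "C", "A", "S1", "C", "missense")
        with pytest.raises(ReferenceMismatchError, match="mismatch"):
            map_mutation_to_isoform(mut, plus_tx(), plus_genome)

    def test_stop_gain_classified_other(self, tmp_path):
        genome = make_genome(tmp_path, {"chrT": "N" * 100 + "ATGTGGAAA"})
        tx = plus_tx()
        mut = GenomicMutation("chrT", 105, "G", "A", "S1", "C", "missense")  # TGG->TGA
        pm = map_mutation_to_isoform(mut, tx, genome)
        assert (pm.alt_aa, pm.var_class) == ("*", "other")


class TestIsoformSelection:
    def test_argmax(self):
        im = select_isoform("G", {"A": 3, "B": 5}, {"A": 1, "B": 2})
        assert im.chosen_isoform_id == "B"

    def test_tie_goes_to_first_reported(self):
        im = select_isoform("G", {"A": 3, "B": 3}, {"A": 1, "B": 2})
        assert im.chosen_isoform_id == "A"
        im = select_isoform("G", {"A": 3, "B": 3}, {"A": 2, "B": 1})
        assert im.chosen_isoform_id == "B"

    def test_sole_isoform_with_zero_mapped(self):
        im = select_isoform("G", {"A": 0}, {"A": 1})
        assert im.chosen_isoform_id == "A"
        assert im.mapped_mutated_positions == 0


class TestReferenceSet:
    def test_chooses_isoform_mapping_most_positions(self, tmp_path):
        # isoform A spans both exons, isoform B only the first
        genome = make_genome(
            tmp_path, {"chrT": "N" * 100 + "ATGGCC" + "GTGTGTGTGTGTGTGTGTGT" + "AAAGGG"}
        )
        tx_a = TranscriptModel("G1", "A", 1, "chrT", "+", ((101, 106), (127, 132)))
        tx_b = TranscriptModel("G1", "B", 2, "chrT", "+", ((101, 106),))
        muts = [
            GenomicMutation("chrT", 102, "T", "A", "S1", "C"),
            GenomicMutation("chrT", 104, "G", "A", "S2", "C"),
            GenomicMutation("chrT", 128, "A", "T", "S3", "C"),
            GenomicMutation("chrT", 131, "G", "T", "S4", "C"),
        ]
        refset = build_reference_set(muts, [tx_a, tx_b], genome)
        (im,) = refset.isoform_mappings
        assert im.chosen_isoform_id == "A"
        assert im.per_isoform_counts == {"A": 4, "B": 2}
        assert len(refset.mapped) == 4
        assert all(pm.isoform_id == "A" for pm in refset.mapped)

    def test_intronic_mutation_in_unmapped_ledger(self, tmp_path):
        genome = make_genome(
            tmp_path, {"chrT": "N" * 100 + "ATGGCC" + "GTGTGTGTGTGTGTGTGTGT" + "AAAGGG"}
        )
        tx = TranscriptModel("G1", "A", 1, "chrT", "+", ((101, 106), (127, 132)))
        muts = [
            GenomicMutation("chrT", 102, "T", "A", "S1", "C"),
            GenomicMutation("chrT", 110, "T", "A", "S1", "C"),  # intron
        ]
        refset = build_reference_set(muts, [tx], genome)
        assert len(refset.mapped) == 1
        ((unmapped_mut, reason),) = refset.unmapped
        assert unmapped_mut.pos == 110
        assert reason == "not in CDS"

    def test_conservation_on_fixture(self, small_bundle):
        bundle, manifest = small_bundle
        muts = mio.read_mutations(bundle / "mutations.tsv")
        transcripts = mio.read_transcripts(bundle / "transcripts.tsv")
        genome = mio.GenomeStore(bundle / "genome.fa")
        refset = build_reference_set(muts, transcripts, genome)
        assert len(refset.mapped) + len(refset.unmapped) == len(muts)
        # every planted event is inside a CDS by construction
        assert len(refset.mapped) == manifest["n_mutations"]
        # mapped calls agree with the generator's planted ground truth
        planted = sorted(
            (e["gene"], e["protein_pos"], e["sample"], e["class"])
            for e in manifest["events"]
        )
        observed = sorted(
            (pm.gene_id, pm.protein_pos, pm.sample_id, pm.var_class)
            for pm in refset.mapped
        )
        assert observed == planted

    def test_reference_sequences_match_manifest(self, small_bundle):
        bundle, manifest = small_bundle
        muts = mio.read_mutations(bundle / "mutations.tsv")
        transcripts = mio.read_transcripts(bundle / "transcripts.tsv")
        genome = mio.GenomeStore(bundle / "genome.fa")
        refset = build_reference_set(muts, transcripts, genome)
        refseqs = reference_sequences(transcripts, genome, refset.isoform_mappings)
        for gene_id, info in manifest["genes"].items():
            assert refseqs[gene_id] == info["protein"]


# --- property: codon-level calls agree with naive full-CDS translation ----

_CODING = [
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if str(Seq(c).translate()) != "*"
]


@st.composite
def cds_and_mutation(draw):
    codons = draw(st.lists(st.sampled_from(_CODING), min_size=2, max_size=12))
    cds = "".join(codons)
    offset = draw(st.integers(1, len(cds)))
    ref = cds[offset - 1]
    alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
    strand = draw(st.sampled_from("+-"))
    return cds, offset, alt, strand


@settings(max_examples=120, deadline=None)
@given(cds_and_mutation())
def test_translation_agrees_with_naive_oracle(tmp_path_factory, case):
    cds, offset, alt, strand = case
    tmp = tmp_path_factory.mktemp("hyp")
    start = 101
    if strand == "+":
        chrom_seq = "N" * 100 + cds
        genomic_pos = start + offset - 1
        top_ref, top_alt = cds[offset - 1], alt
    else:
        chrom_seq = "N" * 100 + str(Seq(cds).reverse_complement())
        genomic_pos = start + len(cds) - offset
        comp = str.maketrans("ACGT", "TGCA")
        top_ref, top_alt = cds[offset - 1].translate(comp), alt.translate(comp)
    genome = make_genome(tmp, {"chrT": chrom_seq})
    tx = TranscriptModel("G", "G.1", 1, "chrT", strand, ((start, start + len(cds) - 1),))
    mut = GenomicMutation("chrT", genomic_pos, top_ref, top_alt, "S", "C")
    pm = map_mutation_to_isoform(mut, tx, genome)

    # oracle: translate reference and mutated CDS in full, diff proteins
    mutated_cds = cds[: offset - 1] + alt + cds[offset:]
    ref_protein = str(Seq(cds).translate())
    alt_protein = str(Seq(mutated_cds).translate())
    codon_i = (offset - 1) // 3
    assert pm.protein_pos == codon_i + 1
    assert pm.ref_aa == ref_protein[codon_i]
    assert pm.alt_aa == alt_protein[codon_i]
    expected = (
        "other" if "*" in (pm.ref_aa, pm.alt_aa)
        else "synonymous" if pm.ref_aa == pm.alt_aa
        else "missense"
    )
    assert pm.var_class == expected
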