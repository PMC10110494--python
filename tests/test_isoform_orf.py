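"""Junction extraction, isoform assembly, ORF scanning, domain annotation."""

import pytest

from _oracles import maximal_compatible_junction_sets
from dupliscan.isoform_orf import (
    IsoformError,
    SpliceJunction,
    assemble_isoforms,
    call_substitutions,
    count_region_residue,
    extract_junctions,
    longest_orf,
    maximal_compatible_chains,
    scan_orfs,
    splice_transcript,
)
from dupliscan.seq_core import AlignmentRecordLite, GenomicInterval, SequenceRecord
from dupliscan.synthetic_data import ancestral_protein, W_REGION_AA


def read(pos, cigar, mapq=60, contig="chr1", name="r"):
    qlen = sum(n for n, op in cigar if op in "MIS")
    return AlignmentRecordLite(name, contig, pos, mapq, cigar, "A" * qlen)


def junction(start, end, support=5, contig="chr1"):
    return SpliceJunction(contig, GenomicInterval(contig, start, end), support)


class TestExtractJunctions:
    def test_intron_coordinates_from_cigar_walk(self):
        recs = [read(101, [(20, "M"), (100, "N"), (20, "M")])]
        (j,) = extract_junctions(recs, min_support=1)
        assert (j.intron.start, j.intron.end) == (120, 220)
        assert j.support == 1

    def test_low_mapq_reads_filtered(self):
        recs = [read(101, [(20, "M"), (100, "N"), (20, "M")], mapq=5)]
        assert extract_junctions(recs, mapq_min=20, min_support=1) == []

    def test_two_introns_from_one_read(self):
        recs = [read(1, [(10, "M"), (50, "N"), (10, "M"), (50, "N"), (10, "M")])]
        juncs = extract_junctions(recs, min_support=1)
        assert [(j.intron.start, j.intron.end) for j in juncs] == [
            (10, 60), (70, 120)
        ]

    def test_support_aggregates_and_min_support_drops(self):
        recs = [read(101, [(20, "M"), (100, "N"), (20, "M")], name=f"r{i}")
                for i in range(3)]
        recs.append(read(500, [(10, "M"), (40, "N"), (10, "M")], name="lonely"))
        juncs = extract_junctions(recs, min_support=2)
        assert len(juncs) == 1 and juncs[0].support == 3

    def test_insertions_do_not_consume_reference(self):
        recs = [read(101, [(10, "M"), (5, "I"), (10, "M"), (50, "N"), (10, "M")])]
        (j,) = extract_junctions(recs, min_support=1)
        assert (j.intron.start, j.intron.end) == (120, 170)

    def test_terminal_n_skipped_with_warning(self):
        recs = [read(101, [(50, "N"), (20, "M")])]
        with pytest.warns(UserWarning, match="terminal N"):
            assert extract_junctions(recs, min_support=1) == []


class TestAssembleIsoforms:
    SPAN = GenomicInterval("chr1", 0, 1000)

    def test_single_chain_gives_one_model(self):
        juncs = [junction(100, 200), junction(300, 400), junction(500, 600)]
        (model,) = assemble_isoforms(juncs, self.SPAN)
        assert [(e.start, e.end) for e in model.exons] == [
            (0, 100), (200, 300), (400, 500), (600, 1000)
        ]
        assert model.junction_support == [5, 5, 5]

    def test_alternative_junctions_give_two_models(self):
        juncs = [
            junction(100, 200), junction(300, 400),
            junction(500, 600), junction(500, 650),
        ]
        models = assemble_isoforms(juncs, self.SPAN)
        assert len(models) == 2
        last_exons = sorted(m.exons[-1].start for m in models)
        assert last_exons == [600, 650]
        # the first three exons agree between the two isoforms
        assert [
            (e.start, e.end) for e in models[0].exons[:3]
        ] == [(e.start, e.end) for e in models[1].exons[:3]]

    def test_no_junctions_gives_single_exon_model(self):
        (model,) = assemble_isoforms([], self.SPAN)
        assert [(e.start, e.end) for e in model.exons] == [(0, 1000)]

    def test_junction_outside_span_rejected(self):
        with pytest.raises(IsoformError, match="outside"):
            assemble_isoforms([junction(900, 1100)], self.SPAN)

    @pytest.mark.parametrize("seed", range(6))
    def test_chain_enumeration_matches_bruteforce(self, seed):
        import numpy as np

        local = np.random.default_rng(seed)
        introns = []
        for _ in range(int(local.integers(1, 7))):
            s = int(local.integers(0, 900))
            e = s + int(local.integers(10, 120))
            introns.append((s, min(e, 999)))
        introns = sorted(set(introns))
        juncs = [junction(s, e) for s, e in introns]
        got = {
            frozenset((j.intron.start, j.intron.end) for j in chain)
            for chain in maximal_compatible_chains(juncs)
        }
        assert got == maximal_compatible_junction_sets(introns)


class TestSpliceTranscript:
    def test_two_exons(self):
        genome = SequenceRecord("g", "AAACCCGGG")
        model_exons = [GenomicInterval("g", 0, 3), GenomicInterval("g", 6, 9)]
        from dupliscan.isoform_orf import TranscriptModel
        cdna = splice_transcript(genome, TranscriptModel("t", model_exons))
        assert cdna.residues == "AAAGGG"

    def test_whole_sequence_identity(self):
        genome = SequenceRecord("g", "AAACCCGGG")
        from dupliscan.isoform_orf import TranscriptModel
        cdna = splice_transcript(genome, TranscriptModel("t", [GenomicInterval("g", 0, 9)]))
        assert cdna.residues == genome.residues

    def test_generator_transcripts_match_truth(self, default_truth):
        for model, truth_cdna in default_truth.transcripts:
            assert splice_transcript(default_truth.genome, model).residues == (
                truth_cdna.residues
            )


class TestScanOrfs:
    def test_minimal_orf(self):
        (orf,) = scan_orfs(SequenceRecord("c", "ATGAAATAA"), min_length_aa=1)
        assert orf.protein.residues == "MK"
        assert (orf.start_nt, orf.end_nt, orf.length_aa, orf.partial) == (0, 9, 2, False)

    def test_no_start_no_orfs(self):
        assert scan_orfs(SequenceRecord("c", "CCCCCC"), min_length_aa=1) == []

    def test_orf_without_stop_flagged_partial(self):
        (orf,) = scan_orfs(SequenceRecord("c", "ATGAAAAAA"), min_length_aa=1)
        assert orf.partial and orf.protein.residues == "MKK"
        assert longest_orf([orf]) is None
        assert longest_orf([orf], include_partial=True) is orf

    def test_orfs_retranslate_to_stored_protein(self, default_truth):
        from dupliscan.pairwise_align import translate
        for _, cdna in default_truth.transcripts:
            for orf in scan_orfs(cdna, min_length_aa=10):
                assert translate(cdna, orf.start_nt).residues == orf.protein.residues

    def test_start_mutation_never_lengthens_longest_orf(self, clean_truth):
        for _, cdna in clean_truth.transcripts:
            base = longest_orf(scan_orfs(cdna))
            s = cdna.residues
            mutated = s[: base.start_nt] + "ATA" + s[base.start_nt + 3 :]
            worse = longest_orf(scan_orfs(SequenceRecord("m", mutated)))
            assert worse is None or worse.length_aa <= base.length_aa


class TestSubstitutionsAndDomains:
    def test_identical_proteins_no_calls(self):
        p = SequenceRecord("p", ancestral_protein(), "protein")
        assert call_substitutions(p, p, [("HD", 100, 159)]) == []

    def test_hd_m54i(self):
        ref = ancestral_protein()
        alt = ref[:152] + "I" + ref[153:]  # residue 153 = HD position 54
        calls = call_substitutions(
            SequenceRecord("r", ref, "protein"),
            SequenceRecord("a", alt, "protein"),
            [("HD", 100, 159)],
        )
        assert [(c.domain, c.position, c.label) for c in calls] == [("HD", 54, "M54I")]

    def test_two_substitutions_ordered(self):
        ref = ancestral_protein()
        alt = ref[:108] + "D" + ref[109:152] + "I" + ref[153:]
        calls = call_substitutions(
            SequenceRecord("r", ref, "protein"),
            SequenceRecord("a", alt, "protein"),
            [("HD", 100, 159)],
        )
        ref_at_10 = ref[108]
        assert [(c.position, c.label) for c in calls] == [
            (10, f"{ref_at_10}10D"),
            (54, "M54I"),
        ]

    def test_empty_domain_list_rejected(self):
        p = SequenceRecord("p", "MKWW", "protein")
        with pytest.raises(IsoformError):
            call_substitutions(p, p, [])

    def test_tryptophan_counts(self):
        protein = SequenceRecord("p", ancestral_protein(), "protein")
        assert count_region_residue(protein, W_REGION_AA, "W") == 8
        # delete two of the eight pentapeptide repeats
        s = ancestral_protein()
        lo, hi = W_REGION_AA
        trimmed = s[: lo - 1] + s[lo - 1 + 10 : hi] + s[hi:]
        shrunk = SequenceRecord("d", trimmed, "protein")
        assert count_region_residue(shrunk, (lo, hi - 10), "W") == 6

    def test_no_tryptophans(self):
        assert count_region_residue(SequenceRecord("p", "MKLV", "protein"), (1, 4)) == 0

    def test_region_bounds_checked(self):
        with pytest.raises(IsoformError):
            count_region_residue(SequenceRecord("p", "MK", "protein"), (1, 3))
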