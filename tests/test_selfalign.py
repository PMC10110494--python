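"""Self-alignment dotplots, duplicated-segment boundaries, duplicate status."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import kmer_self_hits
from dupliscan.seq_core import SequenceRecord
from dupliscan.selfalign import (
    SelfAlignError,
    classify_duplicate_status,
    detect_duplicated_segments,
    self_alignment_hits,
)
from dupliscan.synthetic_data import DuplicationConfig, generate_locus


def dna(s, name="s"):
    return SequenceRecord(name, s, "dna")


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestDotHits:
    def test_small_repeat_matches_bruteforce(self):
        got = self_alignment_hits(dna("ACGTACGT"), k=4).hits
        assert got == kmer_self_hits("ACGTACGT", 4)
        assert (0, 4) in got and (4, 0) in got

    def test_homopolymer_everything_matches(self):
        got = self_alignment_hits(dna("AAAAAAA"), k=4).hits
        assert got == {(i, j) for i in range(4) for j in range(4)}

    def test_random_sequence_has_no_off_diagonal_hits(self, rng):
        s = random_dna(rng, 5000)
        hits = self_alignment_hits(dna(s), k=15).hits
        assert hits == {(i, i) for i in range(5000 - 15 + 1)}

    def test_n_words_never_match(self):
        hits = self_alignment_hits(dna("ANGTANGT"), k=4).hits
        assert hits == set()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=8, max_size=40))
    def test_symmetry_and_diagonal(self, s):
        hits = self_alignment_hits(dna(s.ljust(8, "A")), k=4)
        for i, j in hits.hits:
            assert (j, i) in hits.hits
        for i in range(hits.sequence_length - hits.k + 1):
            word = s.ljust(8, "A")[i : i + 4]
            if "N" not in word:
                assert (i, i) in hits.hits

    def test_degenerate_k_rejected(self):
        with pytest.raises(SelfAlignError):
            self_alignment_hits(dna("ACGTACGT"), k=3)
        with pytest.raises(SelfAlignError):
            self_alignment_hits(dna("ACGT"), k=10)


class TestDetectSegments:
    def test_planted_duplication_boundaries(self, rng):
        x = random_dna(rng, 500)
        y = random_dna(rng, 300)
        xp = list(x)
        for p in rng.choice(500, size=10, replace=False):  # 2% substitutions
            xp[p] = "ACGT"[(("ACGT".index(xp[p])) + 1) % 4]
        s = x + y + "".join(xp)
        segs = detect_duplicated_segments(self_alignment_hits(dna(s), k=15))
        assert len(segs) == 1
        seg = segs[0]
        assert abs(seg.interval_a.start - 0) <= 15
        assert abs(seg.interval_a.end - 500) <= 15
        assert abs(seg.interval_b.start - 800) <= 15
        assert abs(seg.interval_b.end - 1300) <= 15

    def test_random_sequence_yields_nothing(self, rng):
        s = random_dna(rng, 5000)
        assert detect_duplicated_segments(self_alignment_hits(dna(s), k=15)) == []

    def test_perfect_tandem_exact_boundaries(self, rng):
        x = random_dna(rng, 400)
        segs = detect_duplicated_segments(self_alignment_hits(dna(x + x), k=15))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.interval_a.start, seg.interval_a.end) == (0, 400)
        assert (seg.interval_b.start, seg.interval_b.end) == (400, 800)
        assert seg.identity_pct == 100.0


def candidate_region(truth):
    region = truth.duplicate_gene_region
    if region is None:
        return None
    return dna(truth.genome.residues[region.start : region.end], "candidate")


class TestClassify:
    def test_exact_copy_is_intact(self, clean_truth):
        status = classify_duplicate_status(
            clean_truth.ancestral_model,
            clean_truth.genome,
            candidate_region(clean_truth),
            hd_interval_aa=(100, 159),
        )
        assert status.status == "intact"
        assert status.coverage_fraction == pytest.approx(1.0)
        assert status.disabling_events == []

    def test_central_deletion_is_partial(self):
        truth = generate_locus(
            DuplicationConfig(
                seed=5, substitution_rate=0.0, disabling=("partial_deletion",),
                partial_deletion_span=0.6,
            )
        )
        status = classify_duplicate_status(
            truth.ancestral_model, truth.genome, candidate_region(truth),
            hd_interval_aa=(100, 159),
        )
        assert status.status == "partial_deletion"
        assert status.coverage_fraction == pytest.approx(0.4, abs=0.05)

    def test_homeodomain_missense_labelled_m54i(self):
        truth = generate_locus(
            DuplicationConfig(seed=5, substitution_rate=0.0, disabling=("hd_missense",))
        )
        status = classify_duplicate_status(
            truth.ancestral_model, truth.genome, candidate_region(truth),
            hd_interval_aa=(100, 159),
        )
        assert status.status == "coding_compromised"
        assert status.disabling_events == ["HD_missense:M54I"]

    def test_missing_candidate_is_absent(self, clean_truth):
        status = classify_duplicate_status(
            clean_truth.ancestral_model, clean_truth.genome, None,
            hd_interval_aa=(100, 159),
        )
        assert status.status == "absent" and status.coverage_fraction == 0.0

    def test_missing_cds_rejected(self, clean_truth):
        model = clean_truth.ancestral_model
        stripped = type(model)(
            gene_id=model.gene_id, exons=list(model.exons), cds_start=None
        )
        with pytest.raises(SelfAlignError, match="CDS"):
            classify_duplicate_status(
                stripped, clean_truth.genome, candidate_region(clean_truth),
                hd_interval_aa=(100, 159),
            )

    def test_monotone_in_deletion_size(self):
        ranking = {"intact": 0, "coding_compromised": 1, "partial_deletion": 2, "absent": 3}
        seen = []
        for span in (0.2, 0.45, 0.7, 0.97):
            truth = generate_locus(
                DuplicationConfig(
                    seed=6, substitution_rate=0.0, disabling=("partial_deletion",),
                    partial_deletion_span=span,
                )
            )
            status = classify_duplicate_status(
                truth.ancestral_model, truth.genome, candidate_region(truth),
                hd_interval_aa=(100, 159),
            )
            seen.append(ranking[status.status])
        assert seen == sorted(seen)
        assert ranking["intact"] not in seen  # any deletion breaks intactness
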