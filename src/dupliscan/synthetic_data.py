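"""Fully-truthed synthetic tandem-duplication locus generator.

The generator emulates the NANOG/NANOGP1 configuration: a multi-exon
ancestral gene on a contig, an intergenic gap, and a downstream tandem
duplicate of the whole gene unit diverged at a configurable per-site
substitution rate, with optional disabling mutations on the duplicate
(start-codon point mutation with an optional in-frame rescue ATG planted
117 nt downstream, a homeodomain missense change at domain position 54
(M -> I), or a central partial deletion). Two spliced isoforms of the
duplicate differ by an alternative acceptor between the last two internal
exons. Every emitted artefact carries ground truth (duplication
boundaries, mutation events, transcript structures, read origins), so each
pipeline stage can be tested against a known answer with no downloads.

The ancestral protein (305 aa) is built from a fixed template that embeds
the features the downstream analyses look for: a methionine-free N-terminal
39 residues followed by the rescue position at residue 40, a 60-aa
homeodomain-like segment with M at domain position 54, and a
tryptophan-repeat region of eight W residues. Codons are fixed per amino
acid, and UTRs are scrubbed of ATG trigrams, so the spliced cDNA contains
ATG only at in-frame methionines and the longest-ORF arithmetic
(305 aa intact; 266 aa after start loss with the +117 rescue, i.e. 39 aa
shorter) holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .isoform_orf import TranscriptModel, splice_transcript
from .seq_core import (
    AlignmentRecordLite,
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    write_fastq,
    write_sam_lite,
)


class SyntheticDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ancestral protein template and codon usage
# ---------------------------------------------------------------------------

#: one fixed codon per amino acid; chosen so that no adjacent codon pair can
#: spell ATG across a frame boundary (no codon ends in 'A' followed by one
#: starting 'TG'), keeping ATG in-frame-only within the CDS
CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

HD_INTERVAL_AA = (100, 159)   # homeodomain, 1-based inclusive; M at domain pos 54
W_REGION_AA = (170, 209)      # tryptophan-repeat region, 8 x W
PROTEIN_LENGTH_AA = 305


def _cycle(motif: str, n: int) -> str:
    return (motif * (n // len(motif) + 1))[:n]


#: filler alphabet: no M (starts stay designed), no W (count stays 8), no R
#: (the only codon ending in 'A', which could spell ATG across a frame
#: boundary before a TG-initial codon)
_FILLER_AA = "SDVKEPQALTGFHNICY"


def _filler(rng: np.random.Generator, n: int) -> str:
    """Aperiodic filler so the gene body contains no long internal repeats."""
    return "".join(rng.choice(list(_FILLER_AA), n))


def ancestral_protein() -> str:
    """The fixed 305-aa ancestral protein template (M only where designed)."""
    rng = np.random.default_rng(20230412)  # template constant, not a run seed
    n_term = "M" + _filler(rng, 38)                   # initiator M; no M/W until 40
    rescue_site = "L"                                 # residue 40; CTG -> ATG plant
    mid = _filler(rng, 59)                            # 41..99
    hd = list(_cycle("KRTAFSQEQLAHLEATFG", 60))       # 100..159
    hd[53] = "M"                                      # domain position 54
    linker = _cycle("GS", 10)                         # 160..169
    w_region = "WQPLP" * 8                            # 170..209
    c_term = _filler(rng, 96)                         # 210..305
    protein = n_term + rescue_site + mid + "".join(hd) + linker + w_region + c_term
    assert len(protein) == PROTEIN_LENGTH_AA
    return protein


def reverse_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationConfig:
    seed: int = 0
    ancestral_exon_lengths: tuple[int, ...] = (300, 180, 210, 360)
    intron_lengths: tuple[int, ...] = (400, 350, 500)
    utr5_length: int = 60                  # cds_start within the spliced transcript
    intergenic_gap: int = 800
    flank_length: int = 500
    unit_margin: int = 300                 # duplicated unit extends past the gene
    substitution_rate: float = 0.013
    indel_rate: float = 0.0                # indels land in introns/margins only
    disabling: tuple[str, ...] = ("none",)
    hd_interval_aa: tuple[int, int] = HD_INTERVAL_AA
    hd_missense_domain_pos: int = 54
    rescue_start_offset_nt: Optional[int] = 117
    partial_deletion_span: float = 0.6
    alt_acceptor_shift: int = 9            # extra intron bases in isoform 2

    def __post_init__(self):
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise SyntheticDataError("rates must lie in [0, 1]")
        if len(self.ancestral_exon_lengths) < 2:
            raise SyntheticDataError("need at least two exons")
        if len(self.intron_lengths) != len(self.ancestral_exon_lengths) - 1:
            raise SyntheticDataError("need exactly one intron per exon pair")
        bad = set(self.disabling) - {
            "none", "start_codon_loss", "hd_missense", "partial_deletion"
        }
        if bad:
            raise SyntheticDataError(f"unknown disabling events {sorted(bad)}")
        if not (0.0 < self.partial_deletion_span < 1.0):
            raise SyntheticDataError("partial_deletion_span must be in (0, 1)")
        if self.alt_acceptor_shift % 3:
            raise SyntheticDataError("alt_acceptor_shift must keep the frame")


@dataclass(frozen=True)
class MutationEvent:
    """A mutation of the duplicate copy, in pre-mutation unit coordinates.

    ``ref``/``alt`` are the replaced/replacement strings; deletions have
    alt == "". Substitutions never change length.
    """

    position: int
    ref: str
    alt: str
    label: str


def apply_mutation_events(sequence: str, events: Sequence[MutationEvent]) -> str:
    """Replay events on the unmutated unit: substitutions first (coordinates
    preserved), then length-changing events right-to-left."""
    s = list(sequence)
    point = [e for e in events if len(e.ref) == len(e.alt)]
    for e in point:
        assert "".join(s[e.position : e.position + len(e.ref)]) == e.ref
        s[e.position : e.position + len(e.ref)] = e.alt
    length_changing = sorted(
        (e for e in events if len(e.ref) != len(e.alt)),
        key=lambda e: -e.position,
    )
    for e in length_changing:
        assert "".join(s[e.position : e.position + len(e.ref)]) == e.ref
        s[e.position : e.position + len(e.ref)] = e.alt
    return "".join(s)


@dataclass
class SyntheticTruth:
    config: DuplicationConfig
    genome: SequenceRecord
    ancestral_model: GeneModel
    duplicate_model: Optional[GeneModel]
    duplication_boundaries: tuple[GenomicInterval, GenomicInterval]
    #: the duplicate region homologous to the ancestral gene span (None when
    #: fully deleted); the natural candidate for duplicate-status classification
    duplicate_gene_region: Optional[GenomicInterval]
    mutation_events: list[MutationEvent]
    transcripts: list[tuple[TranscriptModel, SequenceRecord]]
    protein: str
    cds_start: int

    @property
    def junctions(self) -> set[tuple[int, int]]:
        """The true intron set (genomic half-open intervals) over all transcripts."""
        out: set[tuple[int, int]] = set()
        for model, _ in self.transcripts:
            for a, b in zip(model.exons, model.exons[1:]):
                out.add((a.end, b.start))
        return out

    def transcript(self, transcript_id: str) -> tuple[TranscriptModel, SequenceRecord]:
        for model, cdna in self.transcripts:
            if model.transcript_id == transcript_id:
                return model, cdna
        raise KeyError(transcript_id)


# ---------------------------------------------------------------------------
# Locus generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int, scrub_atg: bool = False) -> str:
    s = "".join(rng.choice(_BASES, n))
    if scrub_atg:
        while "ATG" in s:
            s = s.replace("ATG", "ATC")
    return s


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def generate_locus(config: DuplicationConfig) -> SyntheticTruth:
    """Build the genome, gene models, truth transcripts and mutation list."""
    rng = np.random.default_rng(config.seed)
    protein = ancestral_protein()
    cds = reverse_translate(protein) + "TAA"
    exon_lengths = list(config.ancestral_exon_lengths)
    intron_lengths = list(config.intron_lengths)
    spliced_length = sum(exon_lengths)
    utr5 = config.utr5_length
    utr3 = spliced_length - utr5 - len(cds)
    if utr3 < 0:
        raise SyntheticDataError(
            f"exons too short for the {len(cds)} nt CDS plus {utr5} nt 5'UTR"
        )

    # spliced transcript, then cut into exons
    spliced = (
        _random_dna(rng, utr5, scrub_atg=True)
        + cds
        + _random_dna(rng, utr3, scrub_atg=True)
    )
    exon_seqs = []
    off = 0
    for L in exon_lengths:
        exon_seqs.append(spliced[off : off + L])
        off += L
    intron_seqs = [_random_dna(rng, L) for L in intron_lengths]

    # unit-local layout: [margin][e1 i1 e2 ... eN][margin]
    margin = config.unit_margin
    parts = [_random_dna(rng, margin)]
    exon_local: list[tuple[int, int]] = []
    pos = margin
    for i, es in enumerate(exon_seqs):
        parts.append(es)
        exon_local.append((pos, pos + len(es)))
        pos += len(es)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    parts.append(_random_dna(rng, margin))
    unit = "".join(parts)
    gene_local = (exon_local[0][0], exon_local[-1][1])

    # ----- mutate the duplicate unit --------------------------------------
    events: list[MutationEvent] = []
    if config.substitution_rate > 0:
        hit = np.nonzero(rng.random(len(unit)) < config.substitution_rate)[0]
        for p in hit:
            ref = unit[int(p)]
            events.append(
                MutationEvent(int(p), ref, _substitute(rng, ref), "substitution")
            )

    def cds_nt_to_local(nt: int) -> int:
        """CDS nucleotide offset -> unit-local genomic position."""
        spliced_off = utr5 + nt
        acc = 0
        for (s, e), L in zip(exon_local, exon_lengths):
            if spliced_off < acc + L:
                return s + (spliced_off - acc)
            acc += L
        raise SyntheticDataError(f"CDS offset {nt} beyond spliced transcript")

    def add_point(pos: int, alt: str, label: str):
        events[:] = [e for e in events if e.position != pos]  # disabling wins
        events.append(MutationEvent(pos, unit[pos], alt, label))

    if "start_codon_loss" in config.disabling:
        third = cds_nt_to_local(2)
        add_point(third, "A", "start_codon_loss")  # ATG -> ATA
        if config.rescue_start_offset_nt is not None:
            r = config.rescue_start_offset_nt
            if r % 3:
                raise SyntheticDataError("rescue offset must be in frame")
            codon = cds[r : r + 3]
            for k in range(3):
                if codon[k] != "ATG"[k]:
                    add_point(cds_nt_to_local(r + k), "ATG"[k], "rescue_start_gain")
    if "hd_missense" in config.disabling:
        # ATG -> ATA at the designed homeodomain methionine (M -> I)
        aa = config.hd_interval_aa[0] + config.hd_missense_domain_pos - 1
        nt = (aa - 1) * 3
        if cds[nt : nt + 3] != "ATG":
            raise SyntheticDataError(
                f"no methionine at homeodomain position {config.hd_missense_domain_pos}"
            )
        add_point(cds_nt_to_local(nt + 2), "A", f"hd_missense:M{config.hd_missense_domain_pos}I")
    deletion: Optional[tuple[int, int]] = None
    if "partial_deletion" in config.disabling:
        span_len = gene_local[1] - gene_local[0]
        del_len = int(round(config.partial_deletion_span * span_len))
        del_start = gene_local[0] + (span_len - del_len) // 2
        deletion = (del_start, del_start + del_len)
        events = [
            e for e in events if not (del_start <= e.position < del_start + del_len)
        ]
        events.append(
            MutationEvent(
                del_start, unit[del_start : del_start + del_len], "", "partial_deletion"
            )
        )
    if config.indel_rate > 0:
        # small indels restricted to introns and margins so exon/CDS truth holds
        non_exonic = [
            (0, gene_local[0]),
            *[
                (exon_local[i][1], exon_local[i + 1][0])
                for i in range(len(exon_local) - 1)
            ],
            (gene_local[1], len(unit)),
        ]
        for lo, hi in non_exonic:
            for p in range(lo, hi):
                if rng.random() >= config.indel_rate:
                    continue
                if deletion and deletion[0] <= p < deletion[1]:
                    continue
                if any(e.position == p for e in events):
                    continue
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5 and p + size <= hi:
                    events.append(
                        MutationEvent(p, unit[p : p + size], "", "indel_deletion")
                    )
                else:
                    ins = _random_dna(rng, size)
                    events.append(
                        MutationEvent(p, unit[p], unit[p] + ins, "indel_insertion")
                    )
    events.sort(key=lambda e: (e.position, e.label))
    dup_unit = apply_mutation_events(unit, events)

    # ----- assemble the genome --------------------------------------------
    flank5 = _random_dna(rng, config.flank_length)
    gap = _random_dna(rng, config.intergenic_gap)
    flank3 = _random_dna(rng, config.flank_length)
    a_start = len(flank5)
    b_start = a_start + len(unit) + len(gap)
    genome_seq = flank5 + unit + gap + dup_unit + flank3
    contig = "chrS"
    genome = SequenceRecord(contig, genome_seq, "dna")

    ancestral_model = GeneModel(
        gene_id="geneA",
        exons=[
            GenomicInterval(contig, a_start + s, a_start + e) for s, e in exon_local
        ],
        cds_start=utr5,
    )

    # map a pre-mutation unit coordinate into the mutated duplicate unit
    length_changing = sorted(
        (e for e in events if len(e.ref) != len(e.alt)), key=lambda e: e.position
    )

    def shift(pos: int) -> Optional[int]:
        delta = 0
        for e in length_changing:
            if e.position + len(e.ref) <= pos:
                delta += len(e.alt) - len(e.ref)
            elif e.position < pos:
                return None  # position falls inside a deletion
        return pos + delta

    def shift_clamped(pos: int) -> int:
        delta = 0
        for e in length_changing:
            if e.position + len(e.ref) <= pos:
                delta += len(e.alt) - len(e.ref)
            elif e.position < pos:
                return e.position + delta  # collapse to the deletion point
        return pos + delta

    duplicate_model: Optional[GeneModel] = None
    dup_exons: list[GenomicInterval] = []
    exons_intact = True
    for s, e in exon_local:
        ms, me = shift(s), shift(e)
        if ms is None or me is None or (deletion and s < deletion[1] and deletion[0] < e):
            exons_intact = False
            continue
        dup_exons.append(GenomicInterval(contig, b_start + ms, b_start + me))
    if dup_exons:
        duplicate_model = GeneModel(
            gene_id="geneB",
            exons=dup_exons,
            cds_start=utr5 if exons_intact else None,
        )

    boundaries = (
        GenomicInterval(contig, a_start, a_start + len(unit)),
        GenomicInterval(contig, b_start, b_start + len(dup_unit)),
    )

    # region of the duplicate homologous to the ancestral gene span
    region_s = b_start + shift_clamped(gene_local[0])
    region_e = b_start + shift_clamped(gene_local[1])
    duplicate_gene_region: Optional[GenomicInterval] = (
        GenomicInterval(contig, region_s, region_e) if region_e - region_s >= 4 else None
    )

    # ----- truth transcripts ----------------------------------------------
    transcripts: list[tuple[TranscriptModel, SequenceRecord]] = []

    def add_transcript(tid: str, exons: list[GenomicInterval]):
        model = TranscriptModel(transcript_id=tid, exons=exons)
        transcripts.append((model, splice_transcript(genome, model)))

    add_transcript("geneA.1", list(ancestral_model.exons))
    if duplicate_model is not None and exons_intact:
        add_transcript("geneB.1", list(duplicate_model.exons))
        shiftv = config.alt_acceptor_shift
        alt_exons = list(duplicate_model.exons)
        last = alt_exons[-1]
        alt_exons[-1] = GenomicInterval(contig, last.start + shiftv, last.end)
        add_transcript("geneB.2", alt_exons)

    return SyntheticTruth(
        config=config,
        genome=genome,
        ancestral_model=ancestral_model,
        duplicate_model=duplicate_model,
        duplication_boundaries=boundaries,
        duplicate_gene_region=duplicate_gene_region,
        mutation_events=events,
        transcripts=transcripts,
        protein=protein,
        cds_start=utr5,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    reads: list[tuple[str, str]]               # (read id, sequence)
    sam_records: list[AlignmentRecordLite]     # truth alignments, MAPQ 60
    read_origins: list[tuple[str, int]]        # (transcript id, offset)
    reference_lengths: dict[str, int]

    def write_fastq(self, path) -> None:
        write_fastq(self.reads, path)

    def write_sam(self, path) -> None:
        write_sam_lite(self.sam_records, path, self.reference_lengths)


def _spliced_to_cigar(
    exons: Sequence[GenomicInterval], offset: int, length: int
) -> tuple[int, list[tuple[int, str]]]:
    """Genomic position (0-based) and M/N CIGAR for a spliced interval."""
    cigar: list[tuple[int, str]] = []
    start_pos: Optional[int] = None
    remaining = length
    acc = 0
    prev_end: Optional[int] = None
    for e in exons:
        L = len(e)
        if offset >= acc + L:
            acc += L
            continue
        local = max(offset - acc, 0)
        take = min(L - local, remaining)
        g = e.start + local
        if start_pos is None:
            start_pos = g
        elif prev_end is not None and g > prev_end:
            cigar.append((g - prev_end, "N"))
        cigar.append((take, "M"))
        prev_end = g + take
        remaining -= take
        acc += L
        if remaining == 0:
            break
    if remaining or start_pos is None:
        raise SyntheticDataError("read extends beyond transcript")
    # merge adjacent M runs (possible when an intron has length 0)
    merged: list[tuple[int, str]] = []
    for n, op in cigar:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + n, op)
        else:
            merged.append((n, op))
    return start_pos, merged


def simulate_rnaseq(
    truth: SyntheticTruth,
    expression_weights: dict[str, float],
    n_reads: int,
    read_length: int = 75,
    error_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedReads:
    """Sample single-end spliced reads from the truth transcripts.

    Transcripts are sampled proportionally to ``expression_weights``,
    offsets uniformly; per-base errors are Bernoulli(``error_rate``). The
    truth SAM carries the correct spliced CIGAR (M/N runs) at MAPQ 60.
    """
    rng = np.random.default_rng(seed)
    tids = [t for t in expression_weights]
    weights = np.array([expression_weights[t] for t in tids], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise SyntheticDataError("weights must be >= 0 and not all zero")
    for tid in tids:
        model, cdna = truth.transcript(tid)
        if read_length > len(cdna.residues):
            raise SyntheticDataError(
                f"read_length {read_length} exceeds transcript {tid} "
                f"({len(cdna.residues)} nt)"
            )
    probs = weights / weights.sum()
    contig = truth.genome.id
    reads: list[tuple[str, str]] = []
    sam_records: list[AlignmentRecordLite] = []
    origins: list[tuple[str, int]] = []
    choice = rng.choice(len(tids), size=n_reads, p=probs)
    for i in range(n_reads):
        tid = tids[int(choice[i])]
        model, cdna = truth.transcript(tid)
        offset = int(rng.integers(0, len(cdna.residues) - read_length + 1))
        seq = list(cdna.residues[offset : offset + read_length])
        if error_rate > 0:
            err = np.nonzero(rng.random(read_length) < error_rate)[0]
            for p in err:
                seq[int(p)] = _substitute(rng, seq[int(p)])
        seq = "".join(seq)
        pos0, cigar = _spliced_to_cigar(model.exons, offset, read_length)
        read_id = f"read{i}|{tid}|{offset}"
        reads.append((read_id, seq))
        origins.append((tid, offset))
        sam_records.append(
            AlignmentRecordLite(
                read_id=read_id,
                contig=contig,
                pos=pos0 + 1,
                mapq=60,
                cigar=cigar,
                sequence=seq,
            )
        )
    return SimulatedReads(
        reads=reads,
        sam_records=sam_records,
        read_origins=origins,
        reference_lengths={contig: len(truth.genome.residues)},
    )
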