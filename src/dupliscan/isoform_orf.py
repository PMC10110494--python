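"""Splice-junction extraction, isoform assembly, ORF prediction and
protein-level substitution annotation.

Spliced RNA-seq aligners encode introns as CIGAR 'N' runs; every 'N' run in
a MAPQ-passing read therefore nominates one intron, and recurrent introns
(support >= ``min_support``) define the splice graph of a locus. Isoforms
are enumerated as maximal chains of mutually compatible junctions (two
junctions conflict iff their introns overlap), which makes the manual
curation step of the original workflow deterministic and reproducible.
ORFs are scanned on the spliced cDNA in all three forward frames with
alternative downstream ATG starts, which is what rescues a near-full-length
protein when the canonical start codon has been lost (the NANOGP1
situation: rescue ATG 117 nt downstream, protein 39 aa shorter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from . import pairwise_align
from .seq_core import (
    AlignmentRecordLite,
    GenomicInterval,
    SequenceRecord,
    SeqCoreError,
)


class IsoformError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceJunction:
    contig: str
    intron: GenomicInterval
    support: int


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval]
    junction_support: list[int] = field(default_factory=list)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class OrfPrediction:
    start_nt: int
    end_nt: int  # half-open on the cDNA; includes the stop codon if present
    frame: int
    protein: SequenceRecord
    length_aa: int
    partial: bool = False  # True when no in-frame stop before the cDNA end


@dataclass(frozen=True)
class SubstitutionAnnotation:
    domain: str
    position: int  # 1-based within the domain, on the reference
    ref_aa: str
    alt_aa: str
    label: str


# ---------------------------------------------------------------------------
# Junction extraction
# ---------------------------------------------------------------------------

def extract_junctions(
    records: Sequence[AlignmentRecordLite],
    mapq_min: int = 20,
    min_support: int = 2,
) -> list[SpliceJunction]:
    """Collect introns from CIGAR 'N' runs of MAPQ-passing reads.

    Intron coordinates come from walking the CIGAR from the record position
    (M/D consume reference; I/S do not; N consumes reference as intron).
    Identical introns aggregate; support below ``min_support`` is dropped.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for rec in records:
        if rec.mapq < mapq_min:
            continue
        if rec.cigar and (rec.cigar[0][1] == "N" or rec.cigar[-1][1] == "N"):
            warnings.warn(
                f"read {rec.read_id!r}: terminal N operation; record skipped"
            )
            continue
        ref = rec.pos - 1
        for length, op in rec.cigar:
            if op in ("M", "D"):
                ref += length
            elif op == "N":
                key = (rec.contig, ref, ref + length)
                counts[key] = counts.get(key, 0) + 1
                ref += length
    junctions = [
        SpliceJunction(contig, GenomicInterval(contig, s, e), n)
        for (contig, s, e), n in counts.items()
        if n >= min_support
    ]
    junctions.sort(key=lambda j: (j.contig, j.intron.start, j.intron.end))
    return junctions


# ---------------------------------------------------------------------------
# Isoform assembly
# ---------------------------------------------------------------------------

def _compatible(a: SpliceJunction, b: SpliceJunction) -> bool:
    return not a.intron.overlaps(b.intron)


def maximal_compatible_chains(
    junctions: Sequence[SpliceJunction],
) -> list[tuple[SpliceJunction, ...]]:
    """All maximal sets of pairwise-compatible (non-overlapping) junctions.

    Junction introns within one gene are sorted by coordinate; chains are
    grown left to right and returned in lexicographic coordinate order.
    """
    ordered = sorted(junctions, key=lambda j: (j.intron.start, j.intron.end))
    leaves: list[tuple[SpliceJunction, ...]] = []

    def grow(prefix: list[SpliceJunction], remaining: list[SpliceJunction]):
        extendable = False
        for idx, j in enumerate(remaining):
            if all(_compatible(j, p) for p in prefix):
                extendable = True
                grow(prefix + [j], remaining[idx + 1 :])
        if not extendable:
            leaves.append(tuple(prefix))

    grow([], list(ordered))
    # a leaf can still be extendable by a junction ordered before its first
    # member; keep only globally maximal chains, deduplicated in order
    seen: set[tuple[tuple[int, int], ...]] = set()
    unique = []
    for c in leaves:
        if any(
            j not in c and all(_compatible(j, p) for p in c) for j in ordered
        ):
            continue
        key = tuple((j.intron.start, j.intron.end) for j in c)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


def assemble_isoforms(
    junctions: Sequence[SpliceJunction],
    gene_span: GenomicInterval,
    transcript_prefix: str = "isoform",
) -> list[TranscriptModel]:
    """One transcript model per maximal chain of compatible junctions.

    Each model's exons are the maximal sub-intervals of ``gene_span`` not
    interior to any of its introns. With no junctions, the single-exon model
    spanning the gene is returned.
    """
    for j in junctions:
        if j.intron.start < gene_span.start or j.intron.end > gene_span.end:
            raise IsoformError(
                f"junction [{j.intron.start},{j.intron.end}) outside gene span "
                f"[{gene_span.start},{gene_span.end})"
            )
    models: list[TranscriptModel] = []
    for n, chain in enumerate(maximal_compatible_chains(junctions), start=1):
        exons = []
        pos = gene_span.start
        for j in chain:
            if j.intron.start > pos:
                exons.append(
                    GenomicInterval(gene_span.contig, pos, j.intron.start)
                )
            pos = j.intron.end
        if gene_span.end > pos:
            exons.append(GenomicInterval(gene_span.contig, pos, gene_span.end))
        models.append(
            TranscriptModel(
                transcript_id=f"{transcript_prefix}{n}",
                exons=exons,
                junction_support=[j.support for j in chain],
            )
        )
    return models


def splice_transcript(genome: SequenceRecord, model: TranscriptModel) -> SequenceRecord:
    """Concatenate exon sequences; '-' strand models are reverse-complemented."""
    n = len(genome.residues)
    parts = []
    for e in model.exons:
        if e.end > n:
            raise IsoformError(
                f"exon [{e.start},{e.end}) outside genome of length {n}"
            )
        parts.append(genome.residues[e.start : e.end])
    cdna = SequenceRecord(model.transcript_id, "".join(parts), "dna")
    if model.exons and model.exons[0].strand == "-":
        cdna = SequenceRecord(model.transcript_id, cdna.reverse_complement().residues)
    return cdna


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

def scan_orfs(cdna: SequenceRecord, min_length_aa: int = 50) -> list[OrfPrediction]:
    """All forward-frame ORFs starting at ATG, ending at the first in-frame
    stop (or the cDNA end, flagged ``partial``).

    Sorted by descending protein length, then ascending start.
    """
    if cdna.alphabet != "dna":
        raise IsoformError("scan_orfs requires a dna record")
    s = cdna.residues
    stops = {"TAA", "TAG", "TGA"}
    orfs: list[OrfPrediction] = []
    for frame in range(3):
        # stop positions per frame, so nested starts share one terminator
        i = frame
        starts: list[int] = []
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            if codon in stops and starts:
                for st in starts:
                    _maybe_add(orfs, cdna, st, i + 3, frame, min_length_aa, False)
                starts = []
            i += 3
        trailing_end = frame + 3 * ((len(s) - frame) // 3)
        for st in starts:  # ran off the end without a stop
            _maybe_add(orfs, cdna, st, trailing_end, frame, min_length_aa, True)
    orfs.sort(key=lambda o: (-o.length_aa, o.start_nt))
    return orfs


def _maybe_add(orfs, cdna, start, end, frame, min_length_aa, partial):
    protein = pairwise_align.translate(cdna, start)
    if protein.residues == "*" or len(protein.residues) < min_length_aa:
        return
    orfs.append(
        OrfPrediction(
            start_nt=start,
            end_nt=end,
            frame=frame,
            protein=protein,
            length_aa=len(protein.residues),
            partial=partial,
        )
    )


def longest_orf(
    orfs: Sequence[OrfPrediction], include_partial: bool = False
) -> OrfPrediction | None:
    """The longest (first-sorted) ORF, excluding partial ones by default."""
    for orf in orfs:
        if include_partial or not orf.partial:
            return orf
    return None


# ---------------------------------------------------------------------------
# Protein-level annotation
# ---------------------------------------------------------------------------

def call_substitutions(
    ref_protein: SequenceRecord,
    alt_protein: SequenceRecord,
    domains: Sequence[tuple[str, int, int]],
) -> list[SubstitutionAnnotation]:
    """Annotate amino-acid substitutions falling inside named domains.

    The proteins are globally aligned; every column with unequal non-gap
    residues whose reference position lies in a domain (1-based inclusive
    aa coordinates) yields one annotation, positioned 1-based within that
    domain. Substitutions to/from 'X' are ignored (unknown residue).
    """
    if not domains:
        raise IsoformError("domain list must be non-empty")
    aln = pairwise_align.global_align(ref_protein, alt_protein)
    out: list[SubstitutionAnnotation] = []
    ref_pos = 0  # 1-based after increment
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            ref_pos += 1
        if x == "-" or y == "-" or x == y or "X" in (x, y):
            continue
        for name, start_aa, end_aa in domains:
            if start_aa <= ref_pos <= end_aa:
                pos = ref_pos - start_aa + 1
                out.append(
                    SubstitutionAnnotation(
                        domain=name,
                        position=pos,
                        ref_aa=x,
                        alt_aa=y,
                        label=f"{x}{pos}{y}",
                    )
                )
    out.sort(key=lambda a: (a.domain, a.position))
    return out


def count_region_residue(
    protein: SequenceRecord, region: tuple[int, int], residue: str = "W"
) -> int:
    """Count ``residue`` in [start_aa, end_aa] (1-based inclusive)."""
    start_aa, end_aa = region
    if not (1 <= start_aa <= end_aa <= len(protein.residues)):
        raise IsoformError(
            f"region {region} outside protein of length {len(protein.residues)}"
        )
    return protein.residues[start_aa - 1 : end_aa].count(residue)
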