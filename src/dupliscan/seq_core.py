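"""Domain types, coordinate conventions and light-weight sequence I/O.

All internal coordinates are 0-based half-open on the forward strand; the
GFF3 and SAM layers convert to/from the 1-based conventions of those formats
at the boundary. Only the small feature subset the pipeline needs is
supported (FASTA records, GFF3 ``exon`` features with a ``Parent``/gene
attribute, and SAM records with M/I/D/N/S CIGAR operations).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")

#: CIGAR operations understood by the pipeline, in pysam integer encoding.
SUPPORTED_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S"}
_CIGAR_CODE = {v: k for k, v in SUPPORTED_CIGAR_OPS.items()}
#: Operations that consume query sequence.
QUERY_OPS = {"M", "I", "S"}
#: Operations that consume reference sequence.
REFERENCE_OPS = {"M", "D", "N"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqCoreError(ValueError):
    """Raised for malformed sequences, models or files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    alphabet: str = "dna"  # "dna" | "protein"

    def __post_init__(self):
        if not self.residues:
            raise SeqCoreError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("dna", "protein"):
            raise SeqCoreError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise SeqCoreError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "dna":
            raise SeqCoreError("reverse_complement requires a dna record")
        return SequenceRecord(self.id, self.residues.translate(_COMPLEMENT)[::-1], "dna")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0:
            raise SeqCoreError(f"negative interval start {self.start}")
        if self.end <= self.start:
            raise SeqCoreError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise SeqCoreError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """An exon chain on one contig/strand, with an optional CDS start.

    ``cds_start`` is a 0-based offset into the spliced transcript (the
    concatenation of exon sequences in genomic order, reverse-complemented
    for '-' strand models).
    """

    gene_id: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None

    def __post_init__(self):
        if not self.exons:
            raise SeqCoreError(f"gene model {self.gene_id!r} has no exons")
        contigs = {e.contig for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(contigs) > 1 or len(strands) > 1:
            raise SeqCoreError(
                f"gene model {self.gene_id!r} mixes contigs/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise SeqCoreError(
                    f"gene model {self.gene_id!r} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class AlignmentRecordLite:
    """The subset of a SAM alignment record the pipeline consumes."""

    read_id: str
    contig: str
    pos: int  # 1-based leftmost, as printed in SAM
    mapq: int
    cigar: list[tuple[int, str]]
    sequence: str
    flag: int = 0

    def __post_init__(self):
        if self.pos < 1:
            raise SeqCoreError(f"read {self.read_id!r}: SAM pos must be >= 1")
        for length, op in self.cigar:
            if op not in _CIGAR_CODE:
                raise SeqCoreError(
                    f"read {self.read_id!r}: unsupported CIGAR op {op!r}"
                )
            if length <= 0:
                raise SeqCoreError(f"read {self.read_id!r}: CIGAR length {length}")
        qlen = sum(n for n, op in self.cigar if op in QUERY_OPS)
        if qlen != len(self.sequence):
            raise SeqCoreError(
                f"read {self.read_id!r}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.sequence)}"
            )

    def reference_blocks(self) -> list[tuple[int, int]]:
        """0-based half-open reference intervals covered by M/D runs.

        N operations split blocks (introns are not part of the span).
        """
        blocks: list[tuple[int, int]] = []
        ref = self.pos - 1
        cur_start = ref
        for length, op in self.cigar:
            if op in ("M", "D"):
                ref += length
            elif op == "N":
                if ref > cur_start:
                    blocks.append((cur_start, ref))
                ref += length
                cur_start = ref
        if ref > cur_start:
            blocks.append((cur_start, ref))
        return blocks

    def reference_end(self) -> int:
        """0-based exclusive end of the full reference footprint."""
        return self.pos - 1 + sum(n for n, op in self.cigar if op in REFERENCE_OPS)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased :class:`SequenceRecord` objects.

    The alphabet is inferred per record (dna if every residue is in ACGTN).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise SeqCoreError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        alphabet = "dna" if set(residues) <= DNA_ALPHABET else "protein"
        records.append(SequenceRecord(rec.id, residues, alphabet))
    if not records:
        raise SeqCoreError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | os.PathLike, width: int = 60
) -> None:
    if not records:
        raise SeqCoreError("refusing to write an empty FASTA file")
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_PARENT_KEYS = ("Parent", "transcript_id", "gene_id", "ID")


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read GFF3 exon features into :class:`GeneModel` objects.

    Exons are grouped by their ``Parent`` (or ``transcript_id``/``gene_id``)
    attribute; GFF's 1-based inclusive coordinates become 0-based half-open.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        parent = None
        for key in _PARENT_KEYS:
            if key in feat.attributes:
                parent = feat.attributes[key][0]
                break
        if parent is None:
            raise SeqCoreError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} has no "
                "Parent/transcript_id/gene_id attribute"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or "+")
        if parent not in grouped:
            grouped[parent] = []
            order.append(parent)
        grouped[parent].append(iv)
    if not grouped:
        raise SeqCoreError(f"no exon features in {path}")
    return [GeneModel(gene_id=g, exons=grouped[g]) for g in order]


def write_gene_models(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write models as GFF3 exon features (Parent = gene_id)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            for i, e in enumerate(m.exons, start=1):
                fh.write(
                    f"{e.contig}\t.\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}"
                    f"\t.\tID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# SAM (text subset via pysam)
# ---------------------------------------------------------------------------

def read_sam_lite(path: str | os.PathLike) -> list[AlignmentRecordLite]:
    """Parse a text SAM file; unmapped records (flag 0x4) are dropped."""
    out: list[AlignmentRecordLite] = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cigar = []
            for code, length in rec.cigartuples or []:
                if code not in SUPPORTED_CIGAR_OPS:
                    raise SeqCoreError(
                        f"read {rec.query_name!r}: unsupported CIGAR op "
                        f"{'MIDNSHP=XB'[code]!r}"
                    )
                cigar.append((length, SUPPORTED_CIGAR_OPS[code]))
            out.append(
                AlignmentRecordLite(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    pos=rec.reference_start + 1,
                    mapq=rec.mapping_quality,
                    cigar=cigar,
                    sequence=(rec.query_sequence or "").upper(),
                    flag=rec.flag,
                )
            )
    return out


def write_sam_lite(
    records: Sequence[AlignmentRecordLite],
    path: str | os.PathLike,
    reference_lengths: dict[str, int],
) -> None:
    """Write records as text SAM with @SQ header lines."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.read_id
            a.flag = rec.flag
            a.reference_id = sam.header.get_tid(rec.contig)
            a.reference_start = rec.pos - 1
            a.mapping_quality = rec.mapq
            a.cigartuples = [(_CIGAR_CODE[op], n) for n, op in rec.cigar]
            a.query_sequence = rec.sequence
            a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.sequence))
            sam.write(a)


def write_fastq(
    reads: Iterable[tuple[str, str]], path: str | os.PathLike, quality_char: str = "I"
) -> None:
    """Write (read_id, sequence) pairs as FASTQ with a fixed quality string."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
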