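"""Global pairwise alignment with overlap-trimmed identity and divergence.

The divergence between a gene and its duplicated copy is summarised by two
statistics computed on a Needleman–Wunsch global alignment:

* ``identity_pct`` — percent identical columns between the first and last
  alignment columns in which both rows carry a residue (terminal overhangs
  are trimmed; internal gap columns stay in the denominator).
* ``divergence_rate`` — substitutions per aligned site: mismatching columns
  divided by columns where both rows carry a residue, within the same
  trimmed overlap. Gap columns are excluded from numerator and denominator,
  so on indel-free duplicates this is the per-site substitution rate that
  governs whether short reads can be assigned uniquely to one copy.

The dynamic programme itself is Biopython's :class:`~Bio.Align.PairwiseAligner`
(affine gaps; a gap of length L costs ``gap_open + (L-1)*gap_extend``).
Default scores mimic the EMBOSS needle DNA defaults. 'N' never matches
anything, including another 'N'.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Data.CodonTable import standard_dna_table
from Bio.Align import substitution_matrices

from .seq_core import SequenceRecord

GAP = "-"
#: characters that never match anything (not even themselves)
WILDCARDS = {"dna": "N", "protein": "X"}
_ALPHABETS = {"dna": "ACGTN", "protein": "ACDEFGHIKLMNPQRSTVWYX*"}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters (EMBOSS-needle-like DNA defaults)."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise AlignmentError("require gap_open >= gap_extend >= 0")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    overlap_start: int
    overlap_end: int
    identity_pct: float
    divergence_rate: float

    def column_pairs(self, start: int | None = None, end: int | None = None):
        a = self.aligned_a[start:end]
        b = self.aligned_b[start:end]
        return zip(a, b)


@lru_cache(maxsize=8)
def _aligner(params: AlignmentParams, alphabet: str) -> Align.PairwiseAligner:
    letters = _ALPHABETS[alphabet]
    wildcard = WILDCARDS[alphabet]
    matrix = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            same = a == b and a != wildcard
            matrix[a, b] = params.match if same else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _overlap_bounds(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    both = [
        i for i, (x, y) in enumerate(zip(aligned_a, aligned_b))
        if x != GAP and y != GAP
    ]
    if not both:
        raise AlignmentError("degenerate alignment: no column has both residues")
    return both[0], both[-1] + 1


def percent_identity_of(aligned_a: str, aligned_b: str, wildcard: str = "N") -> float:
    """Identity (%) over the trimmed overlap of a gapped alignment pair.

    Identical means both residues present, equal, and not the wildcard.
    Internal gap columns count in the denominator only.
    """
    start, end = _overlap_bounds(aligned_a, aligned_b)
    n_cols = end - start
    n_ident = sum(
        1
        for x, y in zip(aligned_a[start:end], aligned_b[start:end])
        if x == y and x != GAP and x != wildcard
    )
    return 100.0 * n_ident / n_cols


def divergence_rate_of(aligned_a: str, aligned_b: str, wildcard: str = "N") -> float:
    """Substitutions per aligned (both-residue) site in the trimmed overlap."""
    start, end = _overlap_bounds(aligned_a, aligned_b)
    n_sites = n_subs = 0
    for x, y in zip(aligned_a[start:end], aligned_b[start:end]):
        if x == GAP or y == GAP:
            continue
        n_sites += 1
        if x != y or x == wildcard:
            n_subs += 1
    return n_subs / n_sites


def global_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignmentParams | None = None
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two same-alphabet records.

    Tie-breaking is deterministic: the first optimal traceback reported by
    the aligner is used.
    """
    if params is None:
        params = AlignmentParams()
    if a.alphabet != b.alphabet:
        raise AlignmentError(
            f"mixed alphabets: {a.id!r} is {a.alphabet}, {b.id!r} is {b.alphabet}"
        )
    aligner = _aligner(params, a.alphabet)
    aln = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    start, end = _overlap_bounds(aligned_a, aligned_b)
    wildcard = WILDCARDS[a.alphabet]
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        overlap_start=start,
        overlap_end=end,
        identity_pct=percent_identity_of(aligned_a, aligned_b, wildcard),
        divergence_rate=divergence_rate_of(aligned_a, aligned_b, wildcard),
    )


def percent_identity(aln: AlignmentResult) -> float:
    return percent_identity_of(aln.aligned_a, aln.aligned_b)


def divergence_rate(aln: AlignmentResult) -> float:
    return divergence_rate_of(aln.aligned_a, aln.aligned_b)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


def translate(cdna: SequenceRecord, offset: int = 0) -> SequenceRecord:
    """Translate from ``offset`` to the first in-frame stop (or sequence end).

    The stop codon is not included in the protein; a trailing partial codon
    is dropped; any codon containing 'N' translates to 'X' (never treated as
    a stop).
    """
    if cdna.alphabet != "dna":
        raise AlignmentError("translate requires a dna record")
    if not (0 <= offset < len(cdna.residues)):
        raise AlignmentError(f"offset {offset} outside [0, {len(cdna.residues)})")
    residues = cdna.residues
    aas: list[str] = []
    for i in range(offset, len(residues) - 2, 3):
        codon = residues[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STOP_CODONS:
            break
        else:
            aas.append(_CODON_TABLE[codon])
    # degenerate immediate stop: render the stop itself so the record is non-empty
    protein = "".join(aas) or "*"
    return SequenceRecord(f"{cdna.id}_pep", protein, "protein")
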