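"""Dotplot-style self-alignment, duplicated-segment boundaries, and
cross-species duplicate-status classification.

A tandem duplication shows up in a self-alignment dotplot as an off-diagonal
line of matches at a near-constant offset. Here the dotplot is built from
exact k-word matches (default k=15), off-diagonal hits are clustered by
offset and chained along the sequence, and each cluster's boundaries are
refined by ungapped extension/trimming so the reported segment pair ends
where homology ends. Segment pairs are then realigned globally to attach a
percent identity.

``classify_duplicate_status`` applies the comparative logic used to decide
whether a duplicated gene copy in another genome is intact, partially
deleted, absent, or full-length but coding-compromised (lost start codon
without rescue, or a missense change inside the DNA-binding homeodomain,
e.g. the M54I change that switches NANOG-type TAAT binding specificity).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median_low

from .pairwise_align import AlignmentParams, global_align, translate
from .seq_core import GeneModel, GenomicInterval, SequenceRecord
from . import isoform_orf


class SelfAlignError(ValueError):
    pass


@dataclass
class DotHits:
    """Exact k-word self-match coordinates (symmetric, diagonal included)."""

    k: int
    hits: set[tuple[int, int]]
    sequence_length: int
    sequence: SequenceRecord | None = None  # kept for boundary refinement


@dataclass
class DuplicatedSegment:
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    n_hits: int
    mean_offset: int
    identity_pct: float


@dataclass
class DuplicateStatus:
    status: str  # intact | partial_deletion | absent | coding_compromised
    coverage_fraction: float
    disabling_events: list[str] = field(default_factory=list)


def self_alignment_hits(seq: SequenceRecord, k: int = 15) -> DotHits:
    """All exact k-word self-matches of ``seq`` (words containing N never match)."""
    if seq.alphabet != "dna":
        raise SelfAlignError("self-alignment requires a dna record")
    if k < 4:
        raise SelfAlignError(f"k={k} is degenerate; use k >= 4")
    n = len(seq.residues)
    if k > n:
        raise SelfAlignError(f"k={k} exceeds sequence length {n}")
    positions: dict[str, list[int]] = defaultdict(list)
    s = seq.residues
    for i in range(n - k + 1):
        word = s[i : i + k]
        if "N" not in word:
            positions[word].append(i)
    hits: set[tuple[int, int]] = set()
    for pos_list in positions.values():
        for i in pos_list:
            for j in pos_list:
                hits.add((i, j))
    return DotHits(k=k, hits=hits, sequence_length=n, sequence=seq)


def _xdrop_extend(
    s: str,
    offset: int,
    start: int,
    end: int,
    match_score: int = 1,
    mismatch_score: int = -3,
    drop: int = 40,
) -> tuple[int, int]:
    """Refine [start, end) of the first copy by ungapped extension/trimming.

    Positions i of the first copy are compared with i+offset of the second;
    extension proceeds outward from the anchor, keeping the position of the
    running-score maximum, and stops once the score falls ``drop`` below it.
    The anchor interval itself is re-walked so over-extended seeds shrink.
    """
    n = len(s)

    def walk(indices) -> int | None:
        best, best_pos, score = 0, None, 0
        for i in indices:
            j = i + offset
            if i < 0 or j >= n:
                break
            ok = s[i] == s[j] and s[i] != "N"
            score += match_score if ok else mismatch_score
            if score > best:
                best, best_pos = score, i
            if score < best - drop:
                break
        return best_pos

    mid = (start + end) // 2
    right = walk(range(mid, n))
    left = walk(range(mid, -1, -1))
    new_start = left if left is not None else start
    new_end = (right + 1) if right is not None else end
    if new_end <= new_start:
        return start, end
    return new_start, new_end


def detect_duplicated_segments(
    hits: DotHits,
    min_span: int = 200,
    max_gap: int | None = None,
    min_hits: int = 10,
    chain_gap: int = 200,
    align_params: AlignmentParams | None = None,
) -> list[DuplicatedSegment]:
    """Cluster off-diagonal self-matches into duplicated segment pairs.

    Hits above the main diagonal (i < j) are single-linkage clustered on
    their offset (j - i) with tolerance ``max_gap`` (default 2k), chained
    along i with gaps up to ``chain_gap``, and clusters spanning >=
    ``min_span`` bases with >= ``min_hits`` hits are reported. Boundaries
    are refined by ungapped extension at the cluster's modal offset, and the
    segment pair is realigned to compute identity.
    """
    if max_gap is None:
        max_gap = 2 * hits.k
    k = hits.k
    upper = sorted((i, j) for i, j in hits.hits if i < j)
    if not upper:
        return []
    # single-linkage on offset
    by_offset = sorted(upper, key=lambda h: h[1] - h[0])
    offset_groups: list[list[tuple[int, int]]] = []
    for h in by_offset:
        d = h[1] - h[0]
        if offset_groups and d - (offset_groups[-1][-1][1] - offset_groups[-1][-1][0]) <= max_gap:
            offset_groups[-1].append(h)
        else:
            offset_groups.append([h])
    segments: list[DuplicatedSegment] = []
    contig = hits.sequence.id if hits.sequence is not None else "seq"
    for group in offset_groups:
        # chain along i
        group.sort()
        chains: list[list[tuple[int, int]]] = [[group[0]]]
        for h in group[1:]:
            if h[0] - chains[-1][-1][0] <= chain_gap:
                chains[-1].append(h)
            else:
                chains.append([h])
        for chain in chains:
            if len(chain) < min_hits:
                continue
            offsets = [j - i for i, j in chain]
            d = median_low(offsets)
            anchor = [i for i, j in chain if j - i == d]
            a_start, a_end = min(anchor), max(anchor) + k
            if hits.sequence is not None:
                a_start, a_end = _xdrop_extend(
                    hits.sequence.residues, d, a_start, a_end
                )
            if a_end - a_start < min_span:
                continue
            interval_a = GenomicInterval(contig, a_start, a_end)
            interval_b = GenomicInterval(contig, a_start + d, a_end + d)
            identity = 100.0
            if hits.sequence is not None:
                seq_a = hits.sequence.residues[a_start:a_end]
                seq_b = hits.sequence.residues[a_start + d : a_end + d]
                aln = global_align(
                    SequenceRecord("a", seq_a),
                    SequenceRecord("b", seq_b),
                    align_params,
                )
                identity = aln.identity_pct
            segments.append(
                DuplicatedSegment(
                    interval_a=interval_a,
                    interval_b=interval_b,
                    n_hits=len(chain),
                    mean_offset=d,
                    identity_pct=identity,
                )
            )
    segments.sort(key=lambda s: (s.interval_a.start, s.interval_b.start))
    return segments


# ---------------------------------------------------------------------------
# Cross-species duplicate-status classification
# ---------------------------------------------------------------------------

def _column_map(aligned_a: str, aligned_b: str) -> list[int | None]:
    """For each position of ungapped A, the matched position of ungapped B."""
    out: list[int | None] = []
    ia = ib = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            out.append(ib)
            ia += 1
            ib += 1
        elif x != "-":
            out.append(None)
            ia += 1
        else:
            ib += 1
    return out


def classify_duplicate_status(
    ancestral: GeneModel,
    genome: SequenceRecord,
    candidate: SequenceRecord | None,
    hd_interval_aa: tuple[int, int],
    absent_threshold: float = 0.10,
    intact_threshold: float = 0.90,
    align_params: AlignmentParams | None = None,
) -> DuplicateStatus:
    """Classify a candidate duplicate region against its ancestral gene.

    ``candidate`` is the homologous genomic region from another species (or
    None/too-short for a full deletion). Coverage is the fraction of the
    ancestral gene span aligned to candidate residues. At high coverage the
    coding sequence is compared codon-by-codon: loss of the canonical ATG
    with no in-frame rescue ATG upstream of the homeodomain is recorded as
    ``start_codon_loss``; any non-synonymous change within the homeodomain
    interval (1-based amino-acid coordinates on the ancestral protein) is
    recorded as ``HD_missense:<RefPosAlt>``.
    """
    if ancestral.cds_start is None:
        raise SelfAlignError("ancestral gene model must define a CDS start")
    span = ancestral.span
    span_seq = genome.residues[span.start : span.end]
    if candidate is None or len(candidate.residues) < 4:
        return DuplicateStatus(status="absent", coverage_fraction=0.0)
    aln = global_align(
        SequenceRecord("ancestral_span", span_seq),
        candidate,
        align_params,
    )
    cmap = _column_map(aln.aligned_a, aln.aligned_b)
    coverage = sum(1 for m in cmap if m is not None) / len(span_seq)
    if coverage < absent_threshold:
        return DuplicateStatus(status="absent", coverage_fraction=coverage)
    if coverage < intact_threshold:
        return DuplicateStatus(status="partial_deletion", coverage_fraction=coverage)

    # --- ORF-level checks ------------------------------------------------
    # genomic positions (relative to gene span) of each spliced-transcript base
    spliced_positions = [
        p - span.start for e in ancestral.exons for p in range(e.start, e.end)
    ]
    cds_positions = spliced_positions[ancestral.cds_start :]
    ancestral_cds = "".join(span_seq[p] for p in cds_positions)
    candidate_cds = "".join(
        candidate.residues[cmap[p]] for p in cds_positions if cmap[p] is not None
    )
    events: list[str] = []
    hd_start_aa, hd_end_aa = hd_interval_aa
    if candidate_cds[0:3] != "ATG":
        rescue = False
        hd_start_nt = (hd_start_aa - 1) * 3
        for off in range(3, min(hd_start_nt, len(candidate_cds) - 2), 3):
            if candidate_cds[off : off + 3] == "ATG":
                rescue = True
                break
        if not rescue:
            events.append("start_codon_loss")
    ref_prot = translate(SequenceRecord("ref_cds", ancestral_cds), 0)
    alt_prot = translate(SequenceRecord("alt_cds", candidate_cds), 0)
    for sub in isoform_orf.call_substitutions(
        ref_prot, alt_prot, [("HD", hd_start_aa, hd_end_aa)]
    ):
        events.append(f"HD_missense:{sub.label}")
    status = "coding_compromised" if events else "intact"
    return DuplicateStatus(
        status=status, coverage_fraction=coverage, disabling_events=events
    )
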