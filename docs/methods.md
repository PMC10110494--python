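# Methods

`dupliscan` re-implements, as one tested pipeline, the computational steps
needed to characterise a tandem gene duplication and its expressed,
unprocessed pseudogene copy — the NANOG/NANOGP1 configuration being the
motivating case: two near-identical gene copies (sequence divergence on the
order of 0.013 substitutions per site) sitting next to each other on one
chromosome, where the duplicate may carry disabling mutations (a lost start
codon with a possible in-frame rescue ATG downstream, a homeodomain
missense change, or a partial deletion) and where every read-based analysis
must first establish that short reads can be assigned uniquely to one copy.

All internal coordinates are 0-based half-open; GFF3 and SAM I/O convert at
the boundary. Synthetic loci are generated on the forward strand;
'-'-strand transcript models are reverse-complemented at splice time.

## Pairwise alignment and divergence statistics

Gene/duplicate pairs are compared with an affine-gap Needleman–Wunsch
global alignment (engine: Biopython `PairwiseAligner`). Default scores are
match +5, mismatch −4, gap open 10, gap extend 0.5 (a gap of length L costs
`gap_open + (L−1)·gap_extend`), mirroring common DNA-alignment defaults; no
parameter set is canonical for this task, so all four are configurable. 'N'
never matches anything, including another 'N' — conservative for all
downstream statistics. End gaps are penalised like internal gaps; because
identity is computed on the trimmed overlap, this choice does not leak into
the reported statistics.

Two statistics are computed on the alignment:

* **percent identity** = identical columns / total columns over the region
  between the first and last column where *both* rows carry a residue.
  Terminal overhangs are excluded; internal gap columns stay in the
  denominator (they are real differences) but cannot score as identical.
* **divergence rate** = mismatching columns / both-residue columns over the
  same trimmed overlap. Gap columns are excluded from numerator and
  denominator, making this a substitutions-per-site rate — the quantity
  that governs read-level distinguishability of the two copies, which is
  substitution-driven (an indel either maps or breaks the read entirely).

Translation uses the standard genetic code; codons containing 'N' yield
'X' and never terminate translation; the protein ends at the first
unambiguous in-frame stop (not included) or the sequence end.

## Self-alignment and duplication boundaries

The dotplot is the set of exact k-word self-matches (k = 15 by default;
words containing 'N' never match). Exact-word matching replaces a
greyscale sliding-score dotplot because it is deterministic and directly
checkable against brute-force enumeration, and is adequate at the ≥ 94%
identities in scope. Hits above the main diagonal are single-linkage
clustered on their offset `j − i` (tolerance `max_gap`, default 2k),
chained along the sequence with gaps up to `chain_gap` (default 200 bp),
and clusters with span ≥ `min_span` (200) and ≥ `min_hits` (10) become
candidate segments.

Cluster boundaries seeded by the min/max hit coordinates are then refined
by an ungapped X-drop–style extension at the cluster's modal offset:
positions `i` and `i + d` are compared outward from the cluster centre with
match +1 / mismatch −3, keeping the running-score maximum and stopping once
the score falls 40 below it. The drop threshold matters: at 5% divergence a
local cluster of three or four substitutions produces drawdowns above 10,
so a small threshold truncates segments early, while beyond the true
boundary the expected slope is −2 per base (75% mismatches on random
sequence), so 40 costs only ~20 bp of exploration and the score maximum
stays at the homology edge. Under this rule, planted boundaries are
recovered to within a few bases at 5% divergence (the guarantee tested is
≤ k = 15 over 20 replicates). Each segment pair is finally realigned
globally to attach a percent identity.

Periodic sequence (e.g. short tandem amino-acid repeats) produces genuine
off-diagonal self-matches; clusters below `min_span` are suppressed, which
is why the synthetic protein template keeps its internal repeats short.

## Duplicate-status classification

A candidate region (the homologous span from another genome or from the
duplicate copy) is classified against the ancestral gene:

1. **coverage** — fraction of the ancestral gene span aligned to candidate
   residues in a global alignment. Coverage < 0.10 → `absent`;
   0.10–0.90 → `partial_deletion`. These thresholds are package defaults
   (no quantitative rule exists in the literature for the motivating
   locus); both are configurable.
2. at high coverage, **ORF-level checks** run on the candidate bases mapped
   through the alignment onto the ancestral CDS: loss of the canonical ATG
   with no in-frame rescue ATG upstream of the homeodomain →
   `start_codon_loss`; any non-synonymous change inside the user-supplied
   homeodomain interval → `HD_missense:<RefPosAlt>` (positions 1-based
   within the domain, e.g. `M54I` — position 54 is the residue that sets
   NANOG-family DNA-binding specificity). Any such event →
   `coding_compromised`, otherwise `intact`.

A lost canonical start *with* a rescue ATG before the homeodomain is
deliberately not a disabling event: it shortens the predicted protein
(by 39 residues with the default +117 nt rescue) but leaves the functional
domains intact — the human-pseudogene configuration — whereas no rescue
means the first translatable ATG lies beyond the homeodomain. The
homeodomain interval is always user-supplied; there is no universal
coordinate convention for it.

## Junctions, isoforms and ORFs

Splice junctions come from CIGAR 'N' runs: every 'N' in a MAPQ ≥ 20 read
nominates one intron (M/D consume reference, I/S do not), identical introns
aggregate, and support < 2 is dropped by default. The inclusive MAPQ
threshold (≥ 20) is used uniformly. Reads whose CIGAR begins or ends with
'N' are skipped with a warning (they carry no anchoring match).

Isoform reconstruction replaces manual curation with a deterministic rule:
one transcript model per **maximal chain of mutually compatible junctions**
(two junctions conflict iff their introns overlap), with exons being the
maximal sub-intervals of the gene span not interior to any used intron.
Chains are enumerated exhaustively and verified against subset enumeration
in tests; exon ends are not trimmed by coverage (no principled rule exists
without a coverage model). With no junctions, the single-exon model
spanning the gene is returned.

ORF scanning reports every ATG-initiated frame in the three forward frames
ending at the first in-frame stop, with length ≥ 50 aa by default; ORFs
truncated by the cDNA end are flagged partial and excluded from longest-ORF
selection. Nested starts sharing a stop are reported separately, which is
what surfaces the downstream rescue start when the canonical one is lost.

## Read disambiguation between paralogs

The mappability of each transcript against the two-locus reference is
measured exactly as a tiling experiment: every read-length window (step
1 bp; 43, 75 or 100 bp typical) is placed at its minimum-Hamming-distance
ungapped offset over all loci (forward strand; 'N' mismatches everything).
A deterministic exhaustive mapper replaces a heuristic spliced aligner
because the question — does every window contain a diagnostic site? — is
mapper-agnostic at locus scale. Placements need ≤ `max_mismatch` (2)
mismatches; a tie across loci is ambiguous (MAPQ-like 0), a unique best
locus scores 60, so the conventional MAPQ ≥ 20 multi-mapping filter reduces
to "unique best placement". Reports count, per source locus, unique-correct
/ cross-mapped / ambiguous / unaligned tiles, with and without the filter.

## Expression quantification

Gene-level counting over the union of exons (isoforms merged,
non-strand-specific), restricted to MAPQ ≥ 20 alignments. A read counts for
a gene iff any of its reference blocks (N gaps excluded) overlaps any exon
by ≥ 1 base; gene models must be mutually non-overlapping so a read counts
at most once. RPM = count / library_total × 10⁶ with library_total
defaulting to all MAPQ-passing reads (configurable, since the canonical
denominator is tool-dependent). log₂ RPM of a zero count is carried as
missing and floored at −4 only for display — no pseudocount, so nonzero
values are never shifted. Detection thresholds use a strict inequality
(log₂RPM > t).

## GC profiles

GC content is (G+C)/(A+C+G+T) with 'N' excluded from both sides; profiles
use fully contained sliding windows (default 30 bp, step 1 — step is not
canonical, so configurable) computed from cumulative counts and verified
per-window against direct counting. The mean of step-1 window values
approximates whole-sequence GC only for GC-homogeneous sequences; edge
windows under-weight the termini, so GC concentrated at an end can deviate
by more than 1/window — the profile reports the exact whole-region GC
separately.

## The synthetic locus generator

The generator is the pipeline's ground-truth instrument. Default geometry:
a 4-exon gene (exons 300/180/210/360 bp, introns 400/350/500 bp, 60 nt
5'UTR), embedded with 300 bp margins in a duplication unit, copied
downstream across an 800 bp intergenic gap, with 500 bp flanks — a 7.6 kb
contig. The duplicate is mutated at a configurable per-site substitution
rate (default 0.013, the divergence regime of the motivating gene pair).
The duplicate expresses two isoforms that differ by an alternative acceptor
at the last intron (9 nt, frame-preserving, codon-aligned), the ancestral
gene one isoform.

The 305-aa protein template is fixed (not seed-dependent) and built so the
downstream analyses have designed answers: an initiator methionine followed
by 38 M/W-free residues; a leucine at residue 40 whose codon becomes the
rescue ATG (+117 nt) under the start-loss scenario, making the rescued ORF
exactly 39 aa / 266 aa vs the 305-aa control; a 60-aa homeodomain-like
segment with M at domain position 54 (the `M54I` target); a
tryptophan-repeat region of eight Ws (so 8×W and Δ2×W counting cases are
constructible); and aperiodic filler elsewhere so the gene body contains no
internal repeat long enough to trigger segment detection. One fixed codon
per amino acid is used, chosen so ATG cannot arise across codon boundaries,
and UTRs are scrubbed of ATG trigrams — the cDNA therefore contains ATG
only at in-frame methionines and the longest-ORF arithmetic holds by
construction. Background substitutions at the default rate can and do
create premature stops in the duplicate's ORF (about 12 CDS substitutions
per locus; realistic pseudogene decay); scenario analyses that need exact
ORF arithmetic therefore run at substitution rate 0 with only the
configured disabling event applied.

Indels default to off (read disambiguation and divergence statistics are
substitution-driven); when enabled they are confined to introns and
margins, with exon coordinates shifted accordingly, so transcript truth
remains exact. Every mutation is recorded as an event (position in
pre-mutation unit coordinates, ref, alt, label) and replaying the event
list on the ancestral unit reproduces the duplicate byte-for-byte — a
tested invariant.

The read simulator samples transcripts proportionally to expression
weights (default 0.6 / 0.3 / 0.1 for ancestral / duplicate isoform 1 /
isoform 2), offsets uniformly, applies Bernoulli per-base substitution
errors, and emits FASTQ (fixed quality 'I') plus a truth SAM whose spliced
M/N CIGARs and MAPQ 60 are exact. What it does **not** emulate — position-
or quality-dependent error profiles, coverage bias, strandedness,
paired-end fragments, mapping ambiguity in the truth SAM — bounds what
passing tests show: they validate the analysis logic on structurally
faithful inputs, not robustness to real library artefacts.

## Problem sizes and determinism

The test suite and the acceptance script run the locus at its default 7.6 kb
scale with 8 000 simulated 75 bp reads — chosen so the weakest junction
(minor isoform at weight 0.1) has ~57× expected support, comfortably above
the 20× regime the recovery guarantees assume — 20 replicates for boundary
recovery, 10 kb pairs for divergence-rate recovery, and 200 random short
pairs for alignment-oracle equivalence. All randomness flows through
seeded NumPy generators; identical configuration and seed give
byte-identical outputs, including CLI output files.

## Known limitations

* The boundary detector assumes a collinear, indel-sparse duplication; a
  duplicate with large internal rearrangements will fragment into several
  segments rather than one.
* The Hamming mapper is ungapped and forward-strand (reverse-complement
  search is off by default); it measures window uniqueness, not full
  aligner behaviour.
* Isoform enumeration is junction-driven only; intron retention and
  coverage-defined exon ends are out of scope.
* `classify_duplicate_status` maps the candidate through a single global
  alignment; highly rearranged candidates can defeat the coordinate
  mapping even at high coverage.
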