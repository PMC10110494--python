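# dupliscan

Analysis toolkit for **tandem gene duplications and their expressed
pseudogene copies**. When a gene is duplicated in place, the new copy sits
next to its ancestor at high sequence identity (often > 97%), may still be
transcribed and spliced, and may or may not retain an intact open reading
frame. Deciding what such a duplicate is — intact paralog, coding-
compromised copy, partial deletion, or gone — and quantifying it from
RNA-seq requires a chain of careful, paralog-aware steps. `dupliscan`
implements that chain as a tested library and CLI:

* **pairwise_align** — affine-gap global alignment with overlap-trimmed
  percent identity and the per-site **divergence rate**
  (substitutions / aligned non-gap sites, the statistic that decides
  whether short reads can be assigned uniquely to one copy),
* **selfalign** — exact k-word self-alignment dotplots, detection of
  duplicated-segment **boundaries**, and cross-species duplicate-status
  classification (`intact` / `coding_compromised` / `partial_deletion` /
  `absent`, with events such as `start_codon_loss` or `HD_missense:M54I`),
* **isoform_orf** — splice-junction extraction from CIGAR 'N' operations
  (MAPQ ≥ 20), isoform assembly as maximal compatible junction chains, ORF
  scanning with alternative downstream starts, and protein-level domain /
  substitution annotation,
* **disambiguation** — the tiled-read cross-mapping experiment: every
  read-length window of each transcript is mapped against all loci with an
  exhaustive Hamming mapper, and cross-mapping / ambiguity rates are
  reported before and after the unique-placement (MAPQ-like) filter,
* **expression_quant** — unique-read gene-level counting, RPM and log₂ RPM
  (RPM = count / library_total × 10⁶), ranking and detection thresholds,
* **gc** — sliding-window GC profiles (default 30 bp windows),
* **synthetic_data** — a fully ground-truthed tandem-duplication locus
  generator (configurable divergence, disabling mutations, alternative
  splicing, spliced reads with truth SAM) so every stage is testable
  without downloads.

The statistic conventions in one line each: identity% and divergence are
computed between the first and last alignment columns where both sequences
have residues (overhangs trimmed; identity keeps internal gap columns in
the denominator, divergence drops gap columns entirely); MAPQ filtering is
inclusive at 20; log₂ RPM of zero counts is missing, floored at −4 for
display, never pseudocounted.

## Worked example

Generate a synthetic locus (ancestral gene + tandem duplicate at 0.013
divergence), simulate spliced reads, and reconstruct what the duplicate
expresses:

```python
from dupliscan import (DuplicationConfig, generate_locus, simulate_rnaseq,
                       extract_junctions, assemble_isoforms, splice_transcript,
                       scan_orfs, longest_orf, global_align)

truth = generate_locus(DuplicationConfig(seed=1))
sim = simulate_rnaseq(truth, {"geneA.1": 0.6, "geneB.1": 0.3, "geneB.2": 0.1},
                      n_reads=8000, read_length=75, seed=1)
junctions = extract_junctions(sim.sam_records, mapq_min=20, min_support=2)
print(f"{len(junctions)} junctions recovered")
for gene, model in (("ancestral", truth.ancestral_model),
                    ("duplicate", truth.duplicate_model)):
    span = model.span
    local = [j for j in junctions
             if span.start <= j.intron.start and j.intron.end <= span.end]
    for iso in assemble_isoforms(local, span, transcript_prefix=f"{gene}_iso"):
        cdna = splice_transcript(truth.genome, iso)
        orf = longest_orf(scan_orfs(cdna))
        print(f"{iso.transcript_id}: {len(iso.exons)} exons, "
              f"cDNA {len(cdna.residues)} nt, longest ORF {orf.length_aa} aa")
aln = global_align(truth.transcript("geneA.1")[1], truth.transcript("geneB.1")[1])
print(f"gene vs duplicate cDNA: identity {aln.identity_pct:.2f}%, "
      f"divergence rate {aln.divergence_rate:.4f}")
```

prints

```
7 junctions recovered
ancestral_iso1: 4 exons, cDNA 1050 nt, longest ORF 305 aa
duplicate_iso1: 4 exons, cDNA 1050 nt, longest ORF 143 aa
duplicate_iso2: 4 exons, cDNA 1041 nt, longest ORF 143 aa
gene vs duplicate cDNA: identity 98.10%, divergence rate 0.0190
```

Reading the output: all 7 true splice junctions were recovered from the
reads; the ancestral gene expresses one 4-exon isoform encoding the full
305-aa protein; the duplicate expresses two isoforms (alternative acceptor
at the last intron, 9 nt shorter cDNA); at this seed the background
substitutions happen to have introduced a premature stop in the duplicate's
reading frame (longest ORF 143 aa) — exactly the kind of coding decay that
turns a duplicate into a pseudogene; and the two cDNAs differ at a 0.019
per-site rate in this realisation of the 0.013 expectation. Running the
start-codon-loss scenario instead
(`DuplicationConfig(seed=1, substitution_rate=0.0,
disabling=("start_codon_loss",))`) yields a duplicate whose longest ORF
starts at a rescue ATG 117 nt downstream and is exactly 39 aa shorter than
the 305-aa control.

The same workflows are available from the shell:

```sh
dupliscan simulate --seed 1 --out sim/
dupliscan junctions --sam sim/truth.sam --out junc/
dupliscan selfdot --fasta sim/genome.fa -k 15 --out dot/
dupliscan crossmap --transcripts sim/transcripts.fa \
    --reference sim/transcripts.fa --read-length 100 --out cm/
```

Every command writes TSV/FASTA/GFF3 outputs plus a `run_manifest.json`
with the package version, resolved options and input checksums; identical
seed and options give byte-identical outputs.

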