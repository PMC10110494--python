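"""Unique-read expression quantification (RPM / log2 RPM) and ranking.

Gene-level counting over the union of exons (isoforms merged), restricted
to unique alignments (MAPQ >= 20 by default). RPM = count / library_total *
1e6, where ``library_total`` defaults to all MAPQ-passing reads. Zero
counts have no defined log2 RPM; they are carried as missing values and
floored at -4 only for display, rather than shifted by a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_core import AlignmentRecordLite, GeneModel

#: display floor for log2 RPM of undetected genes
LOG2_RPM_FLOOR = -4.0


class QuantError(ValueError):
    pass


@dataclass
class ExpressionTable:
    table: pd.DataFrame  # columns: gene_id, raw_count, rpm, log2_rpm
    library_total: int


def count_unique_reads(
    records: Sequence[AlignmentRecordLite],
    models: Sequence[GeneModel],
    mapq_min: int = 20,
) -> tuple[dict[str, int], int]:
    """Count MAPQ-passing reads per gene; returns (counts, library_total).

    A read counts for a gene iff any of its reference blocks (CIGAR walk,
    N gaps excluded) overlaps any exon of the gene by >= 1 base. Reads
    overlapping no gene still count in the library total. Gene models must
    not overlap each other.
    """
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            if a.span.overlaps(b.span):
                raise QuantError(
                    f"gene models {a.gene_id!r} and {b.gene_id!r} overlap"
                )
    counts = {m.gene_id: 0 for m in models}
    library_total = 0
    for rec in records:
        if rec.mapq < mapq_min:
            continue
        library_total += 1
        blocks = rec.reference_blocks()
        for m in models:
            if rec.contig != m.contig:
                continue
            hit = any(
                bs < e.end and e.start < be
                for bs, be in blocks
                for e in m.exons
            )
            if hit:
                counts[m.gene_id] += 1
                break  # models are non-overlapping: at most one gene
    return counts, library_total


def compute_rpm(counts: dict[str, int], library_total: int) -> ExpressionTable:
    """RPM and log2 RPM per gene (log2 of zero counts is missing/NaN)."""
    if library_total < 1:
        raise QuantError("library_total must be >= 1")
    gene_ids = list(counts)
    raw = np.array([counts[g] for g in gene_ids], dtype=np.int64)
    rpm = raw / library_total * 1e6
    with np.errstate(divide="ignore"):
        log2_rpm = np.where(raw > 0, np.log2(np.where(rpm > 0, rpm, 1.0)), np.nan)
    table = pd.DataFrame(
        {"gene_id": gene_ids, "raw_count": raw, "rpm": rpm, "log2_rpm": log2_rpm}
    )
    return ExpressionTable(table=table, library_total=library_total)


def rank_and_threshold(
    table: ExpressionTable, threshold_log2rpm: float = 0.0
) -> tuple[pd.DataFrame, int]:
    """Rank genes by descending log2 RPM (ties by gene_id) and count genes
    strictly above the threshold (log2RPM > t, i.e. rpm > 2**t)."""
    df = table.table.copy()
    df = df.sort_values(
        ["rpm", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    n_above = int((df["rpm"] > 2.0 ** threshold_log2rpm).sum())
    return df, n_above


def display_log2_rpm(table: ExpressionTable, floor: float = LOG2_RPM_FLOOR) -> pd.Series:
    """log2 RPM with missing values floored for plotting/reporting."""
    vals = table.table["log2_rpm"].copy()
    return vals.fillna(floor).clip(lower=floor)
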