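"""GC content and sliding-window GC profiles.

GC content is (#G + #C) / (#G + #C + #A + #T); 'N' bases are excluded from
both numerator and denominator. Profiles use fully contained windows
(default 30 bp, step 1), computed incrementally from cumulative counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq_core import SequenceRecord


class GcError(ValueError):
    pass


@dataclass
class GcProfile:
    window: int
    step: int
    values: list[tuple[int, float]]  # (window start, gc fraction)
    mean_gc: float


def gc_content(seq: SequenceRecord) -> float:
    if seq.alphabet != "dna":
        raise GcError("gc_content requires a dna record")
    s = seq.residues
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise GcError(f"sequence {seq.id!r} has no A/C/G/T bases")
    return gc / (gc + at)


def gc_profile(seq: SequenceRecord, window: int = 30, step: int = 1) -> GcProfile:
    """Fully-contained sliding windows; a window with only N bases is NaN."""
    if seq.alphabet != "dna":
        raise GcError("gc_profile requires a dna record")
    if step < 1:
        raise GcError(f"step {step} < 1")
    n = len(seq.residues)
    if window > n:
        raise GcError(f"window {window} exceeds sequence length {n}")
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(np.int64)
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int64)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_ok = np.concatenate([[0], np.cumsum(is_acgt)])
    values: list[tuple[int, float]] = []
    for start in range(0, n - window + 1, step):
        denom = cum_ok[start + window] - cum_ok[start]
        num = cum_gc[start + window] - cum_gc[start]
        values.append((start, num / denom if denom else math.nan))
    return GcProfile(
        window=window, step=step, values=values, mean_gc=gc_content(seq)
    )
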