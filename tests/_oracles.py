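"""Independent brute-force oracles used by the test suite.

Each function here recomputes, by enumeration or direct counting, a quantity
the library computes by a faster algorithm. They deliberately avoid the
library's code paths (and the libraries backing them) so agreement is a real
cross-check.
"""

from functools import lru_cache
from itertools import combinations


def affine_alignment_score(a: str, b: str, match=5.0, mismatch=-4.0,
                           gap_open=10.0, gap_extend=0.5) -> float:
    """Optimal global affine-gap score by exhaustive recursion.

    A gap of length L costs gap_open + (L-1)*gap_extend; 'N' never matches.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 = last column was a residue pair, 1 = gap in b, 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            cands.append(s + best(i + 1, j + 1, 0))
        if i < len(a):
            cands.append(-(gap_extend if state == 1 else gap_open) + best(i + 1, j, 1))
        if j < len(b):
            cands.append(-(gap_extend if state == 2 else gap_open) + best(i, j + 1, 2))
        return max(cands)

    return best(0, 0, 0)


def kmer_self_hits(seq: str, k: int) -> set[tuple[int, int]]:
    """All (i, j) with identical N-free k-words, by direct comparison."""
    n = len(seq)
    out = set()
    for i in range(n - k + 1):
        wi = seq[i : i + k]
        if "N" in wi:
            continue
        for j in range(n - k + 1):
            if wi == seq[j : j + k]:
                out.add((i, j))
    return out


def maximal_compatible_junction_sets(introns: list[tuple[int, int]]) -> set[frozenset]:
    """All maximal subsets of pairwise non-overlapping intron intervals,
    by enumerating every subset (feasible for <= ~10 introns)."""

    def compatible(s):
        return all(
            not (x[0] < y[1] and y[0] < x[1]) for x, y in combinations(s, 2)
        )

    items = list(introns)
    subsets = [
        frozenset(c)
        for r in range(len(items) + 1)
        for c in combinations(items, r)
        if compatible(c)
    ]
    return {
        s
        for s in subsets
        if not any(s < t for t in subsets)
    }


def hamming_best_placements(read: str, loci: list[tuple[str, str]],
                            max_mismatch: int) -> tuple[int | None, list[str]]:
    """(min mismatches or None, loci attaining it) by scanning every offset."""
    best = None
    best_loci: list[str] = []
    L = len(read)
    for name, ref in loci:
        locus_best = None
        for off in range(len(ref) - L + 1):
            mism = 0
            for x, y in zip(read, ref[off : off + L]):
                if x != y or x == "N" or y == "N":
                    mism += 1
                    if locus_best is not None and mism > locus_best:
                        break
            else:
                if locus_best is None or mism < locus_best:
                    locus_best = mism
        if locus_best is None or locus_best > max_mismatch:
            continue
        if best is None or locus_best < best:
            best, best_loci = locus_best, [name]
        elif locus_best == best:
            best_loci.append(name)
    return best, best_loci


def gc_fraction_window(seq: str, start: int, window: int) -> float:
    """GC fraction of one window by direct counting (N excluded)."""
    w = seq[start : start + window]
    gc = sum(1 for c in w if c in "GC")
    at = sum(1 for c in w if c in "AT")
    return gc / (gc + at) if gc + at else float("nan")
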