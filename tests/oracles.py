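"""Independent brute-force oracles the tests check the package against.

These deliberately re-derive results from first principles (set arithmetic,
exhaustive enumeration, position-by-position loops) and never call the code
paths they validate.
"""

from __future__ import annotations

from functools import lru_cache


def naive_match_counts(positions: list[set[str] | None], target: str, offset: int) -> tuple[int, int]:
    """(matched, defined) comparing position i with target[offset+i-1].

    A position is a set of allowed bases or None for a wildcard.  T equals U.
    """
    t = target.upper().replace("T", "U")
    matched = defined = 0
    for i, allowed in enumerate(positions):
        base = t[offset - 1 + i]
        if allowed is None:
            continue
        defined += 1
        if base in {b.replace("T", "U") for b in allowed}:
            matched += 1
    return matched, defined


def overlap_by_set_intersection(o3: int, o5: int, length: int) -> int:
    """Size of the intersection of the spacer positions covered by a 3'
    terminus at +o3 (covers 1..min(o3, L)) and a 5' terminus at -o5
    (covers max(L-o5+1, 1)..L)."""
    covered3 = set(range(1, min(o3, length) + 1))
    covered5 = set(range(max(length - abs(o5) + 1, 1), length + 1))
    return len(covered3 & covered5)


def best_alignment_score_by_enumeration(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Maximum global alignment score over every possible alignment,
    enumerated recursively."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def minus_strand_relative_walk(gene_start: int, gene_end: int, anchor: str, offset: int) -> int:
    """Map an anchor-relative offset on a minus-strand gene to a genomic
    position by literally walking the reverse-complement transcript."""
    # transcript bases in order are genomic positions gene_end .. gene_start
    transcript = list(range(gene_end, gene_start - 1, -1))
    if anchor == "start_codon":
        anchor_first_idx = 0
        anchor_last_idx = 2
    else:
        anchor_first_idx = len(transcript) - 3
        anchor_last_idx = len(transcript) - 1
    if offset < 0:
        # walk upstream (5'-ward) from the anchor's first base
        idx = anchor_first_idx + offset
        if idx >= 0:
            return transcript[idx]
        # off the transcript: continue in genomic coordinates beyond gene_end
        return gene_end + (-idx)
    idx = anchor_last_idx + offset
    if idx < len(transcript):
        return transcript[idx]
    return gene_start - (idx - len(transcript) + 1)
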