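"""Pairwise global alignment and per-position conservation profiling.

Needleman-Wunsch with a linear gap penalty and deterministic traceback
(ties resolved diagonal > up > left).  Conservation of a set of sequences
anchored to a reference uses star alignment: every sequence is aligned to
the reference pairwise and columns are indexed by reference coordinates;
insertions relative to the reference are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import SequenceRecord

GAP = "-"


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    match: float
    mismatch: float
    gap: float

    @property
    def identity(self) -> float:
        """Percent identity over alignment columns (no dual-gap columns)."""
        cols = ident = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == GAP and y == GAP:
                continue
            cols += 1
            if x == y:
                ident += 1
        return 100.0 * ident / cols if cols else 0.0


@dataclass(frozen=True)
class ConservationProfile:
    reference_id: str
    values: tuple[float, ...]  # one per reference position, in [0, 1]

    def windowed_mean(self, start: int, end: int) -> float:
        """Mean conservation over reference positions [start, end], 1-based."""
        if not (1 <= start <= end <= len(self.values)):
            raise ValueError(f"window {start}..{end} outside 1..{len(self.values)}")
        return float(np.mean(self.values[start - 1 : end]))


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Optimal global alignment under a linear gap scheme."""
    if a.alphabet != b.alphabet:
        raise ValueError("sequences must share an alphabet")
    s, t = a.residues, b.residues
    if not s or not t:
        raise ValueError("cannot align an empty sequence")
    n, m = len(s), len(t)
    # Objective per cell, maximized lexicographically: (score, identities,
    # -columns).  The secondary keys make score, identity and alignment
    # length invariant under jointly reversing (or reverse-complementing)
    # both inputs, which plain traceback tie-breaking would not guarantee.
    score = np.zeros((n + 1, m + 1))
    ident = np.zeros((n + 1, m + 1), dtype=np.int32)
    cols = np.zeros((n + 1, m + 1), dtype=np.int32)
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    cols[:, 0] = np.arange(n + 1)
    cols[0, :] = np.arange(m + 1)
    # 0 = diagonal, 1 = up (consume from a), 2 = left (consume from b)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        ci = s[i - 1]
        for j in range(1, m + 1):
            eq = ci == t[j - 1]
            d = (score[i - 1, j - 1] + (match if eq else mismatch),
                 ident[i - 1, j - 1] + (1 if eq else 0),
                 -(cols[i - 1, j - 1] + 1))
            u = (score[i - 1, j] + gap, ident[i - 1, j], -(cols[i - 1, j] + 1))
            l = (score[i, j - 1] + gap, ident[i, j - 1], -(cols[i, j - 1] + 1))
            best, mv = d, 0
            if u > best:
                best, mv = u, 1
            if l > best:
                best, mv = l, 2
            score[i, j], ident[i, j], cols[i, j] = best[0], best[1], -best[2]
            move[i, j] = mv
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i or j:
        mv = move[i, j]
        if mv == 0:
            out_a.append(s[i - 1])
            out_b.append(t[j - 1])
            i -= 1
            j -= 1
        elif mv == 1:
            out_a.append(s[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(t[j - 1])
            j -= 1
    return AlignmentResult(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score[n, m]),
        match=match,
        mismatch=mismatch,
        gap=gap,
    )


def percent_identity(a: SequenceRecord, b: SequenceRecord, **scores) -> float:
    return global_align(a, b, **scores).identity


def profile_conservation(
    seqs: list[SequenceRecord],
    reference_id: str | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> ConservationProfile:
    """Per-reference-position fraction of sequences sharing the majority
    base; gaps count as mismatches and can never be the majority.
    """
    if len(seqs) < 2:
        raise ValueError("conservation profiling needs at least 2 sequences")
    if reference_id is None:
        ref = seqs[0]
    else:
        matches = [s for s in seqs if s.id == reference_id]
        if not matches:
            raise ValueError(f"reference {reference_id!r} not among inputs")
        ref = matches[0]
    others = [s for s in seqs if s is not ref]

    n = len(ref)
    # columns[i] holds the base each sequence shows at reference position i+1
    columns: list[list[str]] = [[ref.residues[i]] for i in range(n)]
    for other in others:
        aln = global_align(ref, other, match=match, mismatch=mismatch, gap=gap)
        ri = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == GAP:
                continue  # insertion relative to the reference
            columns[ri].append(y)
            ri += 1

    total = len(seqs)
    values = []
    for col in columns:
        counts: dict[str, int] = {}
        for base in col:
            if base != GAP:
                counts[base] = counts.get(base, 0) + 1
        values.append(max(counts.values()) / total if counts else 0.0)
    return ConservationProfile(reference_id=ref.id, values=tuple(values))


def write_conservation_tsv(profile: ConservationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("reference_position\tconservation\n")
        for i, v in enumerate(profile.values, 1):
            fh.write(f"{i}\t{v:.6f}\n")
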