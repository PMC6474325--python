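"""Transcript 5'/3' termini from circularized-RNA junction reads.

A clone read spans the ligation junction of a self-ligated transcript: its
left flank is the 3' end of the molecule, its right flank the 5' end.  The
caller anchors both flanks on the reference by exact matching outward from
a candidate split point, requiring each anchor to be unique and at least
``min_anchor`` bases long.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import (
    GeneFeature,
    RelativePosition,
    SequenceRecord,
    normalize_nucleotide,
    reverse_complement,
    to_genomic,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CloneRead:
    clone_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class TerminusObservation:
    clone_id: str
    kind: str  # "5prime" or "3prime"
    rel: RelativePosition

    def __post_init__(self) -> None:
        if self.kind not in ("5prime", "3prime"):
            raise ValueError(f"kind must be 5prime/3prime, got {self.kind!r}")


@dataclass(frozen=True)
class TerminiTally:
    kind: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def modal_position(self) -> int:
        best = max(self.counts.values())
        return min(p for p, c in self.counts.items() if c == best)

    @property
    def modal_fraction(self) -> float:
        return max(self.counts.values()) / self.total

    def fractions(self) -> dict[int, float]:
        t = self.total
        return {p: c / t for p, c in sorted(self.counts.items())}


class UnmappableCloneError(ValueError):
    pass


class AmbiguousJunctionError(ValueError):
    def __init__(self, clone_id: str, candidates: list[tuple[int, int]]):
        self.candidates = candidates
        super().__init__(
            f"clone {clone_id!r}: multiple equal-score junctions {candidates}"
        )


def _find_unique(haystack: str, needle: str) -> int | None:
    """0-based position of a unique occurrence, else None."""
    first = haystack.find(needle)
    if first == -1:
        return None
    if haystack.find(needle, first + 1) != -1:
        return None
    return first


def _left_anchor(ref: str, flank: str, min_anchor: int) -> tuple[int, int] | None:
    """Longest suffix of `flank` occurring in ref; require the maximal
    matching suffix to occur uniquely and reach min_anchor.

    Returns (anchor_len, 0-based position of the suffix's last base).
    """
    for length in range(len(flank), min_anchor - 1, -1):
        needle = flank[-length:]
        pos = ref.find(needle)
        if pos == -1:
            continue
        if ref.find(needle, pos + 1) != -1:
            return None  # maximal match is ambiguous
        return (length, pos + length - 1)
    return None


def _right_anchor(ref: str, flank: str, min_anchor: int) -> tuple[int, int] | None:
    """Longest prefix of `flank` occurring uniquely in ref.

    Returns (anchor_len, 0-based position of the prefix's first base).
    """
    for length in range(len(flank), min_anchor - 1, -1):
        needle = flank[:length]
        pos = ref.find(needle)
        if pos == -1:
            continue
        if ref.find(needle, pos + 1) != -1:
            return None
        return (length, pos)
    return None


def _hamming_matches(ref: str, segment: str, ref_start0: int) -> int:
    """Matches of `segment` laid on ref at 0-based ref_start0; positions
    falling off the reference count as mismatches."""
    matches = 0
    for i, base in enumerate(segment):
        j = ref_start0 + i
        if 0 <= j < len(ref) and ref[j] == base:
            matches += 1
    return matches


def call_junction(
    read: CloneRead,
    reference: SequenceRecord,
    min_anchor: int = 12,
    trim_polya: bool = True,
    min_identity: float = 0.9,
) -> tuple[int, int]:
    """Locate the ligation junction: returns (three_prime_end, five_prime_end)
    as 1-based positions on the reference.

    A split point is a candidate when both flanks anchor by exact, unique
    matches of >= ``min_anchor`` bases growing outward from the junction.
    Candidates are scored by full-flank agreement with the reference at the
    anchored placement; among equal scores the split closest to the read
    midpoint wins, and a remaining tie across distinct terminus pairs raises
    AmbiguousJunctionError.  Calls explaining less than ``min_identity`` of
    the read are rejected as unmappable (junction-adjacent noise), as are
    reads whose flanks map contiguously (no junction structure).
    Untemplated 3' oligo-A tails are trimmed as a fallback when no
    untrimmed split maps.
    """
    ref = normalize_nucleotide(reference.residues, "rna")
    seq = normalize_nucleotide(read.sequence, "rna")
    n = len(seq)

    def collect(polya: bool) -> list[tuple[int, int, int, int, int]]:
        # (matches, |k - n/2| scaled by 2, three_prime, five_prime, compared)
        out = []
        for k in range(min_anchor, n - min_anchor + 1):
            left = seq[:k]
            trimmed = 0
            if polya:
                while left and left[-1] == "A":
                    left = left[:-1]
                    trimmed += 1
                if trimmed == 0 or len(left) < min_anchor:
                    continue
            la = _left_anchor(ref, left, min_anchor)
            if la is None:
                continue
            right = seq[k:]
            ra = _right_anchor(ref, right, min_anchor)
            if ra is None:
                continue
            _, lend = la
            _, rstart = ra
            three_prime = lend + 1  # to 1-based
            templ = 0
            if polya and trimmed:
                # re-extend over reference-templated As
                while (
                    templ < trimmed
                    and three_prime + templ < len(ref)
                    and ref[three_prime + templ] == "A"
                ):
                    templ += 1
                three_prime += templ
                if trimmed - templ:
                    logger.info(
                        "clone %s: trimmed %d untemplated 3' A(s)",
                        read.clone_id,
                        trimmed - templ,
                    )
            matches = _hamming_matches(ref, left, lend + 1 - len(left)) + templ
            matches += _hamming_matches(ref, right, rstart)
            compared = len(left) + templ + len(right)
            out.append((matches, abs(2 * k - n), three_prime, rstart + 1, compared))
        return out

    cands = collect(False)
    if not cands and trim_polya:
        cands = collect(True)
    if not cands:
        raise UnmappableCloneError(
            f"clone {read.clone_id!r}: no split with both anchors >= {min_anchor}"
        )
    best_score = max(c[0] for c in cands)
    top = [c for c in cands if c[0] == best_score]
    best_balance = min(c[1] for c in top)
    top = [c for c in top if c[1] == best_balance]
    pairs = sorted({(c[2], c[3]) for c in top})
    if len(pairs) > 1:
        raise AmbiguousJunctionError(read.clone_id, pairs)
    three_prime, five_prime = pairs[0]
    compared = top[0][4]
    if best_score < min_identity * compared:
        raise UnmappableCloneError(
            f"clone {read.clone_id!r}: best split explains only "
            f"{best_score}/{compared} bases"
        )
    if five_prime == three_prime + 1:
        raise UnmappableCloneError(
            f"clone {read.clone_id!r}: flanks map contiguously (no junction)"
        )
    if best_score < compared:
        # Imperfect call: noise near the junction can silently shift both
        # termini when the flanking bases happen to repeat.  If any shifted
        # terminus pair explains the read at least as well, refuse the call.
        for delta in (-3, -2, -1, 1, 2, 3):
            q3, q5 = three_prime + delta, five_prime + delta
            best_h = 0
            for k in range(min_anchor, n - min_anchor + 1):
                h = _hamming_matches(ref, seq[:k], q3 - k)
                h += _hamming_matches(ref, seq[k:], q5 - 1)
                best_h = max(best_h, h)
            if best_h >= best_score:
                raise UnmappableCloneError(
                    f"clone {read.clone_id!r}: junction is shift-ambiguous "
                    f"under noise (delta {delta:+d} explains {best_h} bases)"
                )
    return three_prime, five_prime


def tally_termini(observations: list[TerminusObservation], kind: str) -> TerminiTally:
    """Exact per-position clone counts for one terminus kind."""
    if not observations:
        raise ValueError("no observations to tally")
    anchors = {o.rel.anchor for o in observations}
    kinds = {o.kind for o in observations}
    if kinds != {kind}:
        raise ValueError(f"observations of kinds {sorted(kinds)}, expected {kind!r}")
    if len(anchors) != 1:
        raise ValueError(f"mixed anchors {sorted(anchors)}")
    counts: dict[int, int] = {}
    for o in observations:
        counts[o.rel.offset] = counts.get(o.rel.offset, 0) + 1
    return TerminiTally(kind=kind, counts=counts)


def termini_overlap(
    end3: RelativePosition, end5: RelativePosition, intergenic_len: int
) -> tuple[int, tuple[int, int] | None]:
    """Overlap (in nt) of the regions covered by a 3' terminus of the
    upstream gene and a 5' terminus of the downstream gene, on an
    intergenic spacer of length L.

    The 3' terminus at +o3 covers spacer positions 1..min(o3, L); the 5'
    terminus at -o5 covers max(L - o5 + 1, 1)..L.  Returns (length, (lo, hi))
    in spacer coordinates, with None for an empty overlap.
    """
    if intergenic_len <= 0:
        raise ValueError("intergenic length must be positive")
    if end3.anchor != "stop_codon" or end3.offset <= 0:
        raise ValueError("end3 must be anchored +downstream of the upstream stop codon")
    if end5.anchor != "start_codon" or end5.offset >= 0:
        raise ValueError("end5 must be anchored -upstream of the downstream start codon")
    L = intergenic_len
    hi = min(end3.offset, L)
    lo = max(L - abs(end5.offset) + 1, 1)
    length = max(0, hi - lo + 1)
    return length, ((lo, hi) if length else None)


def footprint_sequence(
    genome: SequenceRecord,
    upstream_gene: GeneFeature,
    downstream_gene: GeneFeature,
    end3: RelativePosition,
    end5: RelativePosition,
) -> SequenceRecord:
    """The overlap nucleotides, transcript-strand orientation, as RNA."""
    if upstream_gene.strand != downstream_gene.strand:
        raise ValueError("genes of one transcription unit must share a strand")
    strand = upstream_gene.strand
    if strand == "+":
        L = downstream_gene.start - upstream_gene.end - 1
    else:
        L = upstream_gene.start - downstream_gene.end - 1
    length, window = termini_overlap(end3, end5, L)
    if not length:
        raise ValueError("no footprint: termini do not overlap")
    lo, hi = window
    g3 = to_genomic(RelativePosition("stop_codon", lo), upstream_gene, len(genome))
    g5 = to_genomic(RelativePosition("stop_codon", hi), upstream_gene, len(genome))
    a, b = sorted((g3, g5))
    segment = genome.residues[a - 1 : b]
    if strand == "-":
        segment = reverse_complement(segment)
    return SequenceRecord(
        id=f"footprint_{upstream_gene.gene_id}_{downstream_gene.gene_id}",
        alphabet="nucleotide",
        residues=normalize_nucleotide(segment, "rna"),
    )
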