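"""Degenerate-consensus matching at fixed offsets and whole-sequence scans.

The headline score of a window is the count of matched defined (non-X)
positions; purine-preferring wildcard positions showing A or G are tallied
separately and excluded from the score by default.  T and U compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .code import ConsensusPattern, PURINES
from .seqio import SequenceRecord, normalize_nucleotide, reverse_complement

# per-position flag values
MATCH = "match"
MISMATCH = "mismatch"
WILDCARD = "wildcard"
PURINE_BONUS = "purine_bonus"


@dataclass(frozen=True)
class MatchResult:
    target_id: str
    offset: int  # 1-based start on the forward strand of the target
    strand: str
    matched: int
    defined: int
    purine_bonus: int
    per_position_flags: tuple[str, ...]

    def score(self, purine_weight: float = 0.0) -> float:
        return self.matched + purine_weight * self.purine_bonus


def _compare(pattern: ConsensusPattern, window: str, target_id: str, offset: int, strand: str) -> MatchResult:
    matched = 0
    defined = 0
    bonus = 0
    flags = []
    for p, base in zip(pattern.positions, window):
        if p.is_wildcard:
            if p.purine_preferring and base in PURINES:
                bonus += 1
                flags.append(PURINE_BONUS)
            else:
                flags.append(WILDCARD)
        else:
            defined += 1
            if base in p.allowed:
                matched += 1
                flags.append(MATCH)
            else:
                flags.append(MISMATCH)
    return MatchResult(
        target_id=target_id,
        offset=offset,
        strand=strand,
        matched=matched,
        defined=defined,
        purine_bonus=bonus,
        per_position_flags=tuple(flags),
    )


def match_at(pattern: ConsensusPattern, rna: SequenceRecord, offset: int) -> MatchResult:
    """Compare pattern position i with target base offset+i-1."""
    if rna.alphabet != "nucleotide":
        raise ValueError("match_at requires a nucleotide record")
    m = len(pattern)
    seq = normalize_nucleotide(rna.residues, "rna")
    if offset < 1 or offset + m - 1 > len(seq):
        raise ValueError(
            f"window [{offset}, {offset + m - 1}] outside target of length {len(seq)}"
        )
    return _compare(pattern, seq[offset - 1 : offset - 1 + m], rna.id, offset, "+")


def _encode(seq: str) -> np.ndarray:
    table = np.full(128, 4, dtype=np.int8)  # unknowns match nothing
    for i, b in enumerate("ACGU"):
        table[ord(b)] = i
    table[ord("T")] = 3
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_one_strand(pattern: ConsensusPattern, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (matched, purine_bonus) for every valid offset."""
    m = len(pattern)
    n = len(seq)
    n_win = n - m + 1
    enc = _encode(seq)
    matched = np.zeros(n_win, dtype=np.int32)
    bonus = np.zeros(n_win, dtype=np.int32)
    base_idx = {b: i for i, b in enumerate("ACGU")}
    for i, p in enumerate(pattern.positions):
        col = enc[i : i + n_win]
        if p.is_wildcard:
            if p.purine_preferring:
                bonus += (col == base_idx["A"]) | (col == base_idx["G"])
        else:
            ok = np.zeros(n_win, dtype=bool)
            for b in p.allowed:
                ok |= col == base_idx[b]
            matched += ok
    return matched, bonus


def scan(pattern: ConsensusPattern, target: SequenceRecord, strand_mode: str = "both") -> list[MatchResult]:
    """Evaluate every valid offset; rank by matched desc, purine bonus desc,
    offset asc, then '+' before '-'.

    Minus-strand windows are scanned on the reverse complement and reported
    with forward-strand coordinates.
    """
    if strand_mode not in ("both", "fwd"):
        raise ValueError("strand_mode must be 'both' or 'fwd'")
    if target.alphabet != "nucleotide":
        raise ValueError("scan requires a nucleotide record")
    m = len(pattern)
    seq = normalize_nucleotide(target.residues, "rna")
    n = len(seq)
    if m > n:
        import warnings

        warnings.warn(f"pattern length {m} exceeds target length {n}; empty result", stacklevel=2)
        return []

    results = []
    strands = ["+"] if strand_mode == "fwd" else ["+", "-"]
    defined = pattern.defined_count
    for strand in strands:
        s = seq if strand == "+" else reverse_complement(seq, rna=True)
        matched, bonus = _scan_one_strand(pattern, s)
        for o in range(len(matched)):
            fwd_offset = o + 1 if strand == "+" else n - (o + m) + 1
            results.append(
                MatchResult(
                    target_id=target.id,
                    offset=fwd_offset,
                    strand=strand,
                    matched=int(matched[o]),
                    defined=defined,
                    purine_bonus=int(bonus[o]),
                    per_position_flags=(),
                )
            )
    results.sort(key=lambda r: (-r.matched, -r.purine_bonus, r.offset, r.strand))
    return results


def write_scan_tsv(results: list[MatchResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\toffset\tstrand\tmatched\tdefined\tpurine_bonus\n")
        for r in results:
            fh.write(
                f"{r.target_id}\t{r.offset}\t{r.strand}\t{r.matched}\t{r.defined}\t{r.purine_bonus}\n"
            )
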