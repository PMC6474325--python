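"""Specificity-pair to nucleotide mapping and the degenerate consensus.

A consensus pattern is an ordered list of positions; each position is either
a set of allowed RNA bases (preference order preserved) or the wildcard X.
The text form uses single bases, ``X``, and parenthesized alternatives like
``(C/U)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqio import PROTEIN_LETTERS

RNA_BASES = ("A", "C", "G", "U")
PURINES = {"A", "G"}


@dataclass(frozen=True)
class PatternPosition:
    allowed: tuple[str, ...]  # empty tuple means wildcard X
    purine_preferring: bool = False
    source_motif_index: int | None = None

    def __post_init__(self) -> None:
        for b in self.allowed:
            if b not in RNA_BASES:
                raise ValueError(f"illegal nucleotide {b!r}")

    @property
    def is_wildcard(self) -> bool:
        return not self.allowed


@dataclass(frozen=True)
class ConsensusPattern:
    positions: tuple[PatternPosition, ...]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def defined_count(self) -> int:
        return sum(1 for p in self.positions if not p.is_wildcard)


@dataclass(frozen=True)
class PPRCodeTable:
    entries: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    purine_rule_enabled: bool = True

    def __post_init__(self) -> None:
        for (r6, r1p), bases in self.entries.items():
            for b in bases:
                if b not in RNA_BASES:
                    raise ValueError(f"illegal nucleotide {b!r} for pair ({r6},{r1p})")

    @classmethod
    def load(cls, path: str | Path, purine_rule_enabled: bool = True) -> "PPRCodeTable":
        entries: dict[tuple[str, str], tuple[str, ...]] = {}
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                r6, r1p, bases = line.split("\t")
                entries[(r6, r1p)] = tuple(bases.replace("T", "U").split(","))
        return cls(entries=entries, purine_rule_enabled=purine_rule_enabled)


def default_code_table() -> PPRCodeTable:
    with resources.as_file(resources.files("pprfoot.data") / "ppr_code_table.tsv") as p:
        return PPRCodeTable.load(p)


def predict_consensus(pairs: list[tuple[str, str]], table: PPRCodeTable | None = None) -> ConsensusPattern:
    """One pattern position per (residue6, residue1') pair, N-terminal
    motif mapping to the 5'-most nucleotide.

    Unknown pairs become X; with the purine rule on, an unknown pair whose
    residue6 is serine becomes X flagged purine-preferring.
    """
    if table is None:
        table = default_code_table()
    positions = []
    for i, (r6, r1p) in enumerate(pairs, 1):
        if r6 not in PROTEIN_LETTERS or r1p not in PROTEIN_LETTERS:
            raise ValueError(f"pair {i} ({r6!r},{r1p!r}) is not amino acids")
        bases = table.entries.get((r6, r1p))
        if bases is not None:
            positions.append(PatternPosition(allowed=bases, source_motif_index=i))
        else:
            purine = table.purine_rule_enabled and r6 == "S"
            positions.append(
                PatternPosition(allowed=(), purine_preferring=purine, source_motif_index=i)
            )
    return ConsensusPattern(positions=tuple(positions))


class ConsensusParseError(ValueError):
    def __init__(self, message: str, column: int):
        super().__init__(f"{message} at column {column}")
        self.column = column


def parse_consensus_string(text: str) -> ConsensusPattern:
    """Parse the slash/X text form; round-trips with
    :func:`format_consensus_string`."""
    positions = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "X":
            positions.append(PatternPosition(allowed=()))
            i += 1
        elif c in RNA_BASES:
            positions.append(PatternPosition(allowed=(c,)))
            i += 1
        elif c == "(":
            j = i + 1
            bases = []
            expect_base = True
            while True:
                if j >= n:
                    raise ConsensusParseError("unclosed parenthesis", n)
                cj = text[j]
                if expect_base:
                    if cj not in RNA_BASES:
                        raise ConsensusParseError(f"expected base, got {cj!r}", j + 1)
                    bases.append(cj)
                    expect_base = False
                elif cj == "/":
                    expect_base = True
                elif cj == ")":
                    break
                else:
                    raise ConsensusParseError(f"expected '/' or ')', got {cj!r}", j + 1)
                j += 1
            if len(bases) < 2:
                raise ConsensusParseError("alternative needs at least two bases", j + 1)
            positions.append(PatternPosition(allowed=tuple(bases)))
            i = j + 1
        else:
            raise ConsensusParseError(f"illegal character {c!r}", i + 1)
    return ConsensusPattern(positions=tuple(positions))


def format_consensus_string(pattern: ConsensusPattern) -> str:
    parts = []
    for p in pattern.positions:
        if p.is_wildcard:
            parts.append("X")
        elif len(p.allowed) == 1:
            parts.append(p.allowed[0])
        else:
            parts.append("(" + "/".join(p.allowed) + ")")
    return "".join(parts)


def pattern_to_json_dict(pattern: ConsensusPattern) -> dict:
    return {
        "length": len(pattern),
        "string": format_consensus_string(pattern),
        "positions": [
            {
                "allowed": list(p.allowed),
                "wildcard": p.is_wildcard,
                "purine_preferring": p.purine_preferring,
                "source_motif_index": p.source_motif_index,
            }
            for p in pattern.positions
        ],
    }


def pattern_from_json_dict(d: dict) -> ConsensusPattern:
    return ConsensusPattern(
        positions=tuple(
            PatternPosition(
                allowed=tuple(p["allowed"]),
                purine_preferring=p.get("purine_preferring", False),
                source_motif_index=p.get("source_motif_index"),
            )
            for p in d["positions"]
        )
    )
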