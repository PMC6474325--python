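"""Sequence I/O, alphabet handling and gene-relative coordinates.

All coordinates are 1-based inclusive.  Positions relative to a gene anchor
(start or stop codon) are signed integers with no zero: -1 is the nucleotide
immediately 5' of the anchor's first base, +1 the nucleotide immediately 3'
of the anchor's last base, following the transcript orientation on both
strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_LETTERS = set("ACGTUN")

# Average (not monoisotopic) residue masses in Da; mass of free water added
# once per chain.
WATER_MASS = 18.0153
RESIDUE_MASSES = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_COMPLEMENT_RNA = str.maketrans("ACGUTN", "UGCAAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with a declared alphabet."""

    id: str
    alphabet: str  # "protein" or "nucleotide"
    residues: str

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """A gene span on a genome; start <= end regardless of strand."""

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid span {self.start}..{self.end} for {self.gene_id!r}"
            )


@dataclass(frozen=True)
class RelativePosition:
    """Signed offset from a gene anchor; there is no position zero."""

    anchor: str  # "start_codon" or "stop_codon"
    offset: int

    def __post_init__(self) -> None:
        if self.anchor not in ("start_codon", "stop_codon"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.offset == 0:
            raise ValueError("no position zero in this convention")


def guess_alphabet(residues: str) -> str:
    letters = set(residues.upper())
    if letters <= NUCLEOTIDE_LETTERS:
        return "nucleotide"
    if letters <= PROTEIN_LETTERS | {"X", "*"}:
        return "protein"
    raise ValueError(f"cannot classify alphabet of letters {sorted(letters)}")


def normalize_nucleotide(seq: str, to: str = "rna") -> str:
    """Upper-case and convert T<->U so a sequence never mixes the two."""
    s = seq.upper()
    if to == "rna":
        return s.replace("T", "U")
    if to == "dna":
        return s.replace("U", "T")
    raise ValueError(f"target alphabet must be 'rna' or 'dna', got {to!r}")


def reverse_complement(seq: str, rna: bool | None = None) -> str:
    """Reverse complement; emits RNA when ``rna`` is True, DNA when False,
    and infers from the presence of U when None (defaulting to DNA)."""
    s = seq.upper()
    if rna is None:
        rna = "U" in s and "T" not in s
    if rna:
        return s.translate(_COMPLEMENT_RNA)[::-1]
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    U/T are preserved as written; call :func:`normalize_nucleotide` to
    canonicalize.  Raises on an empty file and on duplicate ids.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        ab = alphabet or guess_alphabet(residues)
        records.append(SequenceRecord(id=rec.id, alphabet=ab, residues=residues))
    if not records:
        raise ValueError(f"no records in {path}")
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate record ids: {', '.join(dups)}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _feature_name(feature) -> str | None:
    for key in ("gene", "locus_tag"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return None


def read_genbank(path: str | Path) -> tuple[SequenceRecord, list[GeneFeature]]:
    """Read a GenBank flat file: sequence plus gene/CDS features.

    Only "gene" and "CDS" features are consulted; a name is taken from the
    gene qualifier, falling back to locus_tag.  A multi-exon or repeated
    feature is reduced to its outermost span with a warning.
    """
    rec = SeqIO.read(str(path), "genbank")
    try:
        residues = str(rec.seq).upper()
    except Exception as exc:  # undefined sequence (e.g. CONTIG-only record)
        raise ValueError(f"no sequence in {path}: {exc}") from None
    if not residues:
        raise ValueError(f"no sequence in {path}")
    genome = SequenceRecord(id=rec.id, alphabet="nucleotide", residues=residues)

    spans: dict[str, list[tuple[int, int, str]]] = {}
    order: list[str] = []
    for feature in rec.features:
        if feature.type not in ("gene", "CDS"):
            continue
        name = _feature_name(feature)
        if name is None:
            continue
        strand = "-" if feature.location.strand == -1 else "+"
        for part in feature.location.parts:
            start = int(part.start) + 1  # to 1-based inclusive
            end = int(part.end)
            if not (1 <= start <= end <= len(genome)):
                raise ValueError(
                    f"feature {name!r} span {start}..{end} outside sequence "
                    f"of length {len(genome)}"
                )
            spans.setdefault(name, []).append((start, end, strand))
            if name not in order:
                order.append(name)

    features = []
    for name in order:
        parts = spans[name]
        strands = {s for _, _, s in parts}
        if len(strands) != 1:
            raise ValueError(f"feature {name!r} has parts on both strands")
        start = min(p[0] for p in parts)
        end = max(p[1] for p in parts)
        distinct = {(p[0], p[1]) for p in parts}
        if len(distinct) > 1:
            warnings.warn(
                f"feature {name!r} has {len(distinct)} parts; "
                f"reduced to outermost span {start}..{end}",
                stacklevel=2,
            )
        features.append(GeneFeature(gene_id=name, start=start, end=end, strand=strands.pop()))
    return genome, features


def _anchor_bounds(gene: GeneFeature, anchor: str) -> tuple[int, int]:
    """(first, last) genomic base of the anchor codon in transcript order."""
    if gene.strand == "+":
        if anchor == "start_codon":
            return gene.start, gene.start + 2
        return gene.end - 2, gene.end
    if anchor == "start_codon":
        return gene.end, gene.end - 2
    return gene.start + 2, gene.start


def to_genomic(rel: RelativePosition, gene: GeneFeature, genome_len: int) -> int:
    """Map a signed anchor-relative offset to a 1-based genomic position."""
    if rel.offset == 0:
        raise ValueError("no position zero in this convention")
    first, last = _anchor_bounds(gene, rel.anchor)
    sign = 1 if gene.strand == "+" else -1
    if rel.offset < 0:
        pos = first + sign * rel.offset
    else:
        pos = last + sign * rel.offset
    if not (1 <= pos <= genome_len):
        raise ValueError(
            f"relative position {rel.anchor}{rel.offset:+d} maps to {pos}, "
            f"outside [1, {genome_len}]"
        )
    return pos


def from_genomic(pos: int, gene: GeneFeature, anchor: str, genome_len: int) -> RelativePosition:
    """Inverse of :func:`to_genomic`; raises if pos falls on the anchor."""
    if not (1 <= pos <= genome_len):
        raise ValueError(f"position {pos} outside [1, {genome_len}]")
    first, last = _anchor_bounds(gene, anchor)
    sign = 1 if gene.strand == "+" else -1
    upstream = sign * (pos - first)
    downstream = sign * (pos - last)
    if upstream < 0:
        return RelativePosition(anchor=anchor, offset=upstream)
    if downstream > 0:
        return RelativePosition(anchor=anchor, offset=downstream)
    raise ValueError(f"position {pos} lies within the {anchor} anchor")


def molecular_mass(protein: SequenceRecord, from_res: int = 1, to_res: int | None = None) -> float:
    """Average-mass of the chain segment [from_res, to_res] plus one water."""
    if protein.alphabet != "protein":
        raise ValueError("molecular_mass requires a protein record")
    n = len(protein)
    if to_res is None:
        to_res = n
    if not (1 <= from_res <= to_res <= n):
        raise ValueError(f"range {from_res}..{to_res} invalid for length {n}")
    total = WATER_MASS
    for i in range(from_res, to_res + 1):
        aa = protein.residues[i - 1]
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"non-standard residue {aa!r} at position {i}") from None
    return total
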