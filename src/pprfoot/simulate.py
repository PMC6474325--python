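"""Seeded generators for every input the pipeline consumes.

Each generator takes a single integer seed driving one numpy Generator
stream, returns in-memory objects plus a truth record sufficient to score
the downstream stage, and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from Bio import SeqIO

from .code import ConsensusPattern, PPRCodeTable, default_code_table, format_consensus_string, predict_consensus
from .motifs import AA_ORDER, MotifProfile, default_profile
from .seqio import GeneFeature, SequenceRecord, normalize_nucleotide, reverse_complement
from .termini import CloneRead

RNA = "ACGU"
DNA = "ACGT"


@dataclass(frozen=True)
class ProteinTruth:
    seed: int
    n_motifs: int
    motif_starts: tuple[int, ...]
    motif_length: int
    code_letters: tuple[tuple[str, str], ...]
    expected_consensus: str
    noise_rate: float


@dataclass(frozen=True)
class GenomeTruth:
    seed: int
    strand: str
    genome_length: int
    gene_a: tuple[int, int]  # upstream gene span, forward coordinates
    gene_b: tuple[int, int]
    intergenic_len: int
    site_offset: int  # forward-strand 1-based start of the planted site
    site_sequence: str  # transcript-orientation RNA
    end3_offset: int
    end5_offset: int
    overlap_window: tuple[int, int]  # spacer coordinates, transcript order


@dataclass(frozen=True)
class CloneTruth:
    seed: int
    noise: float
    flank: int
    clones: tuple[tuple[str, int, int, int, int], ...]
    # (clone_id, end3_offset, end5_offset, ref_pos3, ref_pos5)


@dataclass(frozen=True)
class FamilyTruth:
    seed: int
    rate_in: float
    rate_out: float
    window: tuple[int, int]
    mutated: dict[str, tuple[int, ...]] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=n))


def make_ppr_protein(
    n_motifs: int,
    code_letters: list[tuple[str, str]] | None = None,
    flanks: tuple[int, int] = (50, 30),
    seed: int = 0,
    profile: MotifProfile | None = None,
    table: PPRCodeTable | None = None,
    noise_rate: float = 0.0,
) -> tuple[SequenceRecord, ProteinTruth]:
    """A protein with ``n_motifs`` planted tandem repeats built from the
    detection profile's template, positions 6 and 1' overwritten by the
    requested letters.

    ``code_letters`` holds one (residue6, residue1') pair per motif that has
    a successor (n-1 pairs); None draws them from the code table keys.
    Substitution noise, when requested, never touches positions 1 and 6.
    """
    if n_motifs < 1:
        raise ValueError("need at least one motif")
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = default_profile()
    if table is None:
        table = default_code_table()
    if code_letters is None:
        keys = sorted(table.entries)
        code_letters = [tuple(keys[k]) for k in rng.integers(0, len(keys), size=n_motifs - 1)]
    if len(code_letters) != n_motifs - 1:
        raise ValueError(f"expected {n_motifs - 1} code letter pairs, got {len(code_letters)}")
    for r6, r1p in code_letters:
        if r6 not in AA_ORDER or r1p not in AA_ORDER:
            raise ValueError(f"({r6!r},{r1p!r}) are not amino acids")

    m = profile.length
    motifs = [list(profile.template) for _ in range(n_motifs)]
    for i, (r6, r1p) in enumerate(code_letters):
        motifs[i][5] = r6
        motifs[i + 1][0] = r1p
    if noise_rate:
        for motif in motifs:
            for pos in range(m):
                if pos in (0, 5):
                    continue
                if rng.random() < noise_rate:
                    current = motif[pos]
                    choices = [aa for aa in AA_ORDER if aa != current]
                    motif[pos] = choices[rng.integers(0, len(choices))]

    pre = _random_protein(rng, flanks[0])
    post = _random_protein(rng, flanks[1])
    body = "".join("".join(mot) for mot in motifs)
    residues = pre + body + post
    starts = tuple(flanks[0] + 1 + i * m for i in range(n_motifs))
    expected = format_consensus_string(predict_consensus(list(code_letters), table))
    record = SequenceRecord(id=f"synthetic_ppr_{seed}", alphabet="protein", residues=residues)
    truth = ProteinTruth(
        seed=seed,
        n_motifs=n_motifs,
        motif_starts=starts,
        motif_length=m,
        code_letters=tuple((a, b) for a, b in code_letters),
        expected_consensus=expected,
        noise_rate=noise_rate,
    )
    return record, truth


def realize_pattern(pattern: ConsensusPattern, seed: int = 0) -> str:
    """One RNA string consistent with a pattern: primary preference at
    defined positions, random base at wildcards."""
    rng = np.random.default_rng(seed)
    out = []
    for p in pattern.positions:
        if p.is_wildcard:
            if p.purine_preferring:
                out.append("AG"[rng.integers(0, 2)])
            else:
                out.append(RNA[rng.integers(0, 4)])
        else:
            out.append(p.allowed[0])
    return "".join(out)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(DNA), size=3))
        if codon not in stops:
            out.append(codon)
    return "".join(out)


def make_genome_with_site(
    realization: str,
    intergenic_len: int,
    strand: str = "+",
    seed: int = 0,
    end3_offset: int | None = None,
    end5_offset: int | None = None,
    gene_codons: int = 60,
    flank_len: int = 400,
) -> tuple[SequenceRecord, list[GeneFeature], GenomeTruth]:
    """A two-gene locus whose intergenic spacer carries the binding site.

    The site begins at the second residue of the termini-overlap window.
    Default termini are placed so the overlap is exactly one nucleotide
    longer than the realization, centred in the spacer.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be + or -")
    m = len(realization)
    L = intergenic_len
    if L < m + 1:
        raise ValueError("impossible geometry: spacer shorter than site + 1")
    if (end3_offset is None) != (end5_offset is None):
        raise ValueError("give both termini offsets or neither")
    if end3_offset is None:
        ov_len = m + 1
        lo = (L - ov_len) // 2 + 1
        hi = lo + ov_len - 1
        end3_offset = hi
        end5_offset = -(L - lo + 1)
    else:
        if end3_offset <= 0 or end5_offset >= 0:
            raise ValueError("end3 must be positive, end5 negative")
        hi = min(end3_offset, L)
        lo = max(L - abs(end5_offset) + 1, 1)
        if hi - lo + 1 < m + 1:
            raise ValueError("impossible geometry: overlap shorter than site + 1")

    rng = np.random.default_rng(seed)
    spacer = list("".join(rng.choice(list(DNA), size=L)))
    site_dna = normalize_nucleotide(realization, "dna")
    site_spacer_start = lo + 1  # second overlap residue
    spacer[site_spacer_start - 1 : site_spacer_start - 1 + m] = list(site_dna)
    spacer = "".join(spacer)

    gene_a_seq = "ATG" + _random_codons(rng, gene_codons - 2) + "TAA"
    gene_b_seq = "ATG" + _random_codons(rng, gene_codons - 2) + "TAA"
    left = "".join(rng.choice(list(DNA), size=flank_len))
    right = "".join(rng.choice(list(DNA), size=flank_len))
    plus = left + gene_a_seq + spacer + gene_b_seq + right
    G = len(plus)

    a_start = flank_len + 1
    a_end = a_start + len(gene_a_seq) - 1
    b_start = a_end + L + 1
    b_end = b_start + len(gene_b_seq) - 1
    site_plus_start = a_end + site_spacer_start

    if strand == "+":
        genome_seq = plus
        gene_a = GeneFeature("geneA", a_start, a_end, "+")
        gene_b = GeneFeature("geneB", b_start, b_end, "+")
        site_offset = site_plus_start
    else:
        genome_seq = reverse_complement(plus)
        gene_a = GeneFeature("geneA", G - a_end + 1, G - a_start + 1, "-")
        gene_b = GeneFeature("geneB", G - b_end + 1, G - b_start + 1, "-")
        site_offset = G - (site_plus_start + m - 1) + 1

    genome = SequenceRecord(id=f"synthetic_locus_{seed}", alphabet="nucleotide", residues=genome_seq)
    truth = GenomeTruth(
        seed=seed,
        strand=strand,
        genome_length=G,
        gene_a=(gene_a.start, gene_a.end),
        gene_b=(gene_b.start, gene_b.end),
        intergenic_len=L,
        site_offset=site_offset,
        site_sequence=normalize_nucleotide(realization, "rna"),
        end3_offset=end3_offset,
        end5_offset=end5_offset,
        overlap_window=(lo, hi),
    )
    return genome, [gene_a, gene_b], truth


def write_genbank(genome: SequenceRecord, features: list[GeneFeature], path) -> None:
    """Minimal legal GenBank flat file (LOCUS/FEATURES/ORIGIN)."""
    rec = BioSeqRecord(
        Seq(normalize_nucleotide(genome.residues, "dna")),
        id=genome.id,
        name=genome.id[:16].replace(".", "_"),
        description="synthetic locus",
        annotations={"molecule_type": "DNA"},
    )
    for f in features:
        loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1)
        for ftype in ("gene", "CDS"):
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.gene_id]}))
    SeqIO.write([rec], str(path), "genbank")


def transcript_region(
    genome: SequenceRecord, gene_a: GeneFeature, gene_b: GeneFeature
) -> tuple[SequenceRecord, int, int]:
    """Transcript-orientation RNA of the region from gene A start to gene B
    end, with the 1-based region positions of the gene A stop-codon last
    base and the gene B start-codon first base."""
    if gene_a.strand != gene_b.strand:
        raise ValueError("genes must share a strand")
    if gene_a.strand == "+":
        seq = genome.residues[gene_a.start - 1 : gene_b.end]
        stop_a = gene_a.end - gene_a.start + 1
        start_b = gene_b.start - gene_a.start + 1
    else:
        seq = reverse_complement(genome.residues[gene_b.start - 1 : gene_a.end])
        stop_a = gene_a.end - gene_a.start + 1  # same distance from the 5' end
        start_b = gene_a.end - gene_b.end + 1
    region = SequenceRecord(
        id=f"{gene_a.gene_id}_{gene_b.gene_id}_region",
        alphabet="nucleotide",
        residues=normalize_nucleotide(seq, "rna"),
    )
    return region, stop_a, start_b


def make_crtpcr_clones(
    genome: SequenceRecord,
    gene_a: GeneFeature,
    gene_b: GeneFeature,
    dist3: dict[int, float],
    dist5: dict[int, float],
    n_clones: int,
    noise: float = 0.0,
    flank: int = 30,
    seed: int = 0,
) -> tuple[list[CloneRead], SequenceRecord, CloneTruth]:
    """Junction-spanning clone reads drawn from planted termini
    distributions, with per-base substitution noise.

    Returns the clones, the transcript-orientation reference they map to,
    and the per-clone truth.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    for dist in (dist3, dist5):
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError("terminus probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    region, stop_a, start_b = transcript_region(genome, gene_a, gene_b)
    ref = region.residues

    offsets3 = sorted(dist3)
    offsets5 = sorted(dist5)
    p3s = np.array([dist3[o] for o in offsets3])
    p5s = np.array([dist5[o] for o in offsets5])

    clones = []
    rows = []
    for k in range(n_clones):
        o3 = offsets3[rng.choice(len(offsets3), p=p3s)]
        o5 = offsets5[rng.choice(len(offsets5), p=p5s)]
        pos3 = stop_a + o3
        pos5 = start_b + o5  # o5 negative: -1 is one base 5' of the start codon
        if pos3 - flank + 1 < 1 or pos5 + flank - 1 > len(ref):
            raise ValueError("flank runs off the reference; enlarge the locus")
        read = ref[pos3 - flank : pos3] + ref[pos5 - 1 : pos5 - 1 + flank]
        if noise:
            chars = list(read)
            for i in range(len(chars)):
                if rng.random() < noise:
                    alts = [b for b in RNA if b != chars[i]]
                    chars[i] = alts[rng.integers(0, 3)]
            read = "".join(chars)
        cid = f"clone_{k + 1:03d}"
        clones.append(CloneRead(clone_id=cid, sequence=read))
        rows.append((cid, o3, o5, pos3, pos5))
    truth = CloneTruth(seed=seed, noise=noise, flank=flank, clones=tuple(rows))
    return clones, region, truth


def make_ortholog_family(
    reference_spacer: SequenceRecord,
    n_species: int,
    rate_in: float,
    rate_out: float,
    window: tuple[int, int],
    seed: int = 0,
) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Ortholog set with independent substitutions at two rates: ``rate_in``
    inside the footprint window (1-based, inclusive), ``rate_out`` outside."""
    if n_species < 2:
        raise ValueError("need at least 2 species for conservation profiling")
    for r in (rate_in, rate_out):
        if not (0.0 <= r <= 1.0):
            raise ValueError("rates must be within [0, 1]")
    lo, hi = window
    n = len(reference_spacer)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"window {lo}..{hi} outside 1..{n}")
    rng = np.random.default_rng(seed)
    ref = normalize_nucleotide(reference_spacer.residues, "rna")
    seqs = [SequenceRecord(id=f"{reference_spacer.id}", alphabet="nucleotide", residues=ref)]
    mutated: dict[str, tuple[int, ...]] = {}
    for s in range(2, n_species + 1):
        chars = list(ref)
        hits = []
        for i in range(n):
            rate = rate_in if lo <= i + 1 <= hi else rate_out
            if rng.random() < rate:
                alts = [b for b in RNA if b != chars[i]]
                chars[i] = alts[rng.integers(0, 3)]
                hits.append(i + 1)
        sid = f"species_{s}"
        seqs.append(SequenceRecord(id=sid, alphabet="nucleotide", residues="".join(chars)))
        mutated[sid] = tuple(hits)
    truth = FamilyTruth(
        seed=seed, rate_in=rate_in, rate_out=rate_out, window=(lo, hi), mutated=mutated
    )
    return seqs, truth


def truth_to_dict(truth) -> dict:
    return asdict(truth)
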