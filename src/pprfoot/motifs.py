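"""Tandem repeat-motif detection on protein sequences.

Detection slides a fixed-length position-score profile along the protein,
keeps above-threshold local-maximum windows, and chains them into a tandem
array with inter-motif periods of 31-36 residues.  A C-terminal partial
motif of >=31 residues is retained and flagged.

The bundled default profile (``data/ppr_profile.tsv``) is a hand-built
approximation of the canonical 35-residue P-class repeat consensus with
chemically similar alternates; positions 1 and 6 are left uninformative
because they carry the nucleotide-specificity letters.  It is plain text
and user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import PROTEIN_LETTERS, SequenceRecord

MIN_MOTIF_LEN = 31
MAX_MOTIF_LEN = 36

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class PPRMotif:
    """One annotated repeat, 1-based inclusive protein coordinates."""

    index: int
    start: int
    end: int
    motif_class: str  # "P", "L", "S" or "partial"
    residue6: str
    residue1prime: str | None  # residue 1 of the next motif; None for the last

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class MotifProfile:
    """Per-position amino-acid score table plus detection threshold."""

    def __init__(self, scores: np.ndarray, threshold: float, template: str):
        if scores.ndim != 2 or scores.shape[1] != len(AA_ORDER):
            raise ValueError("scores must be (length, 20)")
        if not np.all(np.isfinite(scores)):
            raise ValueError("profile scores must be finite")
        if len(template) != scores.shape[0]:
            raise ValueError("template length must equal profile length")
        self.scores = scores.astype(float)
        self.threshold = float(threshold)
        self.template = template

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    @classmethod
    def load(cls, path: str | Path) -> "MotifProfile":
        threshold = None
        template = None
        rows: list[list[float]] = []
        header: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("threshold:"):
                        threshold = float(body.split(":", 1)[1])
                    elif body.startswith("template:"):
                        template = body.split(":", 1)[1].strip()
                    continue
                if not line.strip():
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields[1:]
                    continue
                rows.append([float(x) for x in fields[1:]])
        if threshold is None or template is None or header is None:
            raise ValueError(f"profile {path} missing threshold/template/header")
        order = [_AA_INDEX[aa] for aa in header]
        mat = np.full((len(rows), len(AA_ORDER)), np.nan)
        for i, row in enumerate(rows):
            for j, val in zip(order, row):
                mat[i, j] = val
        return cls(mat, threshold, template)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# threshold: {self.threshold}\n")
            fh.write(f"# template: {self.template}\n")
            fh.write("pos\t" + "\t".join(AA_ORDER) + "\n")
            for i in range(self.length):
                vals = "\t".join(f"{v:g}" for v in self.scores[i])
                fh.write(f"{i + 1}\t{vals}\n")


def default_profile() -> MotifProfile:
    with resources.as_file(resources.files("pprfoot.data") / "ppr_profile.tsv") as p:
        return MotifProfile.load(p)


def _window_scores(residues: str, profile: MotifProfile) -> np.ndarray:
    """Score of the profile at every 1-based window start."""
    n = len(residues)
    m = profile.length
    idx = np.array([_AA_INDEX[aa] for aa in residues], dtype=int)
    n_win = n - m + 1
    if n_win <= 0:
        return np.zeros(0)
    out = np.zeros(n_win)
    for i in range(m):
        out += profile.scores[i, idx[i : i + n_win]]
    return out


def _best_chain(cands: list[int], scores: np.ndarray) -> list[int]:
    """Maximum-total-score chain of candidate starts with 31-36 spacing.

    Ties are broken toward the more N-terminal chain.
    """
    if not cands:
        return []
    n = len(cands)
    best: list[float] = [0.0] * n
    prev: list[int] = [-1] * n
    for i, s in enumerate(cands):
        best[i] = scores[s - 1]
        for j in range(i - 1, -1, -1):
            gap = s - cands[j]
            if gap > MAX_MOTIF_LEN:
                break
            if MIN_MOTIF_LEN <= gap <= MAX_MOTIF_LEN:
                cand = best[j] + scores[s - 1]
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = int(np.argmax(best))  # argmax takes the first (most N-terminal) tie
    chain = []
    i = end
    while i != -1:
        chain.append(cands[i])
        i = prev[i]
    return chain[::-1]


def annotate_motifs(protein: SequenceRecord, profile: MotifProfile | None = None) -> list[PPRMotif]:
    """Detect the tandem repeat array of a protein.

    Returns an empty list when the protein is shorter than one motif.
    Deterministic for a fixed profile and threshold.
    """
    if protein.alphabet != "protein":
        raise ValueError("annotate_motifs requires a protein record")
    if profile is None:
        profile = default_profile()
    residues = protein.residues
    bad = set(residues) - PROTEIN_LETTERS
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in {protein.id!r}")
    m = profile.length
    n = len(residues)
    if n < m:
        return []

    w = _window_scores(residues, profile)
    starts1 = np.arange(1, len(w) + 1)

    # local maxima over a +-3 neighbourhood; strict on the left so equal
    # scores resolve to the more N-terminal window
    cands = []
    for i, s in enumerate(starts1):
        if w[i] < profile.threshold:
            continue
        lo = max(0, i - 3)
        hi = min(len(w), i + 4)
        if w[i] >= w[lo:i].max(initial=-np.inf) and w[i] > w[i + 1 : hi].max(initial=-np.inf):
            cands.append(int(s))
        elif w[i] >= w[lo:i].max(initial=-np.inf) and np.all(w[i] >= w[i + 1 : hi]):
            # plateau: keep only the leftmost of an equal run
            if i == 0 or w[i] > w[i - 1]:
                cands.append(int(s))

    chain = _best_chain(cands, w)
    if not chain:
        return []

    # C-terminal partial motif: a >=31 aa tail that cannot fit a full window
    partial_end = None
    last = chain[-1]
    for period in range(MIN_MOTIF_LEN, MAX_MOTIF_LEN + 1):
        s = last + period
        r = n - s + 1
        if MIN_MOTIF_LEN <= r < m:
            idx = np.array([_AA_INDEX[aa] for aa in residues[s - 1 : s - 1 + r]])
            pscore = float(profile.scores[np.arange(r), idx].sum())
            if pscore >= profile.threshold * r / m:
                chain.append(s)
                partial_end = n
                break

    motifs = []
    for k, s in enumerate(chain):
        if k + 1 < len(chain):
            end = chain[k + 1] - 1
            r1p = residues[chain[k + 1] - 1]
        else:
            end = partial_end if partial_end is not None and s + m - 1 > n else s + m - 1
            r1p = None
        length = end - s + 1
        if partial_end is not None and k == len(chain) - 1:
            cls_ = "partial"
        elif length == 36:
            cls_ = "L"
        elif length == 35:
            cls_ = "P"
        else:
            cls_ = "S"
        motifs.append(
            PPRMotif(
                index=k + 1,
                start=s,
                end=end,
                motif_class=cls_,
                residue6=residues[s + 4],
                residue1prime=r1p,
            )
        )
    return motifs


def extract_specificity_pairs(motifs: list[PPRMotif]) -> list[tuple[str, str]]:
    """(residue6, residue1') pairs; n motifs yield n-1 pairs."""
    for a, b in zip(motifs, motifs[1:]):
        if b.start <= a.end:
            raise ValueError(f"motifs {a.index} and {b.index} overlap or are unsorted")
    pairs = []
    for mot in motifs:
        if mot.residue1prime is not None:
            pairs.append((mot.residue6, mot.residue1prime))
    if motifs and len(pairs) != len(motifs) - 1:
        raise ValueError("every motif but the last must carry a 1' residue")
    return pairs


def write_motif_tsv(protein_id: str, motifs: list[PPRMotif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tindex\tstart\tend\tlength\tclass\tresidue6\tresidue1prime\n")
        for m in motifs:
            r1p = m.residue1prime if m.residue1prime is not None else "."
            fh.write(
                f"{protein_id}\t{m.index}\t{m.start}\t{m.end}\t{m.length}\t"
                f"{m.motif_class}\t{m.residue6}\t{r1p}\n"
            )


def read_motif_tsv(path: str | Path) -> dict[str, list[PPRMotif]]:
    """Bypass path: load a user-supplied motif coordinate table."""
    out: dict[str, list[PPRMotif]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            r1p = f[col["residue1prime"]]
            out.setdefault(f[col["protein_id"]], []).append(
                PPRMotif(
                    index=int(f[col["index"]]),
                    start=int(f[col["start"]]),
                    end=int(f[col["end"]]),
                    motif_class=f[col["class"]],
                    residue6=f[col["residue6"]],
                    residue1prime=None if r1p == "." else r1p,
                )
            )
    for motifs in out.values():
        motifs.sort(key=lambda m: m.start)
    return out
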