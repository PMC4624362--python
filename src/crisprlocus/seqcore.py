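"""Sequence primitives shared by every pipeline stage.

FASTA I/O, alphabet validation, reverse complement over the full IUPAC
nucleotide code, GC event counting ("positive" G+C vs "negative" A+T
events, ambiguous bases excluded from both), degenerate-code mapping, and
percent identity/similarity of pre-aligned sequence pairs.

Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive coordinates appear only at GFF3/BLAST boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "MolType",
    "SeqRecord",
    "Region",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "gc_counts",
    "iupac_code",
    "bases_for_iupac",
    "matches_iupac",
    "aligned_pair_stats",
]


class MolType(str, Enum):
    nucleotide = "nucleotide"
    protein = "protein"


NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# IUPAC nucleotide codes as data: code -> base set, and the complement map.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_BASES_TO_CODE = {bases: code for code, bases in IUPAC_BASES.items()}
_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}
IUPAC_COMPLEMENT = {
    code: _BASES_TO_CODE[frozenset(_COMPLEMENT_BASE[b] for b in bases)]
    for code, bases in IUPAC_BASES.items()
}
_REVCOMP_TABLE = str.maketrans(IUPAC_COMPLEMENT)


@dataclass(frozen=True)
class SeqRecord:
    """A validated sequence record: uppercase, alphabet-checked, id without whitespace."""

    id: str
    seq: str
    moltype: MolType = MolType.nucleotide

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        alphabet = (
            NUCLEOTIDE_ALPHABET if self.moltype is MolType.nucleotide else PROTEIN_ALPHABET
        )
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters {sorted(bad)} outside the "
                f"{self.moltype.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Region:
    """0-based half-open interval [start, end) on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _normalise_nucleotide(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, moltype: MolType = MolType.nucleotide) -> list[SeqRecord]:
    """Read a multi-record FASTA file into validated records (file order kept).

    Sequences are uppercased; U is mapped to T in nucleotide mode. Empty
    files, duplicate ids and out-of-alphabet characters raise ValueError
    naming the offending record.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if moltype is MolType.nucleotide:
            seq = _normalise_nucleotide(seq)
        else:
            seq = seq.upper()
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=seq, moltype=moltype))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA wrapped at `width` columns."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def fasta_string(records: Iterable[SeqRecord], width: int = 70) -> str:
    buf = io.StringIO()
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.FastaIO.FastaWriter(buf, wrap=width).write_file(bio)
    return buf.getvalue()


def revcomp(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (W->W, R->Y, ...)."""
    s = seq.upper()
    bad = set(s) - set(IUPAC_COMPLEMENT)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s.translate(_REVCOMP_TABLE)[::-1]


def gc_counts(seq: str) -> tuple[int, int]:
    """Count G+C ("positive") and A+T ("negative") events; N counts to neither."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    return gc, at


def iupac_code(bases: Iterable[str]) -> str:
    """Map a non-empty subset of {A,C,G,T} to its single IUPAC character."""
    key = frozenset(b.upper() for b in bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    if not key <= frozenset("ACGT"):
        raise ValueError(f"base set {sorted(key)} not a subset of ACGT")
    return _BASES_TO_CODE[key]


def bases_for_iupac(code: str) -> frozenset[str]:
    try:
        return IUPAC_BASES[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {code!r}") from None


def matches_iupac(seq: str, pattern: str) -> bool:
    """True when `seq` is a concrete realization of the degenerate `pattern`."""
    if len(seq) != len(pattern):
        return False
    return all(b in bases_for_iupac(p) for b, p in zip(seq.upper(), pattern.upper()))


def aligned_pair_stats(
    a: str, b: str, similarity_matrix=None
) -> tuple[float, float]:
    """Percent identity and percent similarity of two pre-aligned sequences.

    Columns where both sequences are gaps are dropped first; the remaining
    column count is the denominator for both statistics. A column is
    "similar" when it is identical or its residue pair scores positive in
    the similarity matrix (BLOSUM62 by default, EMBOSS-style).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    if similarity_matrix is None:
        from Bio.Align import substitution_matrices

        similarity_matrix = substitution_matrices.load("BLOSUM62")
    cols = [(x, y) for x, y in zip(a.upper(), b.upper()) if not (x == "-" and y == "-")]
    if not cols:
        raise ValueError("alignment contains no residue columns")
    n_ident = 0
    n_sim = 0
    for x, y in cols:
        if "-" in (x, y):
            continue
        if x == y:
            n_ident += 1
            n_sim += 1
        else:
            try:
                score = similarity_matrix[x, y]
            except (KeyError, IndexError):
                score = 0
            if score > 0:
                n_sim += 1
    n_cols = len(cols)
    return 100.0 * n_ident / n_cols, 100.0 * n_sim / n_cols


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (82.56 -> 83, 86.49 -> 86)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
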