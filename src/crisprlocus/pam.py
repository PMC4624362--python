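"""PAM consensus inference from protospacer flanks.

Extracts strand-aware 5' and 3' flanks of high-quality protospacer hits,
reorients minus-strand flanks into protospacer orientation, builds a
per-position nucleotide count matrix for each side, and derives a
degenerate IUPAC consensus: at each position every base whose frequency
reaches `min_base_freq` (default 0.2) enters the base set, which is then
mapped to its IUPAC code. With min_base_freq <= 0.25 the set can never be
empty. Both flanks are always reported so the user can judge which side
is informative; with few supporting hits the report carries a low-support
warning — a handful of protospacers constrains but does not pin down a
motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqcore import SeqRecord, iupac_code, revcomp
from .spacers import ProtospacerHit

__all__ = [
    "FlankRecord",
    "FlankSet",
    "PamConsensus",
    "extract_flanks",
    "build_pfm",
    "consensus_from_pfm",
    "pam_report",
]

LOW_SUPPORT = 10  # below this many flanks the consensus is flagged as tentative


@dataclass(frozen=True)
class FlankRecord:
    hit: ProtospacerHit
    five_prime: str  # reads 5'->3', ends immediately before the protospacer
    three_prime: str  # reads 5'->3', starts immediately after the protospacer
    padded: bool  # True when a contig edge forced N padding


@dataclass(frozen=True)
class FlankSet:
    flank_len: int
    records: tuple[FlankRecord, ...]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PamConsensus:
    side: str  # "five_prime" | "three_prime"
    k: int  # number of scored positions adjacent to the protospacer
    pfm: tuple[Mapping[str, int], ...]  # position 1 = adjacent to the protospacer
    consensus: str  # IUPAC string, reported 5'->3'
    support: int
    min_base_freq: float
    warnings: tuple[str, ...] = field(default=())


def extract_flanks(
    hits: Sequence[ProtospacerHit],
    targets: Mapping[str, SeqRecord] | Sequence[SeqRecord],
    flank_len: int = 10,
) -> FlankSet:
    """Flanks of each hit, both reported in protospacer orientation.

    Plus-strand hits slice the forward target directly; minus-strand hits
    slice the forward target, reverse-complement, and swap sides so that
    "3'" always means 3' of the protospacer. Contig edges are padded with
    N (flagged) so all flanks share flank_len.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    if not isinstance(targets, Mapping):
        targets = {t.id: t for t in targets}
    records = []
    for hit in hits:
        try:
            target = targets[hit.target_id]
        except KeyError:
            raise ValueError(f"hit references unknown target id {hit.target_id!r}") from None
        seq = target.seq
        s, e = hit.target_region.start, hit.target_region.end
        left = seq[max(0, s - flank_len) : s]
        right = seq[e : e + flank_len]
        padded = len(left) < flank_len or len(right) < flank_len
        left = "N" * (flank_len - len(left)) + left
        right = right + "N" * (flank_len - len(right))
        if hit.strand == "+":
            five, three = left, right
        else:
            five, three = revcomp(right), revcomp(left)
        records.append(FlankRecord(hit=hit, five_prime=five, three_prime=three, padded=padded))
    return FlankSet(flank_len=flank_len, records=tuple(records))


def build_pfm(flanks: Sequence[str]) -> list[dict[str, int]]:
    """Per-position counts of A/C/G/T (N tallied separately, excluded from
    the position's denominator)."""
    if not flanks:
        raise ValueError("cannot build a frequency matrix from zero flanks")
    length = len(flanks[0])
    if any(len(f) != length for f in flanks):
        raise ValueError("flanks have unequal lengths")
    pfm: list[dict[str, int]] = []
    for j in range(length):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}
        for f in flanks:
            counts[f[j]] += 1
        pfm.append(counts)
    return pfm


def consensus_from_pfm(
    pfm: Sequence[Mapping[str, int]], min_base_freq: float = 0.2
) -> str:
    """Degenerate IUPAC consensus: per position, bases with frequency >=
    min_base_freq among non-N observations."""
    letters = []
    for j, counts in enumerate(pfm, start=1):
        denom = sum(counts.get(b, 0) for b in "ACGT")
        if denom == 0:
            raise ValueError(f"position {j}: no non-N observations")
        bases = {b for b in "ACGT" if counts.get(b, 0) / denom >= min_base_freq}
        if not bases:  # unreachable for min_base_freq <= 0.25, guarded anyway
            bases = {max("ACGT", key=lambda b: counts.get(b, 0))}
        letters.append(iupac_code(bases))
    return "".join(letters)


def pam_report(
    flankset: FlankSet,
    side: str,
    k: int = 3,
    min_base_freq: float = 0.2,
) -> PamConsensus:
    """Consensus over the first k positions adjacent to the protospacer on
    one side. The consensus string always reads 5'->3'."""
    if side not in {"five_prime", "three_prime"}:
        raise ValueError("side must be 'five_prime' or 'three_prime'")
    if not flankset.records:
        raise ValueError("empty flank set")
    if k < 1 or k > flankset.flank_len:
        raise ValueError(f"k = {k} outside [1, flank_len = {flankset.flank_len}]")
    if side == "three_prime":
        windows = [r.three_prime[:k] for r in flankset.records]
        pfm = build_pfm(windows)  # position 1 adjacent to the protospacer
        consensus = consensus_from_pfm(pfm, min_base_freq)
    else:
        windows = [r.five_prime[-k:] for r in flankset.records]
        pfm_genomic = build_pfm(windows)
        consensus = consensus_from_pfm(pfm_genomic, min_base_freq)
        # store the pfm adjacent-position-first like the 3' side
        pfm = list(reversed(pfm_genomic))
    support = len(flankset.records)
    warnings = []
    if support < LOW_SUPPORT:
        warnings.append(
            f"only {support} supporting flanks: too few to conclusively "
            "determine a PAM; consensus is tentative"
        )
    if any(r.padded for r in flankset.records):
        warnings.append("one or more flanks were N-padded at a contig edge")
    return PamConsensus(
        side=side,
        k=k,
        pfm=tuple(pfm),
        consensus=consensus,
        support=support,
        min_base_freq=min_base_freq,
        warnings=tuple(warnings),
    )
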