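"""De novo CRISPR array detection and decomposition.

A seed-and-extend periodic-repeat finder with CRISPRfinder-like bounds:

1. index all k-mers of the genome (default k = 16);
2. chain k-mer occurrences recurring >= min_units times whose consecutive
   gaps fall inside the plausible repeat+spacer period window;
3. extend each chain left/right to the maximal repeat window (within the
   direct-repeat length bounds) whose columns are unanimous across the
   chained units — strictness here is safe because SNP-bearing units are
   recovered later, and it prevents a chain that happens to exclude a
   degenerate unit from creeping past the true repeat boundary;
4. derive the positionwise majority-rule consensus (ties broken by the
   lexicographically smallest base);
5. greedily absorb degenerate repeat units with up to max_unit_mismatches
   mismatches vs the consensus, both beyond the chain ends (SNP-bearing
   terminal repeats) and inside over-long internal gaps (units whose seed
   k-mer was broken by a SNP);
6. report non-overlapping arrays, preferring higher unit count, then
   longer consensus, then leftmost start, always on the forward strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .seqcore import Region, SeqRecord

__all__ = [
    "DetectorParams",
    "ArrayUnit",
    "ArraySpacer",
    "CrisprArray",
    "find_arrays",
    "consensus_and_mismatches",
    "array_to_gff",
]


@dataclass(frozen=True)
class DetectorParams:
    min_dr_len: int = 23
    max_dr_len: int = 55
    spacer_min_ratio: float = 0.6
    spacer_max_ratio: float = 2.5
    min_units: int = 3
    max_unit_mismatches: int = 4
    seed_kmer: int = 16

    def __post_init__(self) -> None:
        if self.min_dr_len > self.max_dr_len:
            raise ValueError("min_dr_len > max_dr_len")
        if self.spacer_min_ratio >= self.spacer_max_ratio:
            raise ValueError("spacer_min_ratio must be < spacer_max_ratio")
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")


@dataclass(frozen=True)
class ArrayUnit:
    region: Region
    sequence: str
    mismatches: int  # Hamming distance to the array consensus


@dataclass(frozen=True)
class ArraySpacer:
    index: int  # 1-based, numbered left to right in genome orientation
    region: Region
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CrisprArray:
    region: Region
    dr_consensus: str
    units: tuple[ArrayUnit, ...]
    spacers: tuple[ArraySpacer, ...]
    duplicate_spacer_indices: tuple[int, ...] = field(default=())

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


def consensus_and_mismatches(units: list[str]) -> tuple[str, list[int]]:
    """Majority-rule consensus of equal-length units plus per-unit Hamming
    distances to it. Ties go to the lexicographically smallest base."""
    if len(units) < 2:
        raise ValueError("need at least two units for a consensus")
    length = len(units[0])
    if any(len(u) != length for u in units):
        raise ValueError("units have unequal lengths")
    consensus_chars = []
    for j in range(length):
        counts = Counter(u[j] for u in units)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        # tie-break: among max-count bases take the smallest letter
        top = best[1]
        consensus_chars.append(min(b for b, c in counts.items() if c == top))
    consensus = "".join(consensus_chars)
    mismatches = [sum(a != b for a, b in zip(u, consensus)) for u in units]
    return consensus, mismatches


def _chain_seeds(seq: str, params: DetectorParams) -> list[list[int]]:
    k = params.seed_kmer
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    min_period = int(params.min_dr_len * (1 + params.spacer_min_ratio))
    max_period = int(params.max_dr_len * (1 + params.spacer_max_ratio))
    chains: list[list[int]] = []
    for kmer, positions in index.items():
        if len(positions) < params.min_units or "N" in kmer:
            continue
        current = [positions[0]]
        for p in positions[1:]:
            gap = p - current[-1]
            if min_period <= gap <= max_period:
                current.append(p)
            else:
                if len(current) >= params.min_units:
                    chains.append(current)
                current = [p]
        if len(current) >= params.min_units:
            chains.append(current)
    return chains


def _column_unanimous(seq: str, anchors: list[int], offset: int) -> bool:
    first: str | None = None
    for p in anchors:
        q = p + offset
        if q < 0 or q >= len(seq):
            return False
        c = seq[q]
        if first is None:
            first = c
        elif c != first:
            return False
    return True


def _extend_chain(
    seq: str, anchors: list[int], params: DetectorParams
) -> tuple[int, int] | None:
    """Window (a, b) relative to each anchor: the maximal extent whose
    columns are unanimous across the chained units, bounded by max_dr_len
    and by unit non-overlap (window no longer than the smallest anchor gap
    minus the minimal spacer length)."""
    min_gap = min(b - a for a, b in zip(anchors, anchors[1:]))
    max_len = min(
        params.max_dr_len,
        min_gap - int(params.spacer_min_ratio * params.min_dr_len),
    )
    a, b = 0, params.seed_kmer
    while (b - a) < max_len and _column_unanimous(seq, anchors, a - 1):
        a -= 1
    while (b - a) < max_len and _column_unanimous(seq, anchors, b):
        b += 1
    if (b - a) < params.min_dr_len:
        return None
    return a, b


def _absorb_flanking(
    seq: str,
    unit_starts: list[int],
    unit_len: int,
    consensus: str,
    params: DetectorParams,
) -> list[int]:
    """Greedily add degenerate repeat units beyond either end of the chain."""

    def hamming(pos: int) -> int:
        window = seq[pos : pos + unit_len]
        if len(window) < unit_len:
            return unit_len + 1
        return sum(a != b for a, b in zip(window, consensus))

    spacer_min = int(params.spacer_min_ratio * unit_len)
    spacer_max = int(params.spacer_max_ratio * unit_len)

    starts = list(unit_starts)
    while True:  # leftward
        first = starts[0]
        lo = first - unit_len - spacer_max
        hi = first - unit_len - spacer_min
        best: tuple[int, int] | None = None
        for q in range(max(0, lo), hi + 1):
            h = hamming(q)
            if h <= params.max_unit_mismatches and (
                best is None or h < best[0] or (h == best[0] and q > best[1])
            ):
                best = (h, q)  # prefer fewest mismatches, then nearest (largest q)
        if best is None:
            break
        starts.insert(0, best[1])
    while True:  # rightward
        last = starts[-1]
        lo = last + unit_len + spacer_min
        hi = last + unit_len + spacer_max
        best = None
        for q in range(lo, min(hi, len(seq) - unit_len) + 1):
            h = hamming(q)
            if h <= params.max_unit_mismatches and (
                best is None or h < best[0] or (h == best[0] and q < best[1])
            ):
                best = (h, q)
        if best is None:
            break
        starts.append(best[1])

    # internal fill: a gap too long to be one spacer hides a unit whose
    # seed k-mer was broken by a SNP
    changed = True
    while changed:
        changed = False
        for s1, s2 in zip(starts, starts[1:]):
            gap = s2 - (s1 + unit_len)
            if gap <= spacer_max:
                continue
            lo = s1 + unit_len + spacer_min
            hi = s2 - unit_len - spacer_min
            best = None
            for q in range(lo, hi + 1):
                h = hamming(q)
                if h <= params.max_unit_mismatches and (
                    best is None or h < best[0] or (h == best[0] and q < best[1])
                ):
                    best = (h, q)
            if best is not None:
                starts.append(best[1])
                starts.sort()
                changed = True
                break
    return starts


def _trim_window(
    seq: str, starts: list[int], unit_len: int, params: DetectorParams
) -> tuple[list[int], int]:
    """Shave boundary columns that the full unit set reveals as junk.

    A chain that happened to exclude a degenerate unit can extend one or
    two columns past the true repeat boundary (a flanking column can be
    unanimous by chance within a small chain). Across *all* units such a
    column is far from conserved, while a genuine repeat column deviates
    in at most the few SNP-bearing units — so trim boundary columns with
    more than n_units // 4 deviants from the consensus."""
    while unit_len > params.min_dr_len:
        units = [seq[s : s + unit_len] for s in starts]
        consensus, _ = consensus_and_mismatches(units)
        threshold = len(units) // 4
        left_dev = sum(u[0] != consensus[0] for u in units)
        right_dev = sum(u[-1] != consensus[-1] for u in units)
        if left_dev > threshold and left_dev >= right_dev:
            starts = [s + 1 for s in starts]
            unit_len -= 1
        elif right_dev > threshold:
            unit_len -= 1
        else:
            break
    return starts, unit_len


def find_arrays(
    genome: SeqRecord, params: DetectorParams | None = None
) -> list[CrisprArray]:
    """Detect CRISPR arrays in a genome; empty list when nothing is found."""
    params = params or DetectorParams()
    seq = genome.seq
    candidates: list[CrisprArray] = []
    seen_regions: set[tuple[int, int]] = set()
    for anchors in _chain_seeds(seq, params):
        window = _extend_chain(seq, anchors, params)
        if window is None:
            continue
        a, b = window
        unit_len = b - a
        starts = [p + a for p in anchors]
        consensus0, _ = consensus_and_mismatches(
            [seq[s : s + unit_len] for s in starts]
        )
        starts = _absorb_flanking(seq, starts, unit_len, consensus0, params)
        starts, unit_len = _trim_window(seq, starts, unit_len, params)
        unit_seqs = [seq[s : s + unit_len] for s in starts]
        consensus, mismatches = consensus_and_mismatches(unit_seqs)
        region_key = (starts[0], starts[-1] + unit_len)
        if region_key in seen_regions:
            continue
        seen_regions.add(region_key)
        units = tuple(
            ArrayUnit(
                region=Region(genome.id, s, s + unit_len),
                sequence=u,
                mismatches=m,
            )
            for s, u, m in zip(starts, unit_seqs, mismatches)
        )
        spacers = []
        ok = True
        for i, (u1, u2) in enumerate(zip(units, units[1:]), start=1):
            sp_seq = seq[u1.region.end : u2.region.start]
            if not (
                params.spacer_min_ratio * unit_len
                <= len(sp_seq)
                <= params.spacer_max_ratio * unit_len
            ):
                ok = False
                break
            spacers.append(
                ArraySpacer(
                    index=i,
                    region=Region(genome.id, u1.region.end, u2.region.start),
                    sequence=sp_seq,
                )
            )
        if not ok or len(units) < params.min_units:
            continue
        sp_counts = Counter(s.sequence for s in spacers)
        duplicates = tuple(
            s.index for s in spacers if sp_counts[s.sequence] > 1
        )
        candidates.append(
            CrisprArray(
                region=Region(genome.id, region_key[0], region_key[1]),
                dr_consensus=consensus,
                units=units,
                spacers=tuple(spacers),
                duplicate_spacer_indices=duplicates,
            )
        )

    # prefer more units, then longer consensus, then leftmost; keep non-overlapping
    candidates.sort(key=lambda c: (-c.n_units, -len(c.dr_consensus), c.region.start))
    chosen: list[CrisprArray] = []
    for cand in candidates:
        if all(
            cand.region.end <= other.region.start or cand.region.start >= other.region.end
            for other in chosen
        ):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.region.start)
    return chosen


def array_to_gff(array: CrisprArray, source_tag: str = "crisprlocus") -> list[str]:
    """GFF3 lines (1-based inclusive) — one repeat_region parent, one child
    feature per direct repeat and spacer, in coordinate order."""
    contig = array.region.contig_id
    parent_id = f"crispr_array_{array.region.start + 1}"
    lines = ["##gff-version 3"]

    def row(ftype: str, start: int, end: int, attrs: str) -> str:
        return "\t".join(
            [contig, source_tag, ftype, str(start + 1), str(end), ".", "+", ".", attrs]
        )

    lines.append(
        row(
            "repeat_region",
            array.region.start,
            array.region.end,
            f"ID={parent_id};Name=CRISPR_array;consensus={array.dr_consensus}",
        )
    )
    features: list[tuple[int, str]] = []
    for i, unit in enumerate(array.units, start=1):
        features.append(
            (
                unit.region.start,
                row(
                    "direct_repeat",
                    unit.region.start,
                    unit.region.end,
                    f"ID={parent_id}.DR{i};Parent={parent_id};mismatches={unit.mismatches}",
                ),
            )
        )
    for sp in array.spacers:
        features.append(
            (
                sp.region.start,
                row(
                    "binding_site",
                    sp.region.start,
                    sp.region.end,
                    f"ID={parent_id}.Sp{sp.index};Parent={parent_id}",
                ),
            )
        )
    features.sort(key=lambda t: t[0])
    lines.extend(line for _, line in features)
    return lines
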