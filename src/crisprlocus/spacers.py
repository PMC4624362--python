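"""Spacer -> protospacer search and hit-quality scoring.

Spacers are aligned to target contigs by Smith-Waterman local alignment
(both strands, blastn-short-like scoring for 29-30 nt queries) or ingested
from BLAST tabular (outfmt 6) files produced outside the package. Each hit
carries percent identity (matches / alignment columns, BLAST pident
convention), percent coverage (aligned spacer positions / spacer length),
and the percent-hit-quality ranking statistic

    %HQ = %ID * %cov / 100

kept at full precision internally and rounded half-up to an integer for
display. Hits are ranked by %HQ; the reporting filter is a strict
"greater than" at the threshold (default 80). E-values are deliberately
not computed: they are uninformative for queries this short.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .seqcore import Region, SeqRecord, revcomp, round_half_up

__all__ = [
    "AlignmentScoring",
    "ProtospacerHit",
    "hq_score",
    "hq_display",
    "align_spacer",
    "align_spacers",
    "ingest_tabular_hits",
    "rank_and_filter",
    "hits_to_table",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """BLAST-style scores: a gap of length L costs |gap_open| + L * |gap_extend|."""

    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 18.0


@dataclass(frozen=True)
class ProtospacerHit:
    spacer_id: str
    spacer_length: int
    target_id: str
    target_region: Region  # protospacer footprint on the forward target strand
    strand: str  # strand of the target carrying the protospacer in spacer orientation
    pct_id: float
    pct_cov: float
    n_matches: int
    n_mismatches: int
    n_gaps: int
    score: float = 0.0
    best_for_spacer: bool = False

    @property
    def hq(self) -> float:
        return hq_score(self.pct_id, self.pct_cov)

    @property
    def hq_display(self) -> int:
        return hq_display(self.hq)


def hq_score(pct_id: float, pct_cov: float) -> float:
    """Percent hit quality: %ID x %cov / 100, full precision."""
    for name, v in (("pct_id", pct_id), ("pct_cov", pct_cov)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} = {v} outside [0, 100]")
    return pct_id * pct_cov / 100.0


def hq_display(hq: float) -> int:
    """Display rounding for reports: nearest integer, half up."""
    return round_half_up(hq)


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    # PairwiseAligner charges open_gap_score for the first gap position and
    # extend_gap_score for each additional one; BLAST charges open + L*extend.
    al.open_gap_score = scoring.gap_open + scoring.gap_extend
    al.extend_gap_score = scoring.gap_extend
    return al


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int]:
    """(qstart, qend, tstart, tend, matches, mismatches, gaps) of a local alignment."""
    # PairwiseAligner.align(spacer, segment): biopython calls the first
    # argument "target" and the second "query"; aligned[0] indexes the first.
    q_blocks, t_blocks = alignment.aligned
    query = str(alignment.target)  # the spacer
    target = str(alignment.query)  # the segment
    matches = mismatches = 0
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for a, b in zip(query[qs:qe], target[ts:te]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    gaps = 0
    for (prev_q, prev_t), (next_q, next_t) in zip(
        zip(q_blocks[:-1], t_blocks[:-1]), zip(q_blocks[1:], t_blocks[1:])
    ):
        gaps += (next_q[0] - prev_q[1]) + (next_t[0] - prev_t[1])
    qstart, qend = int(q_blocks[0][0]), int(q_blocks[-1][1])
    tstart, tend = int(t_blocks[0][0]), int(t_blocks[-1][1])
    return qstart, qend, tstart, tend, matches, mismatches, gaps


def _collect_hits(
    aligner: Align.PairwiseAligner,
    spacer: SeqRecord,
    segment: str,
    seg_offset: int,
    strand: str,
    target: SeqRecord,
    scoring: AlignmentScoring,
    out: list[ProtospacerHit],
) -> None:
    """Recursively report locally optimal, non-overlapping hits in `segment`."""
    if len(segment) < 4:
        return
    alignments = aligner.align(spacer.seq, segment)
    if alignments.score < scoring.min_score:
        return
    aln = alignments[0]
    qstart, qend, tstart, tend, matches, mismatches, gaps = _alignment_stats(aln)
    columns = matches + mismatches + gaps
    pct_id = 100.0 * matches / columns
    pct_cov = 100.0 * (qend - qstart) / len(spacer.seq)
    if strand == "+":
        fwd_start, fwd_end = seg_offset + tstart, seg_offset + tend
    else:
        # segment is a slice of revcomp(target); map back to forward coordinates
        L = len(target.seq)
        fwd_start = L - (seg_offset + tend)
        fwd_end = L - (seg_offset + tstart)
    out.append(
        ProtospacerHit(
            spacer_id=spacer.id,
            spacer_length=len(spacer.seq),
            target_id=target.id,
            target_region=Region(target.id, fwd_start, fwd_end),
            strand=strand,
            pct_id=pct_id,
            pct_cov=pct_cov,
            n_matches=matches,
            n_mismatches=mismatches,
            n_gaps=gaps,
            score=float(alignments.score),
        )
    )
    _collect_hits(aligner, spacer, segment[:tstart], seg_offset, strand, target, scoring, out)
    _collect_hits(
        aligner, spacer, segment[tend:], seg_offset + tend, strand, target, scoring, out
    )


def align_spacer(
    spacer: SeqRecord,
    target: SeqRecord,
    scoring: AlignmentScoring | None = None,
) -> list[ProtospacerHit]:
    """Smith-Waterman the spacer against both strands of one target contig."""
    if not spacer.seq or not target.seq:
        raise ValueError("empty sequence passed to align_spacer")
    scoring = scoring or AlignmentScoring()
    aligner = _aligner(scoring)
    hits: list[ProtospacerHit] = []
    _collect_hits(aligner, spacer, target.seq, 0, "+", target, scoring, hits)
    _collect_hits(aligner, spacer, revcomp(target.seq), 0, "-", target, scoring, hits)
    hits.sort(key=lambda h: (-h.score, h.target_region.start, h.strand))
    return hits


def align_spacers(
    spacers: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    scoring: AlignmentScoring | None = None,
) -> list[ProtospacerHit]:
    hits: list[ProtospacerHit] = []
    for sp in spacers:
        for tg in targets:
            hits.extend(align_spacer(sp, tg, scoring))
    return hits


def ingest_tabular_hits(
    path: str | Path, spacer_lengths: Mapping[str, int]
) -> list[ProtospacerHit]:
    """Read BLAST outfmt-6 rows (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore) into hits.

    1-based inclusive coordinates become 0-based half-open; sstart > send
    marks a minus-strand hit. Coverage = (qend - qstart + 1) / spacer length.
    """
    hits: list[ProtospacerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if qseqid not in spacer_lengths:
                raise ValueError(f"{path}:{lineno}: unknown spacer id {qseqid!r}")
            sp_len = spacer_lengths[qseqid]
            if sstart <= send:
                strand = "+"
                region = Region(sseqid, sstart - 1, send)
            else:
                strand = "-"
                region = Region(sseqid, send - 1, sstart)
            matches = round_half_up(pident / 100.0 * length)
            hits.append(
                ProtospacerHit(
                    spacer_id=qseqid,
                    spacer_length=sp_len,
                    target_id=sseqid,
                    target_region=region,
                    strand=strand,
                    pct_id=pident,
                    pct_cov=100.0 * (qend - qstart + 1) / sp_len,
                    n_matches=matches,
                    n_mismatches=mismatch,
                    n_gaps=gapopen,
                    score=bitscore,
                )
            )
    return hits


def rank_and_filter(
    hits: Iterable[ProtospacerHit], hq_threshold: float = 80.0
) -> list[ProtospacerHit]:
    """Keep hits with %HQ strictly above the threshold, sorted by %HQ
    descending (ties by spacer id, target id, start); the best hit per
    spacer is flagged."""
    kept = [h for h in hits if h.hq > hq_threshold]
    kept.sort(key=lambda h: (-h.hq, h.spacer_id, h.target_id, h.target_region.start))
    seen: set[str] = set()
    out = []
    for h in kept:
        flag = h.spacer_id not in seen
        seen.add(h.spacer_id)
        out.append(replace(h, best_for_spacer=flag))
    return out


def hits_to_table(hits: Sequence[ProtospacerHit]):
    """Hits as a pandas DataFrame mirroring the report columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "target_id": h.target_id,
                "start": h.target_region.start,
                "end": h.target_region.end,
                "strand": h.strand,
                "pct_id": round(h.pct_id, 2),
                "pct_cov": round(h.pct_cov, 2),
                "hq": round(h.hq, 2),
                "hq_display": h.hq_display,
                "n_matches": h.n_matches,
                "n_mismatches": h.n_mismatches,
                "n_gaps": h.n_gaps,
                "best_for_spacer": h.best_for_spacer,
            }
            for h in hits
        ],
        columns=[
            "spacer_id",
            "target_id",
            "start",
            "end",
            "strand",
            "pct_id",
            "pct_cov",
            "hq",
            "hq_display",
            "n_matches",
            "n_mismatches",
            "n_gaps",
            "best_for_spacer",
        ],
    )
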