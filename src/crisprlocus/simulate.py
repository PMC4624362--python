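"""Seeded synthetic datasets with exact ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a high-GC background chromosome (default 66.5 % G+C) carrying a
horizontally inserted low-GC cas-like locus (default 56 %) followed by a
CRISPR array of 36-nt direct repeats alternating with unique 29-30-nt
spacers, plus "phage" target contigs in which selected spacers are planted
as protospacers at requested identity/coverage with a concrete PAM drawn
from a degenerate template on the 3' flank.

Every random draw comes from one numpy Generator seeded from the spec, so
identical spec+seed gives byte-identical FASTA output.

Two deliberate design properties keep the ground truth exactly
recoverable (see docs/methods.md for rationale):

* planted arrays are rejection-checked so the columns immediately outside
  each repeat are never (near-)unanimously conserved — the array boundary
  is uniquely decodable;
* planted protospacers are constructed so the optimal local alignment
  footprint equals the planted footprint: substitutions sit >= 4 nt from
  either end of the planted copy, and the target base following a
  truncated copy always differs from the spacer base it would pair with;
* the concrete letters behind each degenerate PAM position — and every
  5'-flank column — are stratified (balanced) across the planted hits, so
  the small-support frequency matrix reflects the intended distribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqcore import (
    Region,
    SeqRecord,
    bases_for_iupac,
    revcomp,
    round_half_up,
)

__all__ = [
    "PlantedHit",
    "SyntheticSpec",
    "PlantedHitRecord",
    "SyntheticTruth",
    "generate_dataset",
    "mutate_to_identity",
    "DEFAULT_PLANTED_HITS",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedHit:
    """Request for one spacer->protospacer planting."""

    spacer_index: int  # 1-based, Sp1..SpN numbered left to right
    pct_id: float
    pct_cov: float
    strand: str = "+"


# Default plantings mirror the eight high-quality spacer hits of the study
# system: two perfect prophage matches, and partial-identity/coverage hits
# down to HQ ~83.
DEFAULT_PLANTED_HITS: tuple[PlantedHit, ...] = (
    PlantedHit(8, 100.0, 100.0, "+"),
    PlantedHit(9, 100.0, 100.0, "-"),
    PlantedHit(16, 100.0, 97.0, "+"),
    PlantedHit(13, 90.0, 100.0, "-"),
    PlantedHit(4, 93.0, 97.0, "+"),
    PlantedHit(11, 93.0, 93.0, "-"),
    PlantedHit(10, 93.0, 93.0, "+"),
    PlantedHit(20, 96.0, 86.0, "-"),
)


def _default_spacer_lengths() -> tuple[int, ...]:
    # 19 spacers of 30 nt and two of 29 nt (Sp6 and Sp18 here).
    lengths = [30] * 21
    lengths[5] = 29
    lengths[17] = 29
    return tuple(lengths)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; defaults are the study conditions."""

    genome_length: int = 100_000
    genome_gc: float = 0.665
    locus_gc: float = 0.56
    locus_length: int = 5_600  # cas-like region, excludes the array
    n_spacers: int = 21
    dr_length: int = 36
    spacer_lengths: tuple[int, ...] | None = None
    # unit index (0-based, left to right) -> number of substitutions vs the
    # repeat template. None selects the study-system default: 19 identical
    # units, a terminal unit with 3 SNPs, one interior unit with 1 SNP, and
    # a degenerate opposite terminal unit with 1 SNP. Pass {} for a
    # mismatch-free array.
    dr_snp_plan: Mapping[int, int] | None = None
    pam_template: str = "WGR"
    flank_pad: int = 10
    target_pad: int = 150
    planted_hits: tuple[PlantedHit, ...] = DEFAULT_PLANTED_HITS
    n_decoy_targets: int = 2
    seed: int = 42

    def resolved_spacer_lengths(self) -> tuple[int, ...]:
        if self.spacer_lengths is not None:
            if len(self.spacer_lengths) != self.n_spacers:
                raise ValueError(
                    f"spacer_lengths has {len(self.spacer_lengths)} entries for "
                    f"{self.n_spacers} spacers"
                )
            return tuple(self.spacer_lengths)
        if self.n_spacers == 21:
            return _default_spacer_lengths()
        return tuple([30] * self.n_spacers)

    def resolved_snp_plan(self) -> dict[int, int]:
        if self.dr_snp_plan is not None:
            return dict(self.dr_snp_plan)
        n_units = self.n_spacers + 1
        if n_units < 6:
            return {}
        return {0: 3, 3: 1, n_units - 1: 1}

    def validate(self) -> None:
        if not (0 < self.genome_gc < 1 and 0 < self.locus_gc < 1):
            raise ValueError("GC fractions must lie in (0, 1)")
        if self.n_spacers < 1:
            raise ValueError("need at least one spacer")
        for idx in self.resolved_snp_plan():
            if not 0 <= idx < self.n_spacers + 1:
                raise ValueError(f"dr_snp_plan unit index {idx} out of range")
        for hit in self.planted_hits:
            if not 1 <= hit.spacer_index <= self.n_spacers:
                raise ValueError(f"planted hit spacer index {hit.spacer_index} out of range")
            if hit.pct_cov > 100 or hit.pct_cov <= 0:
                raise ValueError(f"coverage {hit.pct_cov} outside (0, 100]")
            if hit.pct_id > 100 or hit.pct_id <= 0:
                raise ValueError(f"identity {hit.pct_id} outside (0, 100]")
            if hit.strand not in {"+", "-"}:
                raise ValueError(f"strand {hit.strand!r} must be '+' or '-'")


@dataclass(frozen=True)
class PlantedHitRecord:
    spacer_index: int
    target_id: str
    region: Region  # protospacer footprint on the forward target strand
    strand: str
    realized_pct_id: float
    realized_pct_cov: float
    planted_pam: str  # concrete bases, protospacer orientation


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside every simulated dataset."""

    genome_id: str
    locus_region: Region
    array_region: Region
    repeat_regions: tuple[Region, ...]
    spacer_regions: tuple[Region, ...]
    dr_consensus: str
    spacer_seqs: tuple[str, ...]
    planted_hit_records: tuple[PlantedHitRecord, ...]
    requested_gc: Mapping[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        def region(r: Region) -> dict:
            return {"contig_id": r.contig_id, "start": r.start, "end": r.end, "strand": r.strand}

        doc = {
            "genome_id": self.genome_id,
            "locus_region": region(self.locus_region),
            "array_region": region(self.array_region),
            "repeat_regions": [region(r) for r in self.repeat_regions],
            "spacer_regions": [region(r) for r in self.spacer_regions],
            "dr_consensus": self.dr_consensus,
            "spacer_seqs": list(self.spacer_seqs),
            "planted_hit_records": [
                {**asdict(rec), "region": region(rec.region)} for rec in self.planted_hit_records
            ],
            "requested_gc": dict(self.requested_gc),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _substitute(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in positions:
        others = [b for b in "ACGT" if b != out[pos]]
        out[pos] = others[int(rng.integers(len(others)))]
    return "".join(out)


def mutate_to_identity(
    seq: str,
    pct_id: float,
    rng: int | np.random.Generator,
    protect_ends: int = 0,
    min_separation: int = 1,
) -> str:
    """Substitute exactly round((1 - pct_id/100) * len) positions (half-up).

    Positions are distinct and each substitution is to a different base, so
    the Hamming distance to the input equals the substitution count.
    `protect_ends` keeps that many positions untouched at either end, and
    `min_separation` forces substitutions that far apart — together these
    let a caller guarantee that every match run around a substitution is
    long enough for the full planted footprint to be the unique optimum of
    a local alignment.
    """
    if not 0 < pct_id <= 100:
        raise ValueError(f"pct_id {pct_id} outside (0, 100]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_sub = round_half_up((1 - pct_id / 100.0) * len(seq))
    if n_sub == 0:
        return seq
    lo, hi = protect_ends, len(seq) - protect_ends
    if hi - lo < n_sub:
        raise ValueError(
            f"cannot place {n_sub} substitutions in {hi - lo} unprotected positions"
        )
    for _ in range(1000):
        positions = sorted(
            int(p) for p in rng.choice(np.arange(lo, hi), size=n_sub, replace=False)
        )
        if all(b - a >= min_separation for a, b in zip(positions, positions[1:])):
            return _substitute(seq, positions, rng)
    raise ValueError(
        f"cannot place {n_sub} substitutions with separation {min_separation} "
        f"in {hi - lo} positions"
    )


def _boundary_identifiable(column: Sequence[str], n_units: int) -> bool:
    """True when a flanking column is not conserved enough to be mistaken
    for a repeat column by a majority-consensus extender (which tolerates
    n_units // 8 deviant units per column)."""
    counts: dict[str, int] = {}
    for c in column:
        counts[c] = counts.get(c, 0) + 1
    majority = max(counts.values())
    return (n_units - majority) > (n_units // 8)


def _draw_spacers(
    rng: np.random.Generator,
    lengths: Sequence[int],
    gc: float,
    left_flank_base: str,
    right_flank_base: str,
    max_tries: int = 500,
) -> list[str]:
    """Unique spacers whose boundary columns keep the planted array decodable."""
    n_units = len(lengths) + 1
    for _ in range(max_tries):
        spacers = [_random_seq(rng, n, gc) for n in lengths]
        if len(set(spacers)) != len(spacers):
            continue
        # Column immediately right of each repeat: first base of each spacer
        # plus the genomic base after the terminal repeat; mirrored on the left.
        right_col = [s[0] for s in spacers] + [right_flank_base]
        left_col = [left_flank_base] + [s[-1] for s in spacers]
        if _boundary_identifiable(right_col, n_units) and _boundary_identifiable(
            left_col, n_units
        ):
            return spacers
    raise RuntimeError("could not draw unique, boundary-identifiable spacers")


def _balanced_columns(
    rng: np.random.Generator, alphabet_per_position: Sequence[Sequence[str]], n: int
) -> list[list[str]]:
    """One column of length n per position, each a shuffled balanced multiset
    over that position's alphabet (counts differ by at most one)."""
    columns = []
    for letters in alphabet_per_position:
        pool = [letters[i % len(letters)] for i in range(n)]
        columns.append([pool[int(j)] for j in rng.permutation(n)])
    return columns


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[SeqRecord, list[SeqRecord], SyntheticTruth]:
    """Build (genome, targets, truth) for one seeded synthetic dataset."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = spec.resolved_spacer_lengths()
    n_units = spec.n_spacers + 1

    genome_id = "synthetic_chromosome"
    background = _random_seq(rng, spec.genome_length, spec.genome_gc)
    cas_seq = _random_seq(rng, spec.locus_length, spec.locus_gc)
    insert_pos = int(
        rng.integers(spec.genome_length // 4, 3 * spec.genome_length // 4)
    )

    dr_template = _random_seq(rng, spec.dr_length, spec.locus_gc)
    spacers = _draw_spacers(
        rng,
        lengths,
        spec.locus_gc,
        left_flank_base=cas_seq[-1],
        right_flank_base=background[insert_pos],
    )

    units = [dr_template] * n_units
    for unit_idx, n_snps in sorted(spec.resolved_snp_plan().items()):
        if n_snps:
            positions = rng.choice(spec.dr_length, size=n_snps, replace=False)
            units[unit_idx] = _substitute(dr_template, [int(p) for p in positions], rng)

    # Assemble: background[:ins] + cas + (DR Sp)^n DR + background[ins:]
    array_parts: list[str] = []
    for i in range(spec.n_spacers):
        array_parts.append(units[i])
        array_parts.append(spacers[i])
    array_parts.append(units[-1])
    array_seq = "".join(array_parts)

    genome_seq = background[:insert_pos] + cas_seq + array_seq + background[insert_pos:]
    genome = SeqRecord(id=genome_id, seq=genome_seq)

    locus_start = insert_pos
    array_start = insert_pos + len(cas_seq)
    locus_region = Region(genome_id, locus_start, array_start + len(array_seq))
    array_region = Region(genome_id, array_start, array_start + len(array_seq))

    repeat_regions: list[Region] = []
    spacer_regions: list[Region] = []
    cursor = array_start
    for i in range(spec.n_spacers):
        repeat_regions.append(Region(genome_id, cursor, cursor + spec.dr_length))
        cursor += spec.dr_length
        spacer_regions.append(Region(genome_id, cursor, cursor + lengths[i]))
        cursor += lengths[i]
    repeat_regions.append(Region(genome_id, cursor, cursor + spec.dr_length))

    # ---- targets -----------------------------------------------------------
    targets: list[SeqRecord] = []
    records: list[PlantedHitRecord] = []
    n_hits = len(spec.planted_hits)
    if n_hits:
        pam_letters = _balanced_columns(
            rng, [sorted(bases_for_iupac(c)) for c in spec.pam_template], n_hits
        )
        flank5_cols = _balanced_columns(rng, [list("ACGT")] * spec.flank_pad, n_hits)

        kept_list = []
        for hit in spec.planted_hits:
            sp = spacers[hit.spacer_index - 1]
            kept_list.append(round_half_up(hit.pct_cov / 100.0 * len(sp)))

        # Keep the local-alignment footprint flush with the planted copy: the
        # PAM base pairing with the first dropped spacer position must differ
        # from it, else the alignment would extend past the truncation point.
        for i, hit in enumerate(spec.planted_hits):
            sp = spacers[hit.spacer_index - 1]
            kept = kept_list[i]
            if kept < len(sp) and pam_letters[0][i] == sp[kept]:
                for j in range(n_hits):
                    if j == i or pam_letters[0][j] == pam_letters[0][i]:
                        continue
                    sp_j = spacers[spec.planted_hits[j].spacer_index - 1]
                    kept_j = kept_list[j]
                    if kept_j < len(sp_j) and pam_letters[0][i] == sp_j[kept_j]:
                        continue
                    pam_letters[0][i], pam_letters[0][j] = (
                        pam_letters[0][j],
                        pam_letters[0][i],
                    )
                    break

        for i, hit in enumerate(spec.planted_hits):
            sp = spacers[hit.spacer_index - 1]
            kept = kept_list[i]
            # substitutions >= 5 nt from the ends and >= 6 apart: every match
            # run around a substitution then outweighs the mismatch penalty,
            # so the optimal local alignment is exactly the planted footprint
            copy = mutate_to_identity(
                sp[:kept], hit.pct_id, rng, protect_ends=5, min_separation=6
            )
            n_sub = sum(a != b for a, b in zip(copy, sp[:kept]))
            pam = "".join(pam_letters[p][i] for p in range(len(spec.pam_template)))
            flank5 = "".join(flank5_cols[p][i] for p in range(spec.flank_pad))
            tail = _random_seq(rng, spec.flank_pad - len(pam), 0.5) if spec.flank_pad > len(pam) else ""
            cassette = flank5 + copy + pam + tail
            left_pad = _random_seq(rng, spec.target_pad, 0.5)
            right_pad = _random_seq(rng, spec.target_pad, 0.5)
            target_id = f"phage_{i + 1}_Sp{hit.spacer_index}"
            if hit.strand == "+":
                target_seq = left_pad + cassette + right_pad
                start = len(left_pad) + spec.flank_pad
                region = Region(target_id, start, start + kept)
            else:
                target_seq = left_pad + revcomp(cassette) + right_pad
                off = len(cassette) - (spec.flank_pad + kept)  # offset of copy in revcomp'd cassette
                start = len(left_pad) + off
                region = Region(target_id, start, start + kept)
            targets.append(SeqRecord(id=target_id, seq=target_seq))
            records.append(
                PlantedHitRecord(
                    spacer_index=hit.spacer_index,
                    target_id=target_id,
                    region=region,
                    strand=hit.strand,
                    realized_pct_id=100.0 * (kept - n_sub) / kept,
                    realized_pct_cov=100.0 * kept / len(sp),
                    planted_pam=pam,
                )
            )

    for j in range(spec.n_decoy_targets):
        targets.append(
            SeqRecord(
                id=f"decoy_{j + 1}",
                seq=_random_seq(rng, 2 * spec.target_pad + 100, 0.5),
            )
        )

    truth = SyntheticTruth(
        genome_id=genome_id,
        locus_region=locus_region,
        array_region=array_region,
        repeat_regions=tuple(repeat_regions),
        spacer_regions=tuple(spacer_regions),
        dr_consensus=dr_template,
        spacer_seqs=tuple(spacers),
        planted_hit_records=tuple(records),
        requested_gc={
            "genome": spec.genome_gc,
            "locus": spec.locus_gc,
            "targets": 0.5,
        },
    )
    return genome, targets, truth
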