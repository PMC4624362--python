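"""End-to-end orchestration: array detection -> spacer matching -> PAM
inference -> GC/HGT test, with every intermediate written in a standard
format (FASTA, GFF3, TSV, JSON) so any stage can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .arrays import CrisprArray, DetectorParams, array_to_gff, find_arrays
from .gc import locus_vs_background_test, sliding_gc
from .pam import extract_flanks, pam_report
from .seqcore import Region, SeqRecord, read_fasta, write_fasta
from .spacers import (
    AlignmentScoring,
    align_spacers,
    hits_to_table,
    rank_and_filter,
)

logger = logging.getLogger("crisprlocus")

__all__ = ["PipelineConfig", "RunReport", "run_all", "read_bed"]


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable configuration for the whole pipeline."""

    # array detection
    min_dr_len: int = 23
    max_dr_len: int = 55
    spacer_min_ratio: float = 0.6
    spacer_max_ratio: float = 2.5
    min_units: int = 3
    max_unit_mismatches: int = 4
    seed_kmer: int = 16
    # alignment scoring (BLAST-style gap semantics)
    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_score: float = 18.0
    # reporting
    hq_threshold: float = 80.0
    flank_len: int = 10
    pam_k: int = 3
    min_base_freq: float = 0.2
    # GC stage
    gc_window: int = 120
    gc_step: int = 1
    locus_margin: int = 5_000  # upstream margin standing in for the cas operon
    seed: int = 42
    log_level: str = "INFO"

    def detector_params(self) -> DetectorParams:
        return DetectorParams(
            min_dr_len=self.min_dr_len,
            max_dr_len=self.max_dr_len,
            spacer_min_ratio=self.spacer_min_ratio,
            spacer_max_ratio=self.spacer_max_ratio,
            min_units=self.min_units,
            max_unit_mismatches=self.max_unit_mismatches,
            seed_kmer=self.seed_kmer,
        )

    def scoring(self) -> AlignmentScoring:
        return AlignmentScoring(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            min_score=self.min_score,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class RunReport:
    version: str
    config: dict[str, Any]
    input_checksums: dict[str, str]
    arrays: list[dict[str, Any]] = field(default_factory=list)
    n_hits_total: int = 0
    n_hits_passing: int = 0
    pam: dict[str, Any] = field(default_factory=dict)
    gc_test: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def read_bed(path: str | Path) -> list[Region]:
    """Minimal BED reader: chrom, start, end (0-based half-open)."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
        regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def _array_summary(array: CrisprArray) -> dict[str, Any]:
    return {
        "contig": array.region.contig_id,
        "start": array.region.start,
        "end": array.region.end,
        "n_units": array.n_units,
        "n_spacers": array.n_spacers,
        "consensus": array.dr_consensus,
        "unit_mismatches": [u.mismatches for u in array.units],
        "duplicate_spacers": list(array.duplicate_spacer_indices),
    }


def _write_array_artifacts(arrays: list[CrisprArray], outdir: Path) -> list[SeqRecord]:
    spacer_records: list[SeqRecord] = []
    gff_lines: list[str] = ["##gff-version 3"]
    tsv_rows = ["array\ttype\tindex\tstart\tend\tlength\tmismatches\tsequence"]
    for ai, array in enumerate(arrays, start=1):
        gff_lines.extend(array_to_gff(array)[1:])
        for ui, unit in enumerate(array.units, start=1):
            tsv_rows.append(
                f"{ai}\tDR\t{ui}\t{unit.region.start}\t{unit.region.end}"
                f"\t{len(unit.sequence)}\t{unit.mismatches}\t{unit.sequence}"
            )
        for sp in array.spacers:
            tsv_rows.append(
                f"{ai}\tspacer\t{sp.index}\t{sp.region.start}\t{sp.region.end}"
                f"\t{sp.length}\t.\t{sp.sequence}"
            )
            name = f"Sp{sp.index}" if len(arrays) == 1 else f"array{ai}_Sp{sp.index}"
            spacer_records.append(SeqRecord(id=name, seq=sp.sequence))
    (outdir / "arrays.gff3").write_text("\n".join(gff_lines) + "\n")
    (outdir / "arrays.tsv").write_text("\n".join(tsv_rows) + "\n")
    if spacer_records:
        write_fasta(spacer_records, outdir / "spacers.fasta")
    return spacer_records


def run_all(
    genome_path: str | Path,
    targets_path: str | Path | None,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    locus_bed: str | Path | None = None,
) -> RunReport:
    """Run every stage; empty biological results are reported, not fatal."""
    config = config or PipelineConfig()
    logging.basicConfig(level=config.log_level, format="[%(name)s] %(message)s")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    checksums = {"genome": _sha256(genome_path)}
    if targets_path is not None:
        checksums["targets"] = _sha256(targets_path)
    report = RunReport(
        version=__version__,
        config=dataclasses.asdict(config),
        input_checksums=checksums,
    )

    genomes = read_fasta(genome_path)
    genome = genomes[0]
    if len(genomes) > 1:
        report.warnings.append(
            f"genome FASTA has {len(genomes)} records; stages use the first "
            f"({genome.id}) as the chromosome"
        )

    # --- stage: array detection -------------------------------------------
    arrays = find_arrays(genome, config.detector_params())
    logger.info("array_detect: %d array(s) found", len(arrays))
    report.arrays = [_array_summary(a) for a in arrays]
    spacer_records = _write_array_artifacts(arrays, outdir)

    # --- stage: spacer matching + PAM -------------------------------------
    hits_passing = []
    if targets_path is None:
        report.warnings.append("no targets file: spacer-match and PAM stages skipped")
    elif not spacer_records:
        report.warnings.append("no spacers detected: spacer-match and PAM stages skipped")
    else:
        targets = read_fasta(targets_path)
        hits = align_spacers(spacer_records, targets, config.scoring())
        report.n_hits_total = len(hits)
        hits_passing = rank_and_filter(hits, config.hq_threshold)
        report.n_hits_passing = len(hits_passing)
        logger.info(
            "spacer_match: %d hit(s), %d above HQ %.0f",
            len(hits),
            len(hits_passing),
            config.hq_threshold,
        )
        hits_to_table(hits_passing).to_csv(outdir / "hits.tsv", sep="\t", index=False)
        if hits_passing:
            flanks = extract_flanks(hits_passing, targets, config.flank_len)
            sides = {}
            for side in ("five_prime", "three_prime"):
                cons = pam_report(flanks, side, config.pam_k, config.min_base_freq)
                sides[side] = {
                    "consensus": cons.consensus,
                    "support": cons.support,
                    "k": cons.k,
                    "pfm_adjacent_first": [dict(p) for p in cons.pfm],
                    "warnings": list(cons.warnings),
                }
            report.pam = sides
            (outdir / "pam.json").write_text(json.dumps(sides, indent=2) + "\n")
            flank_rows = ["spacer_id\ttarget_id\tstrand\tfive_prime\tthree_prime"]
            for rec in flanks.records:
                flank_rows.append(
                    f"{rec.hit.spacer_id}\t{rec.hit.target_id}\t{rec.hit.strand}"
                    f"\t{rec.five_prime}\t{rec.three_prime}"
                )
            (outdir / "flanks.tsv").write_text("\n".join(flank_rows) + "\n")

    # --- stage: GC / HGT ---------------------------------------------------
    profile = sliding_gc(genome.seq, config.gc_window, config.gc_step)
    with open(outdir / "gc_profile.tsv", "w") as fh:
        fh.write("start\tgc_fraction\n")
        for s, v in zip(profile.starts, profile.values):
            fh.write(f"{s}\t{v:.6f}\n")

    if locus_bed is not None:
        locus_regions = read_bed(locus_bed)
        exclude = [a.region for a in arrays]
        locus_desc = f"user BED {locus_bed}"
    elif arrays:
        # default locus: detected array plus an upstream margin standing in
        # for the cas operon; the array itself is excluded from counting
        a = arrays[0]
        locus_regions = [
            Region(a.region.contig_id, max(0, a.region.start - config.locus_margin), a.region.end)
        ]
        exclude = [a.region]
        locus_desc = (
            f"detected array + {config.locus_margin} bp upstream margin (array excluded)"
        )
    else:
        locus_regions = []
        exclude = []
        locus_desc = "none"

    if locus_regions:
        result = locus_vs_background_test(locus_regions, genome.seq, exclude)
        report.gc_test = {
            "locus_definition": locus_desc,
            "locus_gc": result.locus_gc,
            "locus_at": result.locus_at,
            "background_gc": result.background_gc,
            "background_at": result.background_at,
            "locus_gc_pct": round(100 * result.locus_prop, 2),
            "background_gc_pct": round(100 * result.background_prop, 2),
            "p_two_tailed": result.p_two_tailed,
            "method": result.method,
            "z_p_value": result.z_p_value,
        }
        (outdir / "gc_test.json").write_text(json.dumps(report.gc_test, indent=2) + "\n")
        logger.info(
            "gc_hgt: locus %.1f%% vs genome %.1f%% GC, p = %.3g (%s)",
            100 * result.locus_prop,
            100 * result.background_prop,
            result.p_two_tailed,
            result.method,
        )
    else:
        report.warnings.append("no locus available for the GC test")

    report.to_json(outdir / "report.json")
    return report
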