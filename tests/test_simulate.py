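import numpy as np
import pytest

from crisprlocus.seqcore import bases_for_iupac, gc_counts, matches_iupac, revcomp
from crisprlocus.seqcore import fasta_string
from crisprlocus.simulate import (
    PlantedHit,
    SyntheticSpec,
    generate_dataset,
    mutate_to_identity,
)


class TestDeterminism:
    def test_same_spec_and_seed_give_identical_bytes(self):
        spec = SyntheticSpec(seed=42)
        g1, t1, _ = generate_dataset(spec)
        g2, t2, _ = generate_dataset(spec)
        assert fasta_string([g1]) == fasta_string([g2])
        assert fasta_string(t1) == fasta_string(t2)

    def test_different_seeds_differ(self):
        g1, _, _ = generate_dataset(SyntheticSpec(seed=1))
        g2, _, _ = generate_dataset(SyntheticSpec(seed=2))
        assert g1.seq != g2.seq


class TestArchitecture:
    def test_unit_and_spacer_counts(self, default_dataset):
        _, _, truth = default_dataset
        assert len(truth.repeat_regions) == 22
        assert len(truth.spacer_regions) == 21

    def test_array_tiles_without_overlap(self, default_dataset):
        _, _, truth = default_dataset
        pieces = sorted(
            list(truth.repeat_regions) + list(truth.spacer_regions),
            key=lambda r: r.start,
        )
        assert pieces[0].start == truth.array_region.start
        assert pieces[-1].end == truth.array_region.end
        for a, b in zip(pieces, pieces[1:]):
            assert a.end == b.start  # contiguous, no overlap

    def test_repeat_and_spacer_lengths(self, default_dataset):
        genome, _, truth = default_dataset
        assert all(len(r) == 36 for r in truth.repeat_regions)
        lengths = [len(r) for r in truth.spacer_regions]
        assert sorted(lengths) == sorted([30] * 19 + [29, 29])

    def test_spacers_unique_and_match_regions(self, default_dataset):
        genome, _, truth = default_dataset
        seqs = [genome.seq[r.start : r.end] for r in truth.spacer_regions]
        assert seqs == list(truth.spacer_seqs)
        assert len(set(seqs)) == len(seqs)

    def test_snp_plan_written_into_units(self, default_dataset):
        genome, _, truth = default_dataset
        dists = [
            sum(a != b for a, b in zip(genome.seq[r.start : r.end], truth.dr_consensus))
            for r in truth.repeat_regions
        ]
        assert sorted(dists) == [0] * 19 + [1, 1, 3]
        assert dists[0] == 3  # terminal unit carries the 3 SNPs


class TestComposition:
    def test_genome_gc_within_three_binomial_sd(self, default_dataset):
        genome, _, truth = default_dataset
        bg = genome.seq[: truth.locus_region.start] + genome.seq[truth.locus_region.end :]
        gc, at = gc_counts(bg)
        p = 0.665
        sd = (p * (1 - p) / (gc + at)) ** 0.5
        assert abs(gc / (gc + at) - p) <= 3 * sd

    def test_locus_gc_below_genome_gc(self, default_dataset):
        genome, _, truth = default_dataset
        lg, la = gc_counts(genome.seq[truth.locus_region.start : truth.array_region.start])
        bg, ba = gc_counts(genome.seq)
        assert lg / (lg + la) < bg / (bg + ba)


class TestPlantedHits:
    def test_pam_matches_template(self, default_dataset):
        _, _, truth = default_dataset
        for rec in truth.planted_hit_records:
            assert matches_iupac(rec.planted_pam, "WGR")

    def test_pam_adjacent_to_footprint(self, default_dataset):
        _, targets, truth = default_dataset
        by_id = {t.id: t for t in targets}
        for rec in truth.planted_hit_records:
            seq = by_id[rec.target_id].seq
            if rec.strand == "+":
                flank = seq[rec.region.end : rec.region.end + 3]
            else:
                flank = revcomp(seq[rec.region.start - 3 : rec.region.start])
            assert flank == rec.planted_pam

    def test_realized_identity_at_single_substitution_granularity(self, default_dataset):
        _, targets, truth = default_dataset
        by_id = {t.id: t for t in targets}
        for rec, req in zip(truth.planted_hit_records, SyntheticSpec().planted_hits):
            sp_len = {29, 30}
            kept = len(rec.region)
            assert abs(rec.realized_pct_cov - req.pct_cov) <= 100.0 / 29 + 1e-9
            assert abs(rec.realized_pct_id - req.pct_id) <= 100.0 / kept + 1e-9

    def test_planted_copy_has_requested_hamming_distance(self):
        # 30-nt spacer at 93 % identity -> round(0.07 * 30) = 2 substitutions
        _, targets, truth = generate_dataset(
            SyntheticSpec(seed=5, planted_hits=(PlantedHit(1, 93.0, 100.0, "+"),))
        )
        (rec,) = truth.planted_hit_records
        target = next(t for t in targets if t.id == rec.target_id)
        copy = target.seq[rec.region.start : rec.region.end]
        spacer = truth.spacer_seqs[0]
        assert sum(a != b for a, b in zip(copy, spacer)) == 2

    def test_coverage_above_100_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(
                SyntheticSpec(planted_hits=(PlantedHit(1, 100.0, 101.0, "+"),))
            )


class TestMutateToIdentity:
    def test_full_identity_unchanged(self):
        s = "ACGT" * 8
        assert mutate_to_identity(s, 100.0, 3) == s

    @pytest.mark.parametrize("pct_id,expected", [(90.0, 3), (93.0, 2), (96.7, 1)])
    def test_hamming_distance(self, pct_id, expected):
        s = "ACGTTGCAAC" * 3  # 30-mer
        out = mutate_to_identity(s, pct_id, 11)
        assert sum(a != b for a, b in zip(s, out)) == expected
        assert len(out) == len(s)
        assert set(out) <= set("ACGT")

    def test_separation_honoured(self):
        s = "A" * 30
        out = mutate_to_identity(s, 90.0, 4, protect_ends=5, min_separation=6)
        positions = [i for i, (a, b) in enumerate(zip(s, out)) if a != b]
        assert all(p >= 5 and p <= 24 for p in positions)
        assert all(b - a >= 6 for a, b in zip(positions, positions[1:]))

    def test_out_of_range_identity_rejected(self):
        with pytest.raises(ValueError):
            mutate_to_identity("ACGT", 0.0, 1)


def test_truth_json_round_trips_key_fields(tmp_path, default_dataset):
    import json

    _, _, truth = default_dataset
    p = tmp_path / "truth.json"
    truth.to_json(p)
    doc = json.loads(p.read_text())
    assert doc["dr_consensus"] == truth.dr_consensus
    assert len(doc["repeat_regions"]) == 22
    assert doc["array_region"]["start"] == truth.array_region.start
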