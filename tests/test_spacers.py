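import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprlocus.seqcore import SeqRecord, revcomp
from crisprlocus.spacers import (
    AlignmentScoring,
    align_spacer,
    align_spacers,
    hq_display,
    hq_score,
    ingest_tabular_hits,
    rank_and_filter,
)
from oracles import gotoh_local_score

# the eight (%ID, %cov) pairs of the study's high-quality hit table
TABLE_PAIRS = [
    ("Sp8", 100.0, 100.0),
    ("Sp9", 100.0, 100.0),
    ("Sp16", 100.0, 97.0),
    ("Sp13", 90.0, 100.0),
    ("Sp4", 93.0, 97.0),
    ("Sp11", 93.0, 93.0),
    ("Sp10", 93.0, 93.0),
    ("Sp20", 96.0, 86.0),
]


class TestHqScore:
    @pytest.mark.parametrize(
        "pct_id,pct_cov,full,display",
        [
            (100.0, 97.0, 97.0, 97),
            (93.0, 93.0, 86.49, 86),
            (96.0, 86.0, 82.56, 83),
            (90.0, 100.0, 90.0, 90),
            (0.0, 55.0, 0.0, 0),
        ],
    )
    def test_worked_examples(self, pct_id, pct_cov, full, display):
        hq = hq_score(pct_id, pct_cov)
        assert hq == pytest.approx(full, abs=1e-9)
        assert hq_display(hq) == display

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hq_score(101.0, 50.0)
        with pytest.raises(ValueError):
            hq_score(50.0, -1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0, 100),
    )
    def test_monotone_in_both_arguments(self, id1, id2, cov1, cov2):
        lo_id, hi_id = sorted((id1, id2))
        lo_cov, hi_cov = sorted((cov1, cov2))
        assert hq_score(hi_id, lo_cov) >= hq_score(lo_id, lo_cov)
        assert hq_score(lo_id, hi_cov) >= hq_score(lo_id, lo_cov)


def _embed(spacer: str, seed: int, mutate=None, rc=False) -> SeqRecord:
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), size=80))
    right = "".join(rng.choice(list("ACGT"), size=80))
    insert = mutate(spacer) if mutate else spacer
    if rc:
        insert = revcomp(insert)
    return SeqRecord(id="t", seq=left + insert + right)


class TestAlignSpacer:
    SPACER = SeqRecord(id="Sp1", seq="ACGGTTCAGATCCGATAAGCTTGCAACGTG")

    def test_exact_match(self):
        target = _embed(self.SPACER.seq, 1)
        (hit,) = align_spacer(self.SPACER, target)
        assert (hit.pct_id, hit.pct_cov, hit.hq) == (100.0, 100.0, 100.0)
        assert hit.strand == "+"
        assert (hit.target_region.start, hit.target_region.end) == (80, 110)

    def test_two_substitutions_full_length(self):
        def mutate(s):
            out = list(s)
            out[10] = {"A": "C"}.get(out[10], "A")
            out[20] = {"A": "C"}.get(out[20], "A")
            return "".join(out)

        target = _embed(self.SPACER.seq, 2, mutate=mutate)
        hits = align_spacer(self.SPACER, target)
        best = hits[0]
        assert best.pct_id == pytest.approx(100 * 28 / 30, abs=0.05)
        assert best.pct_cov == 100.0
        assert best.hq == pytest.approx(93.3, abs=0.05)

    def test_reverse_complement_hit(self):
        target = _embed(self.SPACER.seq, 3, rc=True)
        (hit,) = align_spacer(self.SPACER, target)
        assert hit.strand == "-"
        assert hit.pct_id == 100.0
        assert (hit.target_region.start, hit.target_region.end) == (80, 110)

    def test_strand_round_trip(self):
        # aligning against the reverse complement of the target flips the
        # strand and mirrors coordinates
        target = _embed(self.SPACER.seq, 4)
        flipped = SeqRecord(id="t", seq=revcomp(target.seq))
        (h1,) = align_spacer(self.SPACER, target)
        (h2,) = align_spacer(self.SPACER, flipped)
        assert {h1.strand, h2.strand} == {"+", "-"}
        L = len(target.seq)
        assert (h2.target_region.start, h2.target_region.end) == (
            L - h1.target_region.end,
            L - h1.target_region.start,
        )

    def test_two_hits_in_one_target(self):
        rng = np.random.default_rng(5)
        pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        target = SeqRecord(
            id="t", seq=pad(60) + self.SPACER.seq + pad(60) + self.SPACER.seq + pad(60)
        )
        hits = align_spacer(self.SPACER, target)
        perfect = [h for h in hits if h.pct_id == 100.0 and h.pct_cov == 100.0]
        assert len(perfect) == 2

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_score_agrees_with_gotoh_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 41))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 41))))
        scoring = AlignmentScoring(min_score=1.0)
        oracle = gotoh_local_score(a, b)
        hits = align_spacer(SeqRecord(id="q", seq=a), SeqRecord(id="t", seq=b), scoring)
        fwd = [h.score for h in hits if h.strand == "+"]
        if oracle >= scoring.min_score:
            assert fwd and max(fwd) == pytest.approx(oracle)
        else:
            assert not fwd


class TestIngestTabular:
    def _write(self, tmp_path, rows):
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return p

    def test_perfect_hit(self, tmp_path):
        p = self._write(
            tmp_path, [["Sp1", "tgt", 100.0, 30, 0, 0, 1, 30, 101, 130, 1e-9, 55.4]]
        )
        (hit,) = ingest_tabular_hits(p, {"Sp1": 30})
        assert hit.pct_cov == 100.0 and hit.hq == 100.0
        assert hit.strand == "+"
        assert (hit.target_region.start, hit.target_region.end) == (100, 130)

    def test_partial_coverage_hq(self, tmp_path):
        p = self._write(
            tmp_path, [["Sp1", "tgt", 93.0, 29, 2, 0, 1, 29, 101, 129, 1e-5, 40.1]]
        )
        (hit,) = ingest_tabular_hits(p, {"Sp1": 30})
        assert hit.pct_cov == pytest.approx(100 * 29 / 30, abs=0.01)
        assert hit.hq == pytest.approx(93 * (100 * 29 / 30) / 100, abs=0.05)  # ~89.9

    def test_minus_strand_coordinates(self, tmp_path):
        p = self._write(
            tmp_path, [["Sp1", "tgt", 100.0, 30, 0, 0, 1, 30, 500, 471, 1e-9, 55.4]]
        )
        (hit,) = ingest_tabular_hits(p, {"Sp1": 30})
        assert hit.strand == "-"
        assert (hit.target_region.start, hit.target_region.end) == (470, 500)

    def test_unknown_spacer_rejected(self, tmp_path):
        p = self._write(
            tmp_path, [["SpX", "tgt", 100.0, 30, 0, 0, 1, 30, 1, 30, 1e-9, 55.4]]
        )
        with pytest.raises(ValueError, match="SpX"):
            ingest_tabular_hits(p, {"Sp1": 30})

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("Sp1\ttgt\tnot_a_number\t30\t0\t0\t1\t30\t1\t30\t1e-9\t55\n")
        with pytest.raises(ValueError, match=":1"):
            ingest_tabular_hits(p, {"Sp1": 30})


class TestRankAndFilter:
    def _hits_from_pairs(self, pairs):
        from crisprlocus.seqcore import Region
        from crisprlocus.spacers import ProtospacerHit

        return [
            ProtospacerHit(
                spacer_id=sp,
                spacer_length=30,
                target_id="t",
                target_region=Region("t", 0, 30),
                strand="+",
                pct_id=pid,
                pct_cov=cov,
                n_matches=30,
                n_mismatches=0,
                n_gaps=0,
            )
            for sp, pid, cov in pairs
        ]

    def test_all_eight_table_pairs_retained(self):
        kept = rank_and_filter(self._hits_from_pairs(TABLE_PAIRS))
        assert len(kept) == 8
        assert [h.hq_display for h in kept] == sorted(
            [100, 100, 97, 90, 90, 86, 86, 83], reverse=True
        )

    def test_threshold_is_strict(self):
        hits = self._hits_from_pairs([("Sp1", 80.0, 100.0)])  # hq exactly 80
        assert rank_and_filter(hits) == []

    def test_empty_input(self):
        assert rank_and_filter([]) == []

    def test_best_per_spacer_flagged(self):
        hits = self._hits_from_pairs([("Sp1", 100.0, 100.0), ("Sp1", 95.0, 100.0)])
        kept = rank_and_filter(hits)
        assert [h.best_for_spacer for h in kept] == [True, False]


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_realized_stats_match_truth(self, seed):
        from crisprlocus.simulate import SyntheticSpec, generate_dataset

        genome, targets, truth = generate_dataset(SyntheticSpec(seed=seed))
        spacers = [
            SeqRecord(id=f"Sp{i + 1}", seq=s) for i, s in enumerate(truth.spacer_seqs)
        ]
        passing = rank_and_filter(align_spacers(spacers, targets))
        assert len(passing) == 8
        by_target = {r.target_id: r for r in truth.planted_hit_records}
        for h in passing:
            rec = by_target[h.target_id]
            assert h.strand == rec.strand
            assert (h.target_region.start, h.target_region.end) == (
                rec.region.start,
                rec.region.end,
            )
            assert h.pct_id == pytest.approx(rec.realized_pct_id, abs=1e-6)
            assert h.pct_cov == pytest.approx(rec.realized_pct_cov, abs=1e-6)
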