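import numpy as np
import pytest

from contamscreen.coverage import (
    BedGraphError,
    CoverageTrack,
    DecontamConfig,
    coverage_from_reads,
    coverage_stats,
    decontaminate,
    depth_array_to_track,
    read_bedgraph,
    scaffold_label,
    segment_report,
    write_bedgraph,
)
from contamscreen.genome import Assembly, PseudoRead, Scaffold, make_pseudoreads
from contamscreen.markers import SsuLocus
from contamscreen.taxonomy import Label, ReadLabel, UNCLASSIFIED_READ


def labelled_reads(assembly, label_for):
    reads = make_pseudoreads(assembly)
    return [(r, label_for(r)) for r in reads]


def iid_scaffold(rng, gc, length, sid):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return Scaffold(sid, "".join(rng.choice(list("ACGT"), size=length, p=p)))


FOCAL = ReadLabel(Label.FOCAL, "s1")
CONTAM = ReadLabel(Label.CONTAMINANT, "s3")


class TestSegmentReport:
    def test_all_focal_reads_give_pure_records(self):
        rng = np.random.default_rng(0)
        asm = Assembly("a", [iid_scaffold(rng, 0.5, 30_000, "sc")])
        records = segment_report(asm, labelled_reads(asm, lambda r: FOCAL))
        assert all(r.focal == pytest.approx(100.0) for r in records)

    def test_scaffolds_ordered_by_ascending_gc(self):
        rng = np.random.default_rng(1)
        asm = Assembly(
            "a",
            [iid_scaffold(rng, 0.60, 12_000, "high"), iid_scaffold(rng, 0.40, 12_000, "low")],
        )
        records = segment_report(asm, labelled_reads(asm, lambda r: FOCAL))
        assert records[0].scaffold_id == "low" and records[-1].scaffold_id == "high"

    def test_fractions_sum_to_100_under_random_labels(self):
        rng = np.random.default_rng(2)
        asm = Assembly("a", [iid_scaffold(rng, 0.5, 45_000, "sc")])
        pool = [FOCAL, CONTAM, ReadLabel(Label.UNKNOWN, "dom"), UNCLASSIFIED_READ]
        records = segment_report(
            asm, labelled_reads(asm, lambda r: pool[int(rng.integers(0, 4))])
        )
        for r in records:
            assert r.focal + r.contaminant + r.unknown + r.unclassified == pytest.approx(100.0)

    def test_boundary_read_contributes_proportionally(self):
        rng = np.random.default_rng(3)
        asm = Assembly("a", [iid_scaffold(rng, 0.5, 20_000, "sc")])
        # a single contaminant read straddling the 10 kb segment boundary
        # splits its weight 100 nt / 150 nt between the two segments
        straddler = PseudoRead("x", "sc", 9900, 10_150, asm.scaffolds[0].sequence[9900:10_150])
        pairs = [(r, FOCAL) for r in make_pseudoreads(asm)] + [(straddler, CONTAM)]
        records = segment_report(asm, pairs)
        assert len(records) == 2
        w0 = records[0].contaminant / 100.0 * (10_000 + 100)
        w1 = records[1].contaminant / 100.0 * (10_000 + 150)
        assert w0 == pytest.approx(100.0, rel=1e-6)
        assert w1 == pytest.approx(150.0, rel=1e-6)


class TestScaffoldLabel:
    def rec(self, focal, contaminant, length=10_000):
        from contamscreen.coverage import SegmentRecord

        return SegmentRecord("s", 0, length, 50.0, focal, contaminant, 0.0, 100.0 - focal - contaminant)

    def test_focal_majority(self):
        assert scaffold_label([self.rec(90, 5)]) == "FOCAL"

    def test_contaminant_majority(self):
        assert scaffold_label([self.rec(30, 45)]) == "CONTAMINANT"

    def test_nothing_classified_is_undetermined(self):
        assert scaffold_label([self.rec(0, 0)]) == "UNDETERMINED"


class TestCoverageStats:
    def recs(self, coverages, sid="s"):
        from contamscreen.coverage import SegmentRecord

        return [
            SegmentRecord(sid, i * 10_000, (i + 1) * 10_000, 50.0, 100.0, 0.0, 0.0, 0.0, cov)
            for i, cov in enumerate(coverages)
        ]

    def test_constant_depth(self):
        stats = coverage_stats(self.recs([30.0] * 6), {"s": "FOCAL"})
        assert stats.focal_median == 30.0
        assert stats.focal_iqr == 0.0
        assert stats.qcd == 0.0

    def test_single_segment(self):
        stats = coverage_stats(self.recs([42.0]), {"s": "FOCAL"})
        assert stats.focal_median == 42.0 and stats.focal_iqr == 0.0

    def test_two_class_separation(self):
        records = self.recs([68.0] * 5, "f") + self.recs([26.0] * 5, "c")
        stats = coverage_stats(records, {"f": "FOCAL", "c": "CONTAMINANT"})
        assert stats.focal_median == 68.0 and stats.contaminant_median == 26.0

    def test_missing_coverage_rejected(self):
        recs = self.recs([30.0])
        recs[0].coverage = None
        with pytest.raises(ValueError):
            coverage_stats(recs, {"s": "FOCAL"})


class TestBedGraph:
    def test_round_trip(self, tmp_path):
        track = CoverageTrack({"sc": [(0, 100, 5.0), (100, 250, 7.0)]})
        p = tmp_path / "cov.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p)
        assert back.intervals == track.intervals

    def test_interval_beyond_scaffold_rejected(self, tmp_path):
        asm = Assembly("a", [Scaffold("sc", "ACGT" * 25)])
        p = tmp_path / "bad.bedgraph"
        p.write_text("sc\t0\t200\t3\n")
        with pytest.raises(BedGraphError, match=":1"):
            read_bedgraph(p, asm)

    def test_three_columns_rejected(self, tmp_path):
        p = tmp_path / "cols.bedgraph"
        p.write_text("sc\t0\t100\n")
        with pytest.raises(BedGraphError, match=":1"):
            read_bedgraph(p)

    def test_depth_array_collapse(self):
        arr = np.array([0, 0, 2, 2, 2, 1], dtype=float)
        track = depth_array_to_track({"sc": arr})
        assert track.intervals["sc"] == [(0, 2, 0.0), (2, 5, 2.0), (5, 6, 1.0)]
        assert track.mean_depth("sc", 0, 6) == pytest.approx(arr.mean())


class TestNaiveMapper:
    def test_uniform_depth_recovered_within_5_percent(self):
        rng = np.random.default_rng(6)
        scaffold = iid_scaffold(rng, 0.5, 20_000, "sc")
        asm = Assembly("a", [scaffold])
        depth, rl = 20, 100
        n = depth * len(scaffold) // rl
        reads = []
        for i in range(n):
            s = int(rng.integers(0, len(scaffold) - rl + 1))
            reads.append((f"r{i}", scaffold.sequence[s : s + rl]))
        track = coverage_from_reads(asm, reads)
        # interior mean (edges are depleted by read-placement geometry)
        mean = track.mean_depth("sc", 500, len(scaffold) - 500)
        assert mean == pytest.approx(depth, rel=0.05)


class TestDecontaminate:
    def asm(self, rng, n=3, length=2000):
        return Assembly("a", [iid_scaffold(rng, 0.5, length, f"s{i}") for i in range(n)])

    def test_no_contaminants_is_identity(self):
        rng = np.random.default_rng(7)
        asm = self.asm(rng)
        out = decontaminate(asm, labelled_reads(asm, lambda r: FOCAL))
        assert [s.sequence for s in out.scaffolds] == [s.sequence for s in asm.scaffolds]

    def test_single_read_interval_masked_exactly(self):
        rng = np.random.default_rng(8)
        asm = self.asm(rng, n=1, length=1000)
        out = decontaminate(
            asm,
            labelled_reads(asm, lambda r: CONTAM if r.start == 250 else FOCAL),
        )
        seq = out.scaffolds[0].sequence
        assert seq[250:500] == "N" * 250
        assert "N" not in seq[:250] and "N" not in seq[500:]

    def test_mask_mode_conserves_lengths_and_count(self):
        rng = np.random.default_rng(9)
        asm = self.asm(rng)
        out = decontaminate(asm, labelled_reads(asm, lambda r: CONTAM))
        assert len(out.scaffolds) == len(asm.scaffolds)
        assert [len(s) for s in out.scaffolds] == [len(s) for s in asm.scaffolds]

    def test_drop_mode_removes_contaminant_scaffold(self):
        rng = np.random.default_rng(10)
        asm = self.asm(rng, n=2)
        out = decontaminate(
            asm,
            labelled_reads(asm, lambda r: CONTAM if r.scaffold_id == "s1" else FOCAL),
            DecontamConfig(mode="drop"),
        )
        assert [s.scaffold_id for s in out.scaffolds] == ["s0"]

    def test_unknown_reads_never_masked(self):
        rng = np.random.default_rng(11)
        asm = self.asm(rng, n=1, length=1000)
        out = decontaminate(
            asm, labelled_reads(asm, lambda r: ReadLabel(Label.UNKNOWN, "dom"))
        )
        assert "N" not in out.scaffolds[0].sequence

    def test_foreign_marker_loci_masked_when_supplied(self):
        rng = np.random.default_rng(12)
        asm = self.asm(rng, n=1, length=3000)
        locus = SsuLocus("s0", 1000, 2500, "+", None, 95.0, CONTAM)
        out = decontaminate(
            asm, labelled_reads(asm, lambda r: FOCAL), marker_hits=[locus]
        )
        seq = out.scaffolds[0].sequence
        assert seq[1000:2500] == "N" * 1500 and "N" not in seq[:1000]
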