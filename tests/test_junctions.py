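import numpy as np
import pytest

import mitorecomb as mr
from mitorecomb.core import CircularSequence, Interval
from mitorecomb.isomers import circle_sequence
from mitorecomb.junctions import (
    RepeatPair,
    SupportTable,
    build_all_path_references,
    build_path_references,
    count_spanning_reads,
    summarize_recombination,
)
from oracles import brute_force_spanning_counts


def make_genome(rng, n=6000, rep_len=100, starts=(1500, 4000)):
    seq = "".join(rng.choice(list("ACGT"), n))
    rep = "".join(rng.choice(list("ACGT"), rep_len))
    seq = seq[: starts[0]] + rep + seq[starts[0] + rep_len : starts[1]] + rep + seq[starts[1] + rep_len :]
    genome = CircularSequence("toy", seq)
    repeat = RepeatPair(
        "R1",
        Interval(starts[0], starts[0] + rep_len),
        Interval(starts[1], starts[1] + rep_len),
        rep_len,
    )
    return genome, repeat


class TestPathReferences:
    def test_reference_lengths_and_labels(self, rng):
        genome, repeat = make_genome(rng)
        refs = build_path_references(genome, repeat, flank_len=20)
        assert [r.path_label for r in refs] == ["p1", "p2", "p3", "p4"]
        assert all(len(r.seq) == 100 + 2 * 20 for r in refs)
        assert [(r.left_flank_src, r.right_flank_src) for r in refs] == [
            ("a", "a"), ("b", "b"), ("a", "b"), ("b", "a"),
        ]

    def test_second_repeat_labels_offset(self, tiny_sim):
        _, genome, repeats, _, _, _ = tiny_sim
        refs = build_all_path_references(genome, repeats, flank_len=100)
        assert [r.path_label for r in refs] == [f"p{i}" for i in range(1, 9)]
        assert {r.repeat_id for r in refs[:4]} == {"R1"}
        assert {r.repeat_id for r in refs[4:]} == {"R2"}

    def test_zero_flank_degenerate(self, rng):
        genome, repeat = make_genome(rng)
        with pytest.warns(UserWarning):
            refs = build_path_references(genome, repeat, flank_len=0)
        rep_seq = genome.fetch(repeat.copy_a)
        assert all(r.seq == rep_seq for r in refs)

    def test_native_refs_in_master_recombinant_refs_only_in_isomer_b(self, tiny_sim):
        _, genome, repeats, graph, isomers, _ = tiny_sim
        doubled = genome.seq + genome.seq
        iso_b = circle_sequence(isomers["B"].circles[0], graph, canonical=False)
        doubled_b = iso_b + iso_b
        refs = build_path_references(genome, repeats[0], flank_len=200)
        for ref in refs:
            if ref.path_label in ("p1", "p2"):
                assert ref.seq in doubled
                assert ref.seq not in doubled_b
            else:
                assert ref.seq not in doubled
                assert ref.seq in doubled_b

    def test_flank_overlap_warns(self, rng):
        genome, _ = make_genome(rng, n=3000, rep_len=100, starts=(1000, 1150))
        repeat = RepeatPair("R1", Interval(1000, 1100), Interval(1150, 1250), 100)
        with pytest.warns(UserWarning, match="overlap"):
            build_path_references(genome, repeat, flank_len=200)


class TestSpanningCounts:
    def test_empty_read_set(self, rng):
        genome, repeat = make_genome(rng)
        refs = build_path_references(genome, repeat, flank_len=50)
        tables = count_spanning_reads(refs, [])
        assert tables["R1"].counts == {"p1": 0, "p2": 0, "p3": 0, "p4": 0}

    def test_error_free_counts_match_substring_oracle(self, tiny_sim):
        _, genome, repeats, _, _, reads = tiny_sim
        refs = build_all_path_references(genome, repeats, flank_len=200)
        tables = count_spanning_reads(refs, reads, min_identity=1.0, max_end_slack=0)
        got = {}
        for t in tables.values():
            got.update(t.counts)
        assert got == brute_force_spanning_counts(refs, reads)

    def test_error_free_counts_match_truth_containment(self, tiny_sim):
        cfg, genome, repeats, _, _, reads = tiny_sim
        refs = build_all_path_references(genome, repeats, flank_len=cfg.truth_flank)
        tables = count_spanning_reads(refs, reads, min_identity=1.0)
        got = {}
        for t in tables.values():
            got.update(t.counts)
        truth = {f"p{i}": 0 for i in range(1, 9)}
        for r in reads:
            for p in r.label.junction_paths_covered:
                truth[p] += 1
        assert got == truth

    def test_monotone_in_identity(self, tiny_sim):
        _, genome, repeats, _, _, reads = tiny_sim
        refs = build_all_path_references(genome, repeats, flank_len=200)
        loose = count_spanning_reads(refs, reads, min_identity=0.85)
        strict = count_spanning_reads(refs, reads, min_identity=0.99)
        for rid in loose:
            for p in loose[rid].counts:
                assert strict[rid].counts[p] <= loose[rid].counts[p]

    def test_rotation_invariant(self, rng):
        genome, repeat = make_genome(rng)
        reads = []
        for i in range(30):
            start = int(rng.integers(0, len(genome)))
            reads.append((f"r{i}", genome.substring(start, 2000)))
        shift = 1234
        n = len(genome)
        rotated = CircularSequence("rot", genome.seq[shift:] + genome.seq[:shift])
        rot_repeat = RepeatPair(
            "R1",
            Interval((repeat.copy_a.start - shift) % n, (repeat.copy_a.end - shift) % n),
            Interval((repeat.copy_b.start - shift) % n, (repeat.copy_b.end - shift) % n),
            repeat.length,
        )
        t1 = count_spanning_reads(build_path_references(genome, repeat, 50), reads, min_identity=1.0)
        t2 = count_spanning_reads(build_path_references(rotated, rot_repeat, 50), reads, min_identity=1.0)
        assert t1["R1"].counts == t2["R1"].counts

    def test_slack_larger_than_reference_rejected(self, rng):
        genome, repeat = make_genome(rng)
        refs = build_path_references(genome, repeat, flank_len=10)
        with pytest.raises(ValueError):
            count_spanning_reads(refs, [], max_end_slack=100)


def table_from_counts(repeat_id, counts):
    return SupportTable(
        repeat_id,
        {p: [f"x{i}" for i in range(k)] for p, k in counts.items()},
        min_identity=0.8,
        max_end_slack=0,
    )


class TestSummary:
    def test_study_like_counts_active_fraction(self):
        # four supported paths with recombinant minority: 37 of 87
        table = table_from_counts("R1", {"p1": 27, "p2": 23, "p3": 23, "p4": 14})
        s = summarize_recombination(table)
        assert s.status == "active"
        assert s.recombinant_fraction == pytest.approx(37 / 87)
        assert s.majority_conformation == "native"
        assert s.ci_low < 37 / 87 < s.ci_high

    def test_inactive_zero_fraction(self):
        s = summarize_recombination(table_from_counts("R1", {"p1": 10, "p2": 10, "p3": 0, "p4": 0}))
        assert s.status == "inactive"
        assert s.recombinant_fraction == 0.0

    def test_all_zero_is_no_coverage(self):
        s = summarize_recombination(table_from_counts("R1", {"p1": 0, "p2": 0, "p3": 0, "p4": 0}))
        assert s.status == "no coverage"
        assert s.recombinant_fraction is None
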