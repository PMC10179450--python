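import numpy as np
import pytest

import mitorecomb as mr
from mitorecomb.core import circular_substring, gc_content, reverse_complement
from mitorecomb.isomers import circle_sequence
from mitorecomb.repeats import find_dispersed_repeats
from mitorecomb.simulate import ConfigError, SimulationConfig, _source_circles


class TestMasterGenome:
    def test_exact_length_and_planted_repeats(self):
        cfg = SimulationConfig(genome_length=100_000, repeat_lengths=(5000, 3000), seed=3)
        genome, repeats, graph = mr.generate_master_genome(cfg)
        assert len(genome) == 100_000
        assert [rp.length for rp in repeats] == [5000, 3000]
        for rp in repeats:
            a = genome.fetch(rp.copy_a)
            b = genome.fetch(rp.copy_b)
            assert a == b  # planted copies are 100% identical

    def test_gc_within_half_point_of_target(self):
        cfg = SimulationConfig(genome_length=100_000, repeat_lengths=(5000, 3000), seed=3)
        genome, _, _ = mr.generate_master_genome(cfg)
        assert abs(gc_content(genome) - 44.05) < 0.5

    def test_repeat_finder_recovers_planted_pairs(self):
        cfg = SimulationConfig(genome_length=100_000, repeat_lengths=(5000, 3000), seed=3)
        genome, repeats, _ = mr.generate_master_genome(cfg)
        found = find_dispersed_repeats(genome, min_len=2500, max_mismatch=0, max_evalue=None)
        forward = [r for r in found if r.kind == "forward"]
        for rp in repeats:
            hits = [
                r
                for r in forward
                if r.interval_a.start <= rp.copy_a.start
                and r.interval_a.end >= rp.copy_a.end
                and r.interval_b.start <= rp.copy_b.start
                and r.interval_b.end >= rp.copy_b.end
            ]
            assert hits, f"planted repeat {rp.id} not recovered"

    def test_zero_repeats_degenerate(self):
        cfg = SimulationConfig(genome_length=5000, repeat_lengths=(0, 0), seed=1)
        genome, repeats, graph = mr.generate_master_genome(cfg)
        assert len(genome) == 5000
        assert repeats == []

    def test_infeasible_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome_length=10_000, repeat_lengths=(3000, 2000)).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(error_rate=1.5).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(isomer_weights=(0, 0, 0, 0)).validate()

    def test_determinism(self):
        cfg = SimulationConfig(genome_length=30_000, repeat_lengths=(1500, 1000), n_reads=20, seed=9)
        run1 = mr.simulate(cfg)
        run2 = mr.simulate(cfg)
        assert run1[0].seq == run2[0].seq
        assert [r.seq for r in run1[4]] == [r.seq for r in run2[4]]
        cfg2 = SimulationConfig(genome_length=30_000, repeat_lengths=(1500, 1000), n_reads=20, seed=10)
        assert mr.simulate(cfg2)[0].seq != run1[0].seq


class TestIsomerDerivation:
    def test_four_isomers_with_expected_classes(self, tiny_sim):
        _, _, _, _, isomers, _ = tiny_sim
        assert sorted(isomers) == ["A", "B", "C", "D"]
        assert isomers["A"].classification == "master"
        assert isomers["B"].classification == "master"
        assert isomers["C"].classification == "sub_circle_pair"
        assert isomers["D"].classification == "sub_circle_pair"
        assert isomers["B"].recombined_at == frozenset({"R1", "R2"})
        assert isomers["C"].recombined_at == frozenset({"R1"})

    def test_single_repeat_two_isomers(self):
        cfg = SimulationConfig(genome_length=10_000, repeat_lengths=(500, 0), seed=2)
        genome, repeats, graph = mr.generate_master_genome(cfg)
        isomers = mr.derive_isomers(genome, repeats, graph)
        assert sorted(isomers) == ["A", "C"]
        assert isomers["C"].classification == "sub_circle_pair"

    def test_sequence_content_conserved(self, tiny_sim):
        _, genome, _, graph, isomers, _ = tiny_sim
        master_multiset = isomers["A"].segment_multiset()
        for iso in isomers.values():
            assert iso.segment_multiset() == master_multiset
            assert sum(iso.circle_lengths(graph)) == len(genome)

    def test_master_circle_equals_input_genome(self, tiny_sim):
        _, genome, _, graph, isomers, _ = tiny_sim
        seq = circle_sequence(isomers["A"].circles[0], graph, canonical=False)
        # same circle: identical after rotation to the genome's origin
        assert len(seq) == len(genome)
        assert seq in genome.seq + genome.seq


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, tiny_sim):
        cfg, _, _, graph, isomers, reads = tiny_sim
        circles = {
            c.label: c.seq
            for circs in _source_circles(isomers, graph, [], cfg.truth_flank).values()
            for c in circs
        }
        # rebuild with repeats to get labels right
        for r in list(reads)[:40]:
            lab = r.label
            src = circles[lab.source_isomer]
            g = mr.CircularSequence(lab.source_isomer, src)
            expected = circular_substring(
                g, lab.source_interval.start, lab.source_interval.span(len(src))
            )
            if lab.source_interval.strand == "-":
                expected = reverse_complement(expected)
            assert r.seq == expected

    def test_mean_length_close_to_configured(self):
        cfg = SimulationConfig(
            genome_length=150_000,
            repeat_lengths=(4000, 3000),
            n_reads=1000,
            seed=5,
        )
        genome, repeats, graph = mr.generate_master_genome(cfg)
        isomers = mr.derive_isomers(genome, repeats, graph)
        reads = mr.simulate_reads(isomers, graph, repeats, cfg)
        assert abs(reads.mean_length() - 17_520) / 17_520 < 0.10

    def test_pure_master_mixture_excludes_recombinant_paths(self):
        cfg = SimulationConfig(
            genome_length=20_000,
            repeat_lengths=(1000, 800),
            read_mean_length=5_000,
            read_length_sd=1_000,
            n_reads=120,
            error_rate=0.0,
            isomer_weights=(1, 0, 0, 0),
            truth_flank=200,
            seed=13,
        )
        genome, repeats, graph, isomers, reads = mr.simulate(cfg)
        assert {r.label.source_isomer for r in reads} == {"A"}
        covered = {p for r in reads for p in r.label.junction_paths_covered}
        assert covered <= {"p1", "p2", "p5", "p6"}
        refs = mr.build_all_path_references(genome, repeats, flank_len=cfg.truth_flank)
        tables = mr.count_spanning_reads(refs, reads, min_identity=1.0)
        for table in tables.values():
            for path, ids in table.read_ids.items():
                if path in ("p3", "p4", "p7", "p8"):
                    assert ids == []

    def test_weight_on_missing_isomer_rejected(self):
        cfg = SimulationConfig(
            genome_length=10_000, repeat_lengths=(500, 0), isomer_weights=(0, 1, 0, 0), n_reads=5
        )
        genome, repeats, graph = mr.generate_master_genome(cfg)
        isomers = mr.derive_isomers(genome, repeats, graph)
        with pytest.raises(ConfigError):
            mr.simulate_reads(isomers, graph, repeats, cfg)
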