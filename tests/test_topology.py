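"""Topology calling: end overlap, spanning read pairs, verdicts."""
import numpy as np
import pytest

from mge_scout import (
    AnnotatedReplicon,
    ReadPairLink,
    TopologyParams,
    call_topology,
    count_spanning_pairs,
    detect_end_overlap,
    generate_circular_plasmid,
    generate_linear_plasmid,
)

from conftest import random_seq


def brute_force_overlap(seq, min_overlap, max_overlap):
    n = len(seq)
    best = 0
    for L in range(min_overlap, min(max_overlap, n // 2) + 1):
        if seq[:L] == seq[n - L:] and "N" not in seq[:L]:
            best = L
    return best


class TestEndOverlap:
    def test_constructed_redundancy(self):
        rng = np.random.Generator(np.random.PCG64(42))
        y = random_seq(rng, 800)
        z = random_seq(rng, 600)
        seq = y + z + y[:127]
        assert detect_end_overlap(seq, 20, 2000) == 127

    def test_no_overlap_in_random_sequence(self):
        rng = np.random.Generator(np.random.PCG64(43))
        seq = random_seq(rng, 1500)
        assert detect_end_overlap(seq, 20, 2000) == brute_force_overlap(
            seq, 20, 2000
        ) == 0

    def test_matches_brute_force(self):
        """Exact agreement with direct prefix/suffix enumeration,
        including engineered and chance overlaps."""
        for seed in range(8):
            rng = np.random.Generator(np.random.PCG64(200 + seed))
            core = random_seq(rng, int(rng.integers(500, 3000)))
            ov = int(rng.integers(0, 300))
            seq = core + core[:ov] if ov else core
            assert detect_end_overlap(seq, 20, 2000) == brute_force_overlap(
                seq, 20, 2000
            )

    def test_generator_contract(self):
        rep, links, truth = generate_circular_plasmid(
            6000, end_overlap=77, seed=9
        )
        assert detect_end_overlap(rep.sequence, 20, 2000) == 77

    def test_min_overlap_floor(self):
        with pytest.raises(ValueError):
            detect_end_overlap("ACGT" * 100, min_overlap=10)


class TestSpanningPairs:
    def setup_method(self):
        rng = np.random.Generator(np.random.PCG64(7))
        self.rep = AnnotatedReplicon("c1", random_seq(rng, 4000))

    def test_empty_links(self):
        assert count_spanning_pairs(self.rep, [], 500) == 0

    def test_generator_contract(self):
        rep, links, truth = generate_circular_plasmid(
            8000, end_overlap=77, n_spanning_pairs=30, seed=21
        )
        assert count_spanning_pairs(rep, links, 500) == 30

    def test_same_end_does_not_count(self):
        links = [
            ReadPairLink("p1", "c1", 10, "-", 100, "+"),   # both left
            ReadPairLink("p2", "c1", 3950, "+", 3990, "+"),  # both right
        ]
        assert count_spanning_pairs(self.rep, links, 500) == 0

    def test_wrong_orientation_filtered(self):
        links = [ReadPairLink("p", "c1", 10, "+", 3990, "-")]
        assert count_spanning_pairs(self.rep, links, 500) == 0
        links = [ReadPairLink("p", "c1", 10, "-", 3990, "+")]
        assert count_spanning_pairs(self.rep, links, 500) == 1
        # mate order in the file is irrelevant
        links = [ReadPairLink("p", "c1", 3990, "+", 10, "-")]
        assert count_spanning_pairs(self.rep, links, 500) == 1

    def test_other_contig_ignored(self):
        links = [ReadPairLink("p", "other", 10, "-", 3990, "+")]
        assert count_spanning_pairs(self.rep, links, 500) == 0


class TestCallTopology:
    def test_circular_both_channels(self):
        rep, links, truth = generate_circular_plasmid(
            9000, end_overlap=77, n_spanning_pairs=30, seed=3
        )
        call = call_topology(rep, links)
        assert call.verdict == "circular"
        assert call.end_overlap_bp == 77
        assert call.spanning_pairs == 30

    def test_linear_with_tir(self):
        rep, truth = generate_linear_plasmid(9000, 145, seed=4)
        call = call_topology(rep, None)
        assert call.verdict == "linear"
        assert call.tir is not None and call.tir.length_bp == 145

    def test_unresolved_without_evidence(self):
        rng = np.random.Generator(np.random.PCG64(55))
        rep = AnnotatedReplicon("r", random_seq(rng, 5000))
        call = call_topology(rep, None)
        assert call.verdict == "unresolved"
        assert call.end_overlap_bp == 0 and call.spanning_pairs == 0
        assert call.tir is None

    def test_conflict_goes_circular_with_note(self):
        """A TIR alongside strong circular evidence: physical read
        evidence wins, conflict recorded."""
        rep, truth = generate_linear_plasmid(6000, 100, seed=6)
        links = [
            ReadPairLink(f"p{i}", rep.id, 10 + i, "-", 5980 - i, "+")
            for i in range(5)
        ]
        call = call_topology(rep, links)
        assert call.verdict == "circular"
        assert any("conflict" in note for note in call.evidence_notes)


class TestPlantedTruthSuite:
    def test_clean_suite_zero_errors(self):
        """50 circular + 50 linear noise-free replicons: every verdict
        matches the planted truth."""
        params = TopologyParams()
        for seed in range(50):
            rep, links, truth = generate_circular_plasmid(
                3000, end_overlap=50, n_spanning_pairs=8,
                seed=10_000 + seed, end_window=300,
            )
            assert call_topology(rep, links, params).verdict == "circular"
            lrep, ltruth = generate_linear_plasmid(
                3000, 80, seed=20_000 + seed
            )
            assert call_topology(lrep, None, params).verdict == "linear"

    def test_noisy_circular_recall(self):
        """With 5% mate mispairing, circular recall stays >= 95% over 20
        seeds (a property of the default thresholds, measured here).
        Overlap evidence is disabled so the read channel is what is
        being stressed."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rep, links, truth = generate_circular_plasmid(
                4000, end_overlap=0, n_spanning_pairs=10, noise_rate=0.05,
                seed=30_000 + seed, end_window=400,
            )
            if call_topology(rep, links).verdict == "circular":
                hits += 1
        assert hits / n_seeds >= 0.95
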