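"""Feature matrix, classification cascade, and integrated-region calls."""
import itertools

import numpy as np
import pytest

from mge_scout import (
    AnnotatedReplicon,
    ElementProfile,
    FeatureRecord,
    RepeatPair,
    TopologyCall,
    build_profile,
    classify_element,
    delimit_integrated_regions,
)
from mge_scout.records import PROFILE_FLAGS
from mge_scout.simulate import TABLE_ARCHETYPES

from conftest import random_seq


def _profile(**true_flags):
    flags = {k: False for k in PROFILE_FLAGS}
    flags.update({k: True for k in true_flags})
    return ElementProfile("x", 1000, 60.0, 10, "unresolved", flags)


class TestClassification:
    def test_ice_shape(self):
        p = _profile(relaxase=1, virD4=1, virB4=1, tcpC=1, helicase=1,
                     transposase=1, t7ss=1, toxin_antitoxin=1)
        assert classify_element(p) == "putative_ICE"

    def test_conjugative_plasmid_shape(self):
        p = _profile(repA=1, relaxase=1, virD4=1, virB4=1, tcpC=1,
                     transposase=1, t7ss=1, toxin_antitoxin=1)
        assert classify_element(p) == "conjugative_plasmid"

    def test_cryptic_plasmid_repA_only(self):
        assert classify_element(_profile(repA=1)) == "cryptic_plasmid"

    def test_helicase_accepted_as_replication_marker(self):
        """A repA-less replicon with a DnaB-like helicase and an
        incomplete conjugation module (virB4 without relaxase) remains a
        cryptic plasmid rather than being promoted."""
        p = _profile(virB4=1, helicase=1, dna_polymerase=1, integrase=1,
                     transposase=1, trna_genes=1, t7ss=1, toxin_antitoxin=1)
        assert classify_element(p) == "cryptic_plasmid"

    def test_all_false_unclassified(self):
        assert classify_element(_profile()) == "unclassified"

    def test_pure_function_of_flags(self):
        """Classification depends only on the flag vector, never on the
        order flags were set."""
        flags = ["relaxase", "virB4", "transposase", "helicase"]
        results = {
            classify_element(_profile(**{k: True for k in perm}))
            for perm in itertools.permutations(flags)
        }
        assert results == {"putative_ICE"}


class TestBuildProfile:
    def test_table_archetype_flags_and_classes(self, table_suite):
        """Each of the four element archetypes reproduces its expected
        flag column and classification through the full pipeline."""
        from mge_scout import scan_replicons

        for name, (rep, links, truth) in table_suite.items():
            expected = TABLE_ARCHETYPES[name]
            result = scan_replicons([rep], links or None)
            profile = result.profiles[0]
            want = set(expected["flags"])
            got = {k for k, v in profile.flags.items() if v}
            assert got == want, name
            assert profile.classification == expected["classification"], name
            assert profile.topology == expected["topology"], name

    def test_empty_feature_list_all_false(self):
        rng = np.random.Generator(np.random.PCG64(2))
        rep = AnnotatedReplicon("e", random_seq(rng, 500))
        topo = TopologyCall("e", "unresolved")
        profile = build_profile(rep, topo, [])
        assert not any(profile.flags.values())
        assert profile.classification == "unclassified"

    def test_ta_requires_adjacency(self):
        rng = np.random.Generator(np.random.PCG64(3))
        seq = random_seq(rng, 20_000)
        toxin = FeatureRecord(100, 400, "+", "CDS", "toxin", {"Toxin"})
        anti_far = FeatureRecord(15_000, 15_300, "+", "CDS", "antitoxin",
                                 {"Antitoxin"})
        fillers = [
            FeatureRecord(1000 + i * 1000, 1400 + i * 1000, "+", "CDS", "hyp")
            for i in range(10)
        ]
        rep = AnnotatedReplicon("t", seq, [toxin, anti_far] + fillers)
        topo = TopologyCall("t", "unresolved")
        assert not build_profile(rep, topo).flags["toxin_antitoxin"]
        anti_near = FeatureRecord(500, 800, "+", "CDS", "antitoxin",
                                  {"Antitoxin"})
        rep2 = AnnotatedReplicon("t", seq, [toxin, anti_near] + fillers)
        assert build_profile(rep2, topo).flags["toxin_antitoxin"]


def _dr(a1, a2, ln):
    return RepeatPair(a1, a1 + ln - 1, a2, a2 + ln - 1, "direct", ln, 100.0)


class TestIntegratedRegions:
    def _rep(self, feats, n=6000):
        rng = np.random.Generator(np.random.PCG64(4))
        return AnnotatedReplicon("r", random_seq(rng, n), feats)

    def test_cargo_with_adjacent_transposase(self):
        feats = [
            FeatureRecord(1000, 1800, "+", "CDS", "cargo gene"),
            FeatureRecord(3450, 4200, "+", "CDS", "IS110 transposase",
                          {"Transposase"}),
        ]
        rep = self._rep(feats)
        calls = delimit_integrated_regions(rep, [_dr(500, 3200, 100)])
        assert len(calls) == 1
        call = calls[0]
        assert (call.region_start, call.region_end) == (600, 3199)
        assert call.adjacent_transposase == 1
        assert call.cargo_summary["n_cds"] == 1

    def test_empty_region_no_call(self):
        rep = self._rep([FeatureRecord(5000, 5500, "+", "CDS", "outside")])
        assert delimit_integrated_regions(rep, [_dr(500, 3200, 100)]) == []

    def test_nested_pairs_outer_first(self):
        """Two nested DR pairs on a constructed 5 kb map: both called,
        outer (longer region) first, regions never reach into arms."""
        feats = [
            FeatureRecord(1500, 2100, "+", "CDS", "inner cargo"),
            FeatureRecord(3000, 3600, "+", "CDS", "outer-only cargo"),
        ]
        rep = self._rep(feats)
        outer = _dr(200, 4500, 120)   # region 320..4499
        inner = _dr(1000, 2500, 80)   # region 1080..2499
        calls = delimit_integrated_regions(rep, [inner, outer])
        assert len(calls) == 2
        assert (calls[0].region_start, calls[0].region_end) == (320, 4499)
        assert (calls[1].region_start, calls[1].region_end) == (1080, 2499)
        for c, dr in zip(calls, (outer, inner)):
            assert c.region_start == dr.arm1_end + 1
            assert c.region_end == dr.arm2_start - 1

    def test_low_identity_pair_ignored(self):
        rep = self._rep([FeatureRecord(1000, 1800, "+", "CDS", "cargo")])
        weak = RepeatPair(500, 599, 3200, 3299, "direct", 100, 95.0)
        assert delimit_integrated_regions(rep, [weak]) == []

    def test_transposase_beyond_adjacency_not_linked(self):
        feats = [
            FeatureRecord(1000, 1800, "+", "CDS", "cargo"),
            FeatureRecord(4800, 5400, "+", "CDS", "transposase",
                          {"Transposase"}),
        ]
        rep = self._rep(feats)
        calls = delimit_integrated_regions(rep, [_dr(500, 3200, 100)],
                                           max_adjacency=1000)
        assert len(calls) == 1
        assert calls[0].adjacent_transposase is None
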