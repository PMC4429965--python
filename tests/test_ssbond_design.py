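import numpy as np
import pytest

from ssdesign import aufaea
from ssdesign import ssbond_design as ssd
from ssdesign import synthetic_data as syn
from ssdesign.ssbond_design import (
    CandidatePair,
    DbdParams,
    TriadSpec,
    consensus,
    detect_native_bridges,
    enumerate_candidates_dbd,
    enumerate_candidates_modip,
    filter_candidates,
)


class TestNativeDetection:
    def test_planted_bridge_found_at_its_distance(self, bridged_helix):
        bridges = detect_native_bridges(bridged_helix)
        assert [b.label for b in bridges] == ["C8-C22"]
        assert bridges[0].sg_distance == pytest.approx(2.05, abs=1e-6)

    def test_no_cysteines_yields_empty_list(self, helix30):
        assert detect_native_bridges(helix30) == []

    def test_cysteine_without_sgamma_is_skipped_with_warning(self, bridged_helix, caplog):
        import copy

        s = copy.deepcopy(bridged_helix)
        res8 = s.get("A", 8)
        res8.atoms = [a for a in res8.atoms if a.name != "SG"]
        with caplog.at_level("WARNING"):
            bridges = detect_native_bridges(s)
        assert bridges == []
        assert "C8" in caplog.text

    def test_each_cysteine_joins_at_most_one_bridge(self):
        # three mutually close cysteines: greedy shortest-first pairing
        s = syn.make_structure(syn.FixtureSpec(
            length=30, planted_pairs=[(8, 22, 3.85)], native_bridges=[(8, 22)]))
        # add a third CYS whose SG sits 2.1 A from residue 8's SG
        import copy

        s = copy.deepcopy(s)
        third = s.get("A", 15)
        third.name = "CYS"
        sg8 = s.get("A", 8).atom("SG").coords
        from ssdesign.structure_io import Atom

        third.atoms.append(Atom("SG", "S", sg8 + np.array([2.1, 0, 0])))
        bridges = detect_native_bridges(s, sg_cutoff=2.3)
        members = [m for b in bridges for m in (b.res1.seqnum, b.res2.seqnum)]
        assert len(members) == len(set(members))
        assert [b.label for b in bridges] == ["C8-C22"]  # 2.05 beats 2.1, 15 left out


class TestModipEnumeration:
    def test_planted_pair_graded_a_by_direct_window_check(self, planted_helix):
        pairs = {p.label: p for p in enumerate_candidates_modip(planted_helix)}
        p = pairs["A8-A22"]
        # oracle: recompute both distances straight from the coordinates
        r8, r22 = planted_helix.get("A", 8), planted_helix.get("A", 22)
        dca = np.linalg.norm(r8.atom("CA").coords - r22.atom("CA").coords)
        dcb = np.linalg.norm(r8.atom("CB").coords - r22.atom("CB").coords)
        assert 4.4 <= dca <= 6.8 and 3.4 <= dcb <= 4.6
        assert p.modip_grade == "A"

    def test_distant_pair_absent(self, helix30):
        labels = {p.label for p in enumerate_candidates_modip(helix30)}
        # ends of the helix are tens of angstroms apart
        assert "A1-A30" not in labels

    def test_engineered_contact_is_the_only_grade_a_pair(self):
        s = syn.make_structure(syn.FixtureSpec(
            motif="hairpin", length=24, planted_pairs=[(5, 20, 3.85)]))
        grade_a = [p.label for p in enumerate_candidates_modip(s) if p.modip_grade == "A"]
        assert grade_a == ["A5-A20"]

    def test_too_small_structure_rejected(self):
        s = syn.make_structure(syn.FixtureSpec(length=3))
        with pytest.raises(ValueError, match="too small"):
            enumerate_candidates_modip(s)


class TestDbdEnumeration:
    def test_planted_ideal_pair_has_minimal_score(self, planted_helix):
        cands = enumerate_candidates_dbd(planted_helix)
        # brute-force oracle: recompute the score for every reported pair
        params = DbdParams()
        for p in cands:
            expected = (params.w_dist * (p.cb_distance - params.ideal_cb) ** 2
                        + params.w_chi3
                        * (1 + np.cos(2 * np.radians(p.chi3_est))) / 2)
            assert p.dbd_score == pytest.approx(expected, abs=1e-12)
        assert cands[0].label == "A8-A22"
        assert abs(abs(cands[0].chi3_est) - 87.0) < 10.0

    def test_pairs_reported_once_in_canonical_order(self, planted_helix):
        cands = enumerate_candidates_dbd(planted_helix)
        keys = [p.key for p in cands]
        assert len(keys) == len(set(keys))
        for p in cands:
            assert (p.res1.chain, p.res1.seqnum) < (p.res2.chain, p.res2.seqnum)

    def test_pair_beyond_window_excluded(self, helix30):
        # helix i,i+7 Cbeta pairs sit around 7-10 A, outside [3.0, 5.1]
        labels = {p.label for p in enumerate_candidates_dbd(helix30)}
        assert "A5-A12" not in labels

    def test_widening_the_window_never_removes_candidates(self, dumbbell40):
        narrow = {p.label for p in enumerate_candidates_dbd(
            dumbbell40, DbdParams(cb_window=(3.0, 4.5)))}
        wide = {p.label for p in enumerate_candidates_dbd(
            dumbbell40, DbdParams(cb_window=(3.0, 5.1)))}
        wider = {p.label for p in enumerate_candidates_dbd(
            dumbbell40, DbdParams(cb_window=(2.5, 6.0)))}
        assert narrow <= wide <= wider


def _label_pairs(labels):
    return [CandidatePair.from_labels(a, b) for a, b in labels]


class TestConsensus:
    def test_disjoint_lists_give_empty_consensus(self):
        a = _label_pairs([("A1", "G5"), ("S7", "T11")])
        b = _label_pairs([("V2", "L9")])
        assert consensus(a, b) == []

    def test_consensus_is_commutative_and_idempotent(self, dumbbell40):
        a = enumerate_candidates_modip(dumbbell40)
        b = enumerate_candidates_dbd(dumbbell40)
        ab = consensus(a, b)
        ba = consensus(b, a)
        assert [p.key for p in ab] == [p.key for p in ba]
        assert [p.key for p in consensus(a, a)] == [p.key for p in sorted(
            a, key=lambda p: (p.res1.chain, p.res1.seqnum, p.res2.seqnum))]

    def test_subset_returns_the_smaller_list(self):
        b = _label_pairs([(f"A{i}", f"G{i + 10}") for i in range(1, 8)])
        a = b[:3]
        assert {p.key for p in consensus(a, b)} == {p.key for p in a}

    def test_large_lists_sharing_eleven_labels_yield_eleven(self):
        shared = _label_pairs(aufaea.CONSENSUS_PAIRS)  # 11 pairs
        only_a = _label_pairs([(f"A{300 + i}", f"G{400 + i}") for i in range(30)])
        only_b = _label_pairs([(f"V{500 + i}", f"L{600 + i}") for i in range(58)])
        list_a = shared + only_a  # 41 pairs, DbD-sized
        list_b = shared + only_b  # 69 pairs, MODIP-sized
        assert len(consensus(list_a, list_b)) == 11


class TestFilter:
    def test_printed_worked_example_reduces_eleven_to_five(self):
        decisions = filter_candidates(
            aufaea.consensus_candidates(), aufaea.NATIVE_BRIDGES,
            triad=aufaea.TRIAD, triad_proximal=aufaea.TRIAD_PROXIMAL)
        kept = [d.pair.label for d in decisions if d.verdict == "kept"]
        assert kept == ["A24-R66", "Y80-P200", "F176-Y186", "Y122-Y125", "A126-N152"]
        rules = {d.pair.label: d.rule for d in decisions if d.verdict == "rejected"}
        assert rules == {
            "C91-C94": "native_pair",
            "C227-C234": "native_pair",
            "D93-A167": "near_native",
            "C94-F168": "near_native",
            "W214-C234": "near_native",
            "H97-Y100": "triad_proximity",
        }

    def test_native_pair_rule_fires_first(self):
        decisions = filter_candidates(
            _label_pairs([("C91", "C94")]), aufaea.NATIVE_BRIDGES)
        assert decisions[0].verdict == "rejected"
        assert decisions[0].rule == "native_pair"

    def test_empty_input_empty_output(self):
        assert filter_candidates([], aufaea.NATIVE_BRIDGES) == []

    def test_decisions_partition_the_input(self):
        pairs = aufaea.consensus_candidates()
        decisions = filter_candidates(pairs, aufaea.NATIVE_BRIDGES,
                                      triad=aufaea.TRIAD,
                                      triad_proximal=aufaea.TRIAD_PROXIMAL)
        assert len(decisions) == len(pairs)
        assert [d.pair.key for d in decisions] == [p.key for p in pairs]
        kept = [d for d in decisions if d.verdict == "kept"]
        rejected = [d for d in decisions if d.verdict == "rejected"]
        assert len(kept) + len(rejected) == len(pairs)
        # no native-bridge cysteine ever appears in a kept pair
        native_members = {m for a, b in aufaea.NATIVE_BRIDGES
                          for m in (int(a[1:]), int(b[1:]))}
        for d in kept:
            assert d.pair.res1.seqnum not in native_members
            assert d.pair.res2.seqnum not in native_members

    def test_structure_based_triad_proximity(self, planted_helix):
        # residue 10 is spatially close to residue 8 on the same helix turn
        triad = TriadSpec(labels=("A10",), radius=6.0)
        decisions = filter_candidates(
            _label_pairs([("A8", "A22")]), [], triad=triad, structure=planted_helix)
        assert decisions[0].rule == "triad_proximity"
        assert decisions[0].distance <= 6.0
        # a generous radius of zero reach keeps the pair
        decisions = filter_candidates(
            _label_pairs([("A8", "A22")]), [],
            triad=TriadSpec(labels=("A10",), radius=0.5), structure=planted_helix)
        assert decisions[0].verdict == "kept"

    def test_missing_triad_label_is_a_configuration_error(self, planted_helix):
        with pytest.raises(ValueError, match="S133"):
            filter_candidates(_label_pairs([("A8", "A22")]), [],
                              triad=TriadSpec(labels=("S133",)), structure=planted_helix)

    def test_planted_pair_survives_end_to_end(self, planted_helix):
        """Both enumerators propose the planted ideal pair and filtering keeps it."""
        modip = enumerate_candidates_modip(planted_helix)
        dbd = enumerate_candidates_dbd(planted_helix)
        both = consensus(modip, dbd)
        assert any(p.label == "A8-A22" for p in both)
        decisions = filter_candidates(both, detect_native_bridges(planted_helix))
        verdicts = {d.pair.label: d.verdict for d in decisions}
        assert verdicts["A8-A22"] == "kept"
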