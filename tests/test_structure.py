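"""Anchor maps, inversion calling, endpoint snapping, homolog search."""

import numpy as np
import pytest

from plastocomp.records import PlastomeRecord, SequenceRecord, revcomp
from plastocomp.simulate import (
    InversionSpec,
    PlastomeSpec,
    generate_plastome,
    plant_inversion,
)
from plastocomp.structure import (
    build_anchor_map,
    detect_inversions,
    find_flanking_inverted_repeat,
    search_repeat_homolog,
)

from conftest import random_dna


@pytest.fixture(scope="module")
def inv_sim():
    spec = PlastomeSpec.scaled(
        seed=21, inversion=InversionSpec(length=3000, flank_len=164)
    )
    return generate_plastome(spec)


class TestAnchorMap:
    def test_genome_vs_itself_all_same_orientation(self):
        seq = SequenceRecord("a", random_dna(np.random.default_rng(0), 3000))
        anchors = build_anchor_map(seq, seq)
        assert anchors
        assert all(a.orientation == "same" for a in anchors)
        assert all(a.ref_pos == a.query_pos for a in anchors)

    def test_genome_vs_reverse_complement_all_inverted(self):
        seq = SequenceRecord("a", random_dna(np.random.default_rng(1), 3000))
        anchors = build_anchor_map(seq, seq.reverse_complement())
        assert anchors
        assert all(a.orientation == "inverted" for a in anchors)

    def test_small_k_rejected(self):
        seq = SequenceRecord("a", "ACGT" * 100)
        with pytest.raises(ValueError):
            build_anchor_map(seq, seq, k=9)

    def test_identity_comparison_yields_no_inversions(self):
        seq = SequenceRecord("a", random_dna(np.random.default_rng(2), 5000))
        anchors = build_anchor_map(seq, seq)
        assert detect_inversions(anchors) == []


class TestInversionCalling:
    def test_planted_inversion_recovered_exactly_after_snapping(self, inv_sim):
        donor, ref, truth = inv_sim.donor, inv_sim.record, inv_sim.truth
        inv = truth.inversion
        part = donor.partition
        anchors = build_anchor_map(donor.seq, ref.seq,
                                   ref_mask=[part.irb, part.ira])
        (call,) = detect_inversions(anchors)
        flank = find_flanking_inverted_repeat(donor.seq, call)
        assert call.snapped
        assert (call.ref_start, call.ref_end) == (inv["start"], inv["end"])
        assert flank.length == inv["flank_len"] == 164
        assert flank.pos5 == tuple(inv["flank5"])
        assert flank.pos3 == tuple(inv["flank3"])
        # repeat copies abut the snapped endpoints exactly
        assert flank.pos5[1] == call.ref_start
        assert flank.pos3[0] == call.ref_end

    def test_report_coordinates_are_one_based_inclusive(self, inv_sim):
        donor, ref, truth = inv_sim.donor, inv_sim.record, inv_sim.truth
        part = donor.partition
        anchors = build_anchor_map(donor.seq, ref.seq,
                                   ref_mask=[part.irb, part.ira])
        (call,) = detect_inversions(anchors)
        find_flanking_inverted_repeat(donor.seq, call)
        s1, e1 = call.report_coords()
        assert s1 == truth.inversion["start"] + 1
        assert e1 == truth.inversion["end"]
        # in 1-based terms the 5' copy ends at s1 - 1 and the 3' copy starts
        # at e1 + 1: the contiguous coordinates of a repeat-mediated inversion
        fl = call.flanking_repeat
        assert fl.pos5[1] == s1 - 1  # 0-based end == 1-based last base
        assert fl.pos3[0] + 1 == e1 + 1

    def test_symmetry_under_ref_query_exchange(self, inv_sim):
        donor, ref = inv_sim.donor, inv_sim.record
        part = donor.partition
        fwd = detect_inversions(build_anchor_map(donor.seq, ref.seq,
                                                 ref_mask=[part.irb, part.ira]))
        rev = detect_inversions(build_anchor_map(ref.seq, donor.seq,
                                                 ref_mask=[part.irb, part.ira]))
        assert len(fwd) == len(rev) == 1
        f_len = fwd[0].ref_end - fwd[0].ref_start
        r_len = rev[0].ref_end - rev[0].ref_start
        assert abs(f_len - r_len) < 500  # same event, anchor-resolution slack

    def test_anchor_k_sweep_stable_after_snapping(self, inv_sim):
        donor, ref, truth = inv_sim.donor, inv_sim.record, inv_sim.truth
        part = donor.partition
        for k in (17, 21, 25):
            anchors = build_anchor_map(donor.seq, ref.seq, k=k,
                                       ref_mask=[part.irb, part.ira])
            (call,) = detect_inversions(anchors)
            find_flanking_inverted_repeat(donor.seq, call)
            assert (call.ref_start, call.ref_end) == (
                truth.inversion["start"], truth.inversion["end"]
            ), f"k={k}"


class TestFlankSearch:
    def test_inversion_without_flanks_returns_none(self):
        rng = np.random.default_rng(30)
        seq = random_dna(rng, 8000)
        s, e = 2000, 5000
        inverted = seq[:s] + revcomp(seq[s:e]) + seq[e:]
        ref = SequenceRecord("r", seq)
        qry = SequenceRecord("q", inverted)
        (call,) = detect_inversions(build_anchor_map(ref, qry))
        assert find_flanking_inverted_repeat(ref, call) is None
        assert not call.snapped

    def test_forty_bp_flank_with_one_mismatch(self):
        rng = np.random.default_rng(31)
        base = PlastomeRecord(seq=SequenceRecord("b", random_dna(rng, 9000)))
        donor, inverted, truth = plant_inversion(
            base, (3000, 6000), flank_len=40, flank_mismatches=1, rng=rng
        )
        (call,) = detect_inversions(build_anchor_map(donor.seq, inverted.seq))
        flank = find_flanking_inverted_repeat(donor.seq, call)
        assert flank is not None
        assert flank.length == 40
        assert flank.mismatches == 1
        assert (call.ref_start, call.ref_end) == (3000, 6000)


class TestHomologSearch:
    def test_self_hit_identity_100(self):
        rng = np.random.default_rng(40)
        genome = SequenceRecord("g", random_dna(rng, 5000))
        unit = genome.residues[1000:1164]
        hit = search_repeat_homolog(unit, genome)
        assert hit is not None
        assert hit["identity"] == 100.0
        assert hit["interval"] == (1000, 1164)
        assert hit["strand"] == "+"

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(41)
        genome = SequenceRecord("g", random_dna(rng, 5000))
        unit = revcomp(genome.residues[2000:2100])
        hit = search_repeat_homolog(unit, genome)
        assert hit["strand"] == "-"
        assert hit["interval"] == (2000, 2100)

    def test_random_genome_rarely_hits(self):
        rng = np.random.default_rng(42)
        unit = random_dna(rng, 164)
        misses = 0
        trials = 40
        for t in range(trials):
            genome = SequenceRecord("g", random_dna(np.random.default_rng(500 + t), 5000))
            if search_repeat_homolog(unit, genome) is None:
                misses += 1
        assert misses >= int(0.95 * trials)

    def test_short_unit_rejected(self):
        with pytest.raises(ValueError):
            search_repeat_homolog("ACGT", SequenceRecord("g", "ACGT" * 100))
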