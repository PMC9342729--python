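"""Repeat surveys versus brute-force oracles and constructed cases."""

import numpy as np
import pytest

from plastocomp.records import revcomp
from plastocomp.repeats import (
    DispersedParams,
    SSRParams,
    canonical_ssr_class,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
)

from conftest import random_dna
from oracles import dispersed_micro_oracle, dispersed_oracle, ssr_oracle

# background with no qualifying SSR of unit 1-6
BG = "AACCGGTT" * 30


class TestSSR:
    def test_mononucleotide_threshold(self):
        seq = BG + "T" + "A" * 10 + "C" + BG
        hits = find_ssrs(seq)
        assert [(h.motif, h.n_repeats, h.canonical_class) for h in hits] == [
            ("A", 10, "A/T")
        ]
        assert not find_ssrs(BG + "T" + "A" * 9 + "C" + BG)

    def test_interval_arithmetic(self):
        seq = BG + "T" + "AGC" * 6 + "T" + BG
        (h,) = find_ssrs(seq)
        assert h.end - h.start == 3 * 6
        assert seq[h.start : h.end] == "AGC" * 6

    @pytest.mark.parametrize(
        "motif,expected",
        [("A", "A/T"), ("AT", "AT/AT"), ("AGG", "AGG/CCT"),
         ("AAG", "AAG/CTT"), ("TTA", "AAT/ATT"), ("GA", "AG/CT")],
    )
    def test_canonical_class(self, motif, expected):
        assert canonical_ssr_class(motif) == expected

    def test_non_primitive_motifs_not_reported_as_longer_units(self):
        seq = BG + "T" + "A" * 12 + "C" + BG
        hits = find_ssrs(seq)
        assert all(h.unit == 1 for h in hits)

    def test_matches_bruteforce_oracle_on_seeded_sequences(self):
        params = SSRParams()
        for seed in range(30):
            rng = np.random.default_rng(seed)
            seq = random_dna(rng, 400)
            # plant a few runs to make the comparison non-trivial
            for motif, rep in (("A", 10), ("AT", 6), ("CTT", 5)):
                p = int(rng.integers(0, len(seq) - len(motif) * rep))
                seq = seq[:p] + motif * rep + seq[p + len(motif) * rep :]
            got = {(h.start, h.end, h.motif, h.n_repeats) for h in find_ssrs(seq, params)}
            assert got == ssr_oracle(seq, params.min_repeats_by_unit), f"seed {seed}"


class TestTandem:
    def test_exact_two_copy_unit35(self):
        rng = np.random.default_rng(12)
        unit = random_dna(rng, 35)
        seq = BG + unit * 2 + BG
        hits = find_tandem_repeats(seq)
        (h,) = [x for x in hits if x.period == 35]
        assert h.identity == 100.0
        assert h.n_copies == 2

    def test_one_mismatch_identity_34_of_35(self):
        rng = np.random.default_rng(13)
        unit = random_dna(rng, 35)
        second = list(unit)
        second[17] = {"A": "C", "C": "A", "G": "T", "T": "G"}[second[17]]
        seq = BG + unit + "".join(second) + BG
        hits = [h for h in find_tandem_repeats(seq) if h.period == 35]
        assert hits, "mismatched tandem must still be reported"
        h = hits[0]
        assert h.identity == pytest.approx(100 * 34 / 35, abs=0.5)
        assert h.identity >= 90.0

    def test_short_unit_detected_internally_but_filtered(self):
        rng = np.random.default_rng(14)
        unit = random_dna(rng, 10)
        seq = BG + unit * 3 + BG
        raw = find_tandem_repeats(seq, report_all=True)
        assert any(h.period == 10 and h.n_copies == 3 for h in raw)
        assert not [h for h in find_tandem_repeats(seq) if h.period == 10]

    def test_planted_genome_tandems_recovered(self, small_sim_plain):
        rec, truth = small_sim_plain.record, small_sim_plain.truth
        hits = find_tandem_repeats(rec.seq.residues)
        for t in truth.tandems:
            matching = [
                h for h in hits
                if h.period == t["period"]
                and min(h.end, t["end"]) - max(h.start, t["start"])
                >= 0.9 * (t["end"] - t["start"])
            ]
            assert matching, f"planted tandem {t} not recovered"


class TestDispersed:
    def test_sealed_palindromic_pair_reported_exactly_once(self, small_sim_plain):
        rec, truth = small_sim_plain.record, small_sim_plain.truth
        mask = [tuple(truth.regions["IRb"])]
        hits = find_dispersed_repeats(rec.seq.residues, mask=mask)
        got = {(h.kind, h.pos1, h.pos2, h.length, h.mismatches) for h in hits}
        want = {
            (t["kind"], tuple(t["pos1"]), tuple(t["pos2"]), t["length"],
             t["mismatches"])
            for t in truth.dispersed
        }
        # the planted tandems also show up as forward self-pairs; ignore them
        tandem_zone = [(t["start"] - 8, t["end"] + 8) for t in truth.tandems]
        got = {
            h for h in got
            if not any(z[0] <= h[1][0] and h[2][1] <= z[1] for z in tandem_zone)
        }
        assert got == want

    def test_matches_full_diagonal_oracle(self):
        params = DispersedParams()
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            seq = random_dna(rng, 500)
            unit = random_dna(rng, 34)
            p1, p2, p3 = 40, 220, 400
            seq = (seq[:p1] + unit + seq[p1 + 34 : p2] + unit
                   + seq[p2 + 34 : p3] + revcomp(unit) + seq[p3 + 34 :])
            got = {(h.kind, h.pos1, h.pos2, h.length, h.mismatches)
                   for h in find_dispersed_repeats(seq, params)}
            want = dispersed_oracle(seq, params.min_len, params.max_hamming)
            assert got == want, f"seed {seed}"

    def test_diagonal_oracle_agrees_with_micro_oracle(self):
        # validates the fast oracle itself against the definitional one
        for seed in range(4):
            rng = np.random.default_rng(seed)
            seq = random_dna(rng, 70)
            unit = random_dna(rng, 12)
            seq = seq[:10] + unit + seq[22:40] + unit + seq[52:]
            want = dispersed_micro_oracle(seq, min_len=10, h=1)
            got = dispersed_oracle(seq, min_len=10, max_hamming=1)
            impl = {
                (h.kind, h.pos1, h.pos2, h.length, h.mismatches)
                for h in find_dispersed_repeats(
                    seq, DispersedParams(min_len=10, max_hamming=1)
                )
            }
            assert got == want, f"seed {seed}"
            assert impl == want, f"seed {seed}"

    def test_hits_reextract_consistently(self, small_sim_plain):
        seq = small_sim_plain.record.seq.residues
        truth = small_sim_plain.truth
        hits = find_dispersed_repeats(seq, mask=[tuple(truth.regions["IRb"])])
        for h in hits:
            a = seq[h.pos1[0] : h.pos1[1]]
            b = seq[h.pos2[0] : h.pos2[1]]
            if h.kind == "forward":
                mm = sum(x != y for x, y in zip(a, b))
            else:
                mm = sum(x != y for x, y in zip(a, revcomp(b)))
            assert mm == h.mismatches
            assert len(a) == len(b) == h.length

    def test_mask_suppresses_ir_pair(self, small_sim_plain):
        rec, truth = small_sim_plain.record, small_sim_plain.truth
        irb = tuple(truth.regions["IRb"])
        masked = find_dispersed_repeats(rec.seq.residues, mask=[irb])
        assert not any(
            h.pos1[0] >= irb[0] and h.pos1[1] <= irb[1] for h in masked
        )

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DispersedParams(min_len=4)
        with pytest.raises(ValueError):
            DispersedParams(max_hamming=-1)
        with pytest.raises(ValueError):
            SSRParams(min_repeats_by_unit={1: 10})
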