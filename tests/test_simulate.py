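"""The synthetic-plastome generator: determinism, planted truth, the K80
divergence process, and closed-loop agreement with the detectors."""

import numpy as np
import pytest
from scipy import stats as sps

from plastocomp.io import read_genbank, write_genbank
from plastocomp.records import PlastomeRecord, SequenceRecord, revcomp
from plastocomp.simulate import (
    DivergenceSpec,
    InversionSpec,
    PlastomeSpec,
    _k80_probs,
    default_study,
    diverge_genomes,
    generate_plastome,
    plant_inversion,
)

from conftest import random_dna


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        spec = PlastomeSpec.scaled(seed=42)
        a = generate_plastome(spec)
        b = generate_plastome(PlastomeSpec.scaled(seed=42))
        assert a.record.seq.residues == b.record.seq.residues
        assert a.truth.ssrs == b.truth.ssrs
        assert a.truth.dispersed == b.truth.dispersed

    def test_different_seed_differs(self):
        a = generate_plastome(PlastomeSpec.scaled(seed=1))
        b = generate_plastome(PlastomeSpec.scaled(seed=2))
        assert a.record.seq.residues != b.record.seq.residues


class TestStructure:
    def test_ira_is_reverse_complement_of_irb(self, small_sim_plain):
        rec, truth = small_sim_plain.record, small_sim_plain.truth
        irb = rec.seq.fetch(*truth.regions["IRb"])
        ira = rec.seq.fetch(*truth.regions["IRa"])
        assert ira == revcomp(irb)

    def test_genbank_output_round_trips(self, small_sim_plain, tmp_path):
        rec = small_sim_plain.record
        path = tmp_path / "sim.gb"
        write_genbank(rec, path)
        back, report = read_genbank(path)
        assert back.seq.residues == rec.seq.residues
        assert len(back.features) == len(rec.features)
        assert not report.skipped

    def test_ir_genes_duplicated_with_copy_index(self, small_sim_plain):
        rec = small_sim_plain.record
        rrn = [f for f in rec.features if f.gene_name == "rrn23" and f.kind == "rRNA"]
        assert sorted(f.copy_index for f in rrn) == [1, 2]
        n = len(rec.seq.residues)
        tx1, tx2 = [
            "".join(
                revcomp(rec.seq.fetch(s, e)) if st == -1 else rec.seq.fetch(s, e)
                for s, e, st in f.parts
            )
            for f in rrn
        ]
        assert tx1 == tx2  # identical transcripts from the two IR copies


class TestPlantInversion:
    def test_interval_colliding_with_ir_rejected(self, small_sim_plain):
        rec = small_sim_plain.record
        lsc_end = rec.partition.lsc[1]
        with pytest.raises(ValueError, match="IR"):
            plant_inversion(rec, (lsc_end - 500, lsc_end + 500))

    def test_interval_on_feature_rejected(self, small_sim_plain):
        rec = small_sim_plain.record
        gene = next(f for f in rec.features if f.kind == "CDS")
        mid = (gene.span[0] + gene.span[1]) // 2
        with pytest.raises(ValueError, match="endpoint"):
            plant_inversion(rec, (mid, mid + 2000))

    def test_whole_lsc_minus_margins_still_detected(self):
        from plastocomp.structure import build_anchor_map, detect_inversions

        rng = np.random.default_rng(8)
        base = PlastomeRecord(seq=SequenceRecord("b", random_dna(rng, 15_000)))
        flank = 60
        s, e = flank + 5, 15_000 - flank - 5
        donor, inverted, truth = plant_inversion(
            base, (s, e), flank_len=flank, rng=rng
        )
        calls = detect_inversions(
            build_anchor_map(donor.seq, inverted.seq), min_block=1000
        )
        assert len(calls) == 1


class TestDivergence:
    def test_rate_zero_identical(self, small_sim_plain):
        base = small_sim_plain.record
        genomes, truth = diverge_genomes(
            base, DivergenceSpec(n_genomes=2, rate=0.0, indel_rate=0.0, seed=1)
        )
        for g in genomes:
            assert g.seq.residues == base.seq.residues

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            DivergenceSpec(kappa=0)

    def test_transition_transversion_ratio_within_binomial_bounds(self, small_sim_plain):
        base = small_sim_plain.record
        rate, kappa = 0.05, 2.0
        genomes, truth = diverge_genomes(
            base,
            DivergenceSpec(n_genomes=4, rate=rate, kappa=kappa,
                           indel_rate=0.0, seed=7),
        )
        p_ts, p_tv = _k80_probs(rate, kappa)
        p_ts_given_sub = p_ts / (p_ts + 2 * p_tv)
        for n_ts, n_tv in zip(truth.realized_transitions,
                              truth.realized_transversions):
            n_sub = n_ts + n_tv
            lo, hi = sps.binom.interval(0.99, n_sub, p_ts_given_sub)
            assert lo <= n_ts <= hi

    def test_ir_copies_stay_identical_after_divergence(self, small_sim_plain):
        base = small_sim_plain.record
        genomes, _ = diverge_genomes(
            base, DivergenceSpec(n_genomes=1, rate=0.03, seed=3)
        )
        g = genomes[0]
        irb = g.seq.fetch(*g.partition.irb)
        ira = g.seq.fetch(*g.partition.ira)
        assert ira == revcomp(irb)

    def test_annotations_lift_through_indels(self, small_sim_plain):
        base = small_sim_plain.record
        genomes, truth = diverge_genomes(
            base, DivergenceSpec(n_genomes=1, rate=0.0, indel_rate=0.01, seed=9)
        )
        g = genomes[0]
        assert truth.n_indels[0] > 0
        assert len(g.seq.residues) != len(base.seq.residues)
        # genes are untouched by indels: lifted transcripts identical
        for f_old, f_new in zip(base.features, g.features):
            tx_old = "".join(
                revcomp(base.seq.fetch(s, e)) if st == -1 else base.seq.fetch(s, e)
                for s, e, st in f_old.parts
            )
            tx_new = "".join(
                revcomp(g.seq.fetch(s, e)) if st == -1 else g.seq.fetch(s, e)
                for s, e, st in f_new.parts
            )
            assert tx_old == tx_new, f_old.gene_name

    def test_expected_pairwise_distance_helper(self):
        from plastocomp.simulate import DivergenceTruth

        t = DivergenceTruth([0.01, 0.02], [], [], [], [])
        assert t.expected_pairwise_d(0, 1) == pytest.approx(3.0)
        assert t.expected_pairwise_d(-1, 1, multiplier=10) == pytest.approx(20.0)


class TestStudyBundle:
    def test_bundle_is_complete_and_deterministic(self):
        a = default_study(seed=9, spec=PlastomeSpec.scaled(seed=9))
        b = default_study(seed=9, spec=PlastomeSpec.scaled(seed=9))
        assert a.reference.seq.residues == b.reference.seq.residues
        assert a.relatives[0].seq.residues == b.relatives[0].seq.residues
        assert a.hot_loci == b.hot_loci
        assert len(a.relatives) == 3
        assert a.truth.inversion is not None
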