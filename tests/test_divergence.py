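"""IGS extraction, alignment, K2p distances and ranking."""

import math

import numpy as np
import pytest

from plastocomp.divergence import (
    align_locus,
    extract_igs,
    igs_divergence_scan,
    k2p_distance,
    pairwise_alignment_score,
    rank_hypervariable,
    score_locus,
)
from plastocomp.records import (
    FeatureAnnotation,
    PlastomeRecord,
    QuadripartitePartition,
    SequenceRecord,
)

from conftest import random_dna
from oracles import gotoh_score


def _record_with_genes(spans, length=2000, junctions=None):
    rng = np.random.default_rng(55)
    feats = [
        FeatureAnnotation(name, "gene", [(s, e, 1)])
        for name, s, e in spans
    ]
    part = None
    if junctions:
        part = QuadripartitePartition(
            lsc=junctions["lsc"], irb=junctions["irb"],
            ssc=junctions["ssc"], ira=junctions["ira"],
            junctions=junctions["j"], genome_length=length,
        )
    return PlastomeRecord(
        seq=SequenceRecord("t", random_dna(rng, length)),
        features=feats, partition=part,
    )


class TestExtractIGS:
    def test_circular_adjacency_four_genes_four_loci(self):
        rec = _record_with_genes(
            [("a", 100, 300), ("b", 500, 700), ("c", 900, 1100), ("d", 1400, 1700)]
        )
        loci = extract_igs(rec)
        assert [l.name for l in loci] == ["a-b", "b-c", "c-d", "d-a"]
        # the wrap locus spans the origin
        assert loci[-1].interval == (1700, 100)
        assert len(loci[-1].sequence) == 2000 - 1700 + 100

    def test_abutting_genes_drop_locus(self):
        rec = _record_with_genes(
            [("a", 100, 300), ("b", 300, 500), ("c", 900, 1100), ("d", 1400, 1700)]
        )
        names = [l.name for l in extract_igs(rec)]
        assert "a-b" not in names and len(names) == 3

    def test_junction_spanning_locus_excluded(self):
        j = {
            "lsc": (0, 1000), "irb": (1000, 1300), "ssc": (1300, 1700),
            "ira": (1700, 2000),
            "j": {"JLB": 1000, "JSB": 1300, "JSA": 1700, "JLA": 0},
        }
        rec = _record_with_genes(
            [("a", 100, 300), ("b", 900, 980), ("c", 1050, 1100),
             ("d", 1400, 1600)],
            junctions=j,
        )
        names = [l.name for l in extract_igs(rec)]
        assert "b-c" not in names  # spans JLB at 1000
        assert "a-b" in names

    def test_exclude_interval_drops_locus(self):
        rec = _record_with_genes(
            [("a", 100, 300), ("b", 500, 700), ("c", 900, 1100), ("d", 1400, 1700)]
        )
        names = [l.name for l in extract_igs(rec, exclude=[(350, 450)])]
        assert "a-b" not in names and "b-c" in names

    def test_no_genes_is_error(self):
        rec = PlastomeRecord(seq=SequenceRecord("t", "ACGT" * 100))
        with pytest.raises(ValueError):
            extract_igs(rec)

    def test_trna_locus_names_keep_anticodon(self, small_sim_plain):
        loci = extract_igs(small_sim_plain.donor or small_sim_plain.record)
        joined = ";".join(l.name for l in loci)
        assert "trnL-UAG" in joined


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_locus({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert aln["a"] == aln["b"] == "ACGTACGT"

    def test_one_gap_example_matches_dp_oracle(self):
        score = pairwise_alignment_score("ACGT", "AGT")
        assert score == gotoh_score("ACGT", "AGT") == -7.0
        aln = align_locus({"a": "ACGT", "b": "AGT"})
        assert aln["a"] == "ACGT" and aln["b"].count("-") == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_pairwise_score_matches_oracle_on_short_strings(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(1, 11)))
        b = random_dna(rng, int(rng.integers(1, 11)))
        assert pairwise_alignment_score(a, b) == pytest.approx(gotoh_score(a, b))

    def test_progressive_alignment_preserves_residues(self):
        rng = np.random.default_rng(77)
        base = random_dna(rng, 300)
        seqs = {}
        for i in range(4):
            s = list(base)
            for p in rng.choice(300, 9, replace=False):
                s[p] = "ACGT"[rng.integers(4)]
            seqs[f"g{i}"] = "".join(s)
        seqs["g2"] = seqs["g2"][:100] + seqs["g2"][104:]  # deletion
        aln = align_locus(seqs)
        assert len({len(r) for r in aln.values()}) == 1
        for gid, row in aln.items():
            assert row.replace("-", "") == seqs[gid]

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            align_locus({"a": "ACGT", "b": ""})
        with pytest.raises(ValueError):
            align_locus({"a": "ACGT"})


class TestK2p:
    def test_identical_rows_zero(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert r.d == 0.0 and r.P == 0.0 and r.Q == 0.0

    def test_closed_form_example(self):
        # 100 sites, 10 transitions, 5 transversions -> 17.02 per 100 sites
        a = "A" * 85 + "A" * 10 + "A" * 5
        b = "A" * 85 + "G" * 10 + "C" * 5
        r = k2p_distance(a, b)
        assert (r.P, r.Q, r.n_sites) == (0.10, 0.05, 100)
        assert r.d == pytest.approx(17.02, abs=0.005)

    def test_symmetry_and_zero_iff_identical(self):
        rng = np.random.default_rng(5)
        a = random_dna(rng, 200)
        b = random_dna(rng, 200)
        ra, rb = k2p_distance(a, b), k2p_distance(b, a)
        assert ra.d == rb.d and ra.P == rb.P and ra.Q == rb.Q
        if a != b:
            assert ra.d > 0

    def test_gap_and_n_columns_excluded(self):
        r = k2p_distance("AC-GNT", "ACCGAT")
        assert r.n_sites == 4  # columns 0,1,3,5

    def test_saturation_flagged(self):
        a = "A" * 10
        b = "G" * 5 + "C" * 5  # P=0.5, Q=0.5 -> log args <= 0
        r = k2p_distance(a, b)
        assert r.saturated and r.d is None

    def test_all_gap_error(self):
        with pytest.raises(ValueError):
            k2p_distance("----", "AC-G")

    def test_reduces_to_jukes_cantor_at_equal_rates(self):
        # when each substitution type is equally likely, P = p/3, Q = 2p/3
        # and the K2p closed form collapses to the JC69 formula exactly
        for p in (0.06, 0.15, 0.30):
            n = 300
            k = int(p * n)
            ts = k // 3
            tv = k - ts  # Q = 2P requires tv == 2*ts; choose k divisible by 3
            ts, tv = k // 3, 2 * (k // 3)
            a = "A" * n
            b = ("G" * ts) + ("C" * (tv // 2)) + ("T" * (tv - tv // 2)) + "A" * (n - ts - tv)
            r = k2p_distance(a, b)
            pp = (ts + tv) / n
            jc = -0.75 * math.log(1 - 4 * pp / 3) * 100
            assert r.d == pytest.approx(jc, rel=1e-9)


class TestRanking:
    def test_identical_genomes_yield_empty_report(self):
        loci = [
            score_locus(f"l{i}", {"a": "ACGTAC" * 20, "b": "ACGTAC" * 20})
            for i in range(3)
        ]
        assert rank_hypervariable(loci, threshold=5.0) == []

    def test_no_loci_error(self):
        with pytest.raises(ValueError):
            rank_hypervariable([])

    def test_hot_locus_ranks_first_on_study_bundle(self):
        from plastocomp.simulate import PlastomeSpec, default_study

        bundle = default_study(seed=5, spec=PlastomeSpec.scaled(seed=5))
        genomes = [bundle.donor] + bundle.relatives
        inv = bundle.truth.inversion
        scored, ranked = igs_divergence_scan(
            genomes,
            partitions={g.id: g.partition for g in genomes},
            exclude={g.id: [(inv["start"], inv["end"])] for g in genomes},
        )
        assert ranked
        hottest = max(bundle.hot_loci, key=bundle.hot_loci.get)
        assert ranked[0].name == hottest
        assert ranked[0].summary_max >= ranked[0].summary_mean


class TestK2pProperties:
    """Randomized invariants of the K2p estimator."""

    from hypothesis import given, settings, strategies as st

    dna = st.text(alphabet="ACGT", min_size=20, max_size=120)

    @given(a=dna, b=dna)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        ra = k2p_distance(a, b)
        rb = k2p_distance(b, a)
        assert (ra.P, ra.Q, ra.d) == (rb.P, rb.Q, rb.d)
        assert 0 <= ra.P <= 1 and 0 <= ra.Q <= 1 and ra.P + ra.Q <= 1
        if ra.d is not None:
            assert ra.d >= 0
            # distance corrects for multiple hits: never below the raw
            # proportion of differing sites
            assert ra.d >= 100 * (ra.P + ra.Q) - 1e-9

    @given(a=dna)
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_identity_gives_zero(self, a):
        r = k2p_distance(a, a)
        assert r.d == 0.0 and not r.saturated
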