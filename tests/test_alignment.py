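"""Alignment primitives against independent exhaustive oracles."""
import math

import numpy as np
import pytest

from bathyvir.alignment import (
    estimate_evalue,
    local_align_aa,
    local_align_nt,
    maximal_exact_matches,
)
from bathyvir.records import revcomp

from conftest import random_aa, random_dna
from oracles import aa_aligner, brute_mems, nt_aligner


class TestLocalAlignNT:
    def test_exact_substring_hit(self, genome_20k):
        q = genome_20k.seq[5_000:5_100]
        h = local_align_nt(q, genome_20k.seq)[0]
        assert h.identity == 1.0 and h.align_len == 100 and h.strand == "+"
        assert genome_20k.seq[h.s_start : h.s_end] == q

    def test_reverse_complement_hit(self, genome_20k):
        q = revcomp(genome_20k.seq[7_000:7_120])
        h = local_align_nt(q, genome_20k.seq)[0]
        assert h.strand == "-" and h.identity == 1.0
        assert (h.s_start, h.s_end) == (7_000, 7_120)

    def test_planted_substitutions_give_expected_identity(self, genome_20k):
        q = list(genome_20k.seq[3_000:3_100])
        # plant 5 substitutions away from the ends so local alignment
        # cannot trim them off
        for pos in (10, 30, 50, 70, 90):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        h = local_align_nt("".join(q), genome_20k.seq)[0]
        assert h.align_len == 100 and h.identity == pytest.approx(0.95)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align_nt("", "ACGT")

    def test_score_symmetry(self):
        rng = np.random.default_rng(21)
        a, b = random_dna(rng, 200), random_dna(rng, 180)
        sa = local_align_nt(a, b)[0].score
        sb = local_align_nt(b, a)[0].score
        assert sa == sb

    def test_seeded_path_agrees_with_exact_path(self, genome_20k):
        # a read-length query against a long subject takes the seeded path;
        # force the exact path by slicing the subject around the hit
        rng = np.random.default_rng(22)
        q = list(genome_20k.seq[9_000:9_100])
        for pos in rng.integers(5, 95, 6):
            q[pos] = "ACGT"[rng.integers(0, 4)]
        q = "".join(q)
        seeded = local_align_nt(q, genome_20k.seq)[0]
        exact = local_align_nt(q, genome_20k.seq[8_500:9_700])[0]
        assert seeded.score == exact.score


class TestOracleEquivalence:
    """Seed-and-extend / exact-path scores equal Biopython's exhaustive
    local dynamic programming on seeded random pairs (both alphabets)."""

    def test_nucleotide_scores_match_exhaustive_dp(self):
        rng = np.random.default_rng(31)
        al = nt_aligner()
        for t in range(40):
            a = random_dna(rng, int(rng.integers(30, 500)))
            if t % 2:
                b = random_dna(rng, int(rng.integers(30, 500)))
            else:
                arr = list(a)
                for p in rng.integers(0, len(arr), len(arr) // 10 + 1):
                    arr[p] = "ACGT"[rng.integers(0, 4)]
                mid = len(arr) // 2
                del arr[mid : mid + 2]
                b = "".join(arr)
            mine = max(
                (h.score for h in local_align_nt(a, b) if h.strand == "+"),
                default=0.0,
            )
            assert mine == al.score(a, b)

    def test_protein_scores_match_exhaustive_dp(self):
        rng = np.random.default_rng(32)
        al = aa_aligner()
        for t in range(40):
            a = random_aa(rng, int(rng.integers(30, 400)))
            if t % 2:
                b = random_aa(rng, int(rng.integers(30, 400)))
            else:
                arr = list(a)
                for p in rng.integers(0, len(arr), len(arr) // 8 + 1):
                    arr[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
                b = "".join(arr)
            hits = local_align_aa(a, b)
            mine = hits[0].score if hits else 0.0
            assert mine == al.score(a, b)


class TestLocalAlignAA:
    def test_identical_proteins(self):
        p = random_aa(np.random.default_rng(41), 100)
        h = local_align_aa(p, p)[0]
        assert h.identity == 1.0 and h.align_len == 100

    def test_unrelated_proteins_never_reach_conserved_bar(self):
        # chance local alignments of random proteins may have high identity
        # over a few columns, but never >30% identity over >30 aligned aa
        # with E <= 0.01 simultaneously
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b = random_aa(rng, 100), random_aa(rng, 100)
            hits = local_align_aa(a, b)
            if hits:
                h = hits[0]
                assert not (
                    h.align_len > 30 and h.identity > 0.30 and h.evalue <= 0.01
                )

    def test_embedded_related_block_recovered(self):
        rng = np.random.default_rng(43)
        core = random_aa(rng, 80)
        mutated = list(core)
        for p in rng.choice(80, size=48, replace=False):  # 40% identity kept
            mutated[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
        subject = random_aa(rng, 60) + "".join(mutated) + random_aa(rng, 60)
        h = local_align_aa(core, subject)[0]
        # the hit must land on the planted block
        assert 40 <= h.s_start <= 80 and 120 <= h.s_end <= 160

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            local_align_aa("", "MKV")


class TestEvalue:
    def test_direct_evaluation(self):
        # independent arithmetic: E = K*m*n*exp(-lambda*score)
        expected = 0.1 * 100 * 1e6 * math.exp(-0.5 * 40)
        assert estimate_evalue(40, 100, 10**6, K=0.1, lam=0.5) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(2.0611536e-2, rel=1e-6)

    def test_linearity_in_database_size(self):
        e1 = estimate_evalue(30, 100, 10**6, 0.1, 0.5)
        e2 = estimate_evalue(30, 100, 2 * 10**6, 0.1, 0.5)
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_decreasing_in_score(self):
        evs = [estimate_evalue(s, 100, 10**6, 0.1, 0.5) for s in range(0, 200, 5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert estimate_evalue(10_000, 100, 10**6, 0.1, 0.5) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            estimate_evalue(10, 100, 100, K=0.0, lam=0.5)
        with pytest.raises(ValueError):
            estimate_evalue(10, 100, 100, K=0.1, lam=-1)


class TestMaximalExactMatches:
    def test_planted_55bp_copy_found(self, genome_20k):
        rng = np.random.default_rng(51)
        region = genome_20k.seq[4_000:4_055]
        b = random_dna(rng, 3_000) + region + random_dna(rng, 3_000)
        mems = maximal_exact_matches(genome_20k.seq, b, 31)
        spans = [m for m in mems if m.length >= 55
                 and m.a_start <= 4_000 and m.a_end >= 4_055]
        assert len(spans) == 1

    def test_strict_length_threshold(self):
        rng = np.random.default_rng(52)
        core = random_dna(rng, 30)
        a = random_dna(rng, 500) + core + random_dna(rng, 500)
        b = random_dna(rng, 500) + core + random_dna(rng, 500)
        long_enough = [m for m in maximal_exact_matches(a, b, 31)
                       if m.length >= 31]
        assert long_enough == []

    def test_self_match_covers_full_length(self):
        s = random_dna(np.random.default_rng(53), 800)
        mems = maximal_exact_matches(s, s, 100)
        full = [m for m in mems if m.length == 800]
        assert len(full) == 1 and full[0].strand == "+"

    def test_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(54)
        for trial in range(5):
            a = random_dna(rng, 600)
            b = random_dna(rng, 500)
            # plant shared material on both strands
            b = b[:100] + a[200:260] + b[160:300] + revcomp(a[400:450]) + b[350:]
            got = {
                (m.a_start, m.a_end, m.b_start, m.b_end, m.strand)
                for m in maximal_exact_matches(a, b, 12)
            }
            assert got == brute_mems(a, b, 12)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(55)
        a = random_dna(rng, 400)
        b = random_dna(rng, 300) + a[100:150] + random_dna(rng, 100)
        ab = {(m.a_start, m.a_end, m.b_start, m.b_end, m.strand)
              for m in maximal_exact_matches(a, b, 20)}
        ba = {(m.b_start, m.b_end, m.a_start, m.a_end, m.strand)
              for m in maximal_exact_matches(b, a, 20)}
        assert ab == ba

    def test_n_never_matches(self):
        a = "ACGTACGTACGTNACGTACGTACGT"
        mems = maximal_exact_matches(a, a, 13)
        assert not any(
            "N" in a[m.a_start : m.a_end] for m in mems
        )
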