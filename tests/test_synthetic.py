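"""Generator contracts: GC composition, planted repeats, provirus
arithmetic, and the closed-form mismatch distribution of simulated reads."""
import numpy as np
import pytest

from bathyvir.records import GeneCall, GeneCategory, gc_fraction
from bathyvir.synthetic import (
    excise_fosmid_contig,
    make_att_host,
    make_depth_community,
    make_host_with_provirus,
    make_viral_genome,
    simulate_reads,
)

from oracles import brute_border


class TestMakeViralGenome:
    def test_gc_within_binomial_bounds(self):
        g = make_viral_genome(30_000, 0.5, seed=1)
        assert len(g) == 30_000
        sd = (0.5 * 0.5 / 30_000) ** 0.5
        assert abs(g.gc - 0.5) < 3 * sd

    def test_gc_zero_gives_at_only(self):
        g = make_viral_genome(500, 0.0, seed=2)
        assert set(g.seq) <= {"A", "T"}

    def test_deterministic_under_seed(self):
        a = make_viral_genome(1_000, 0.4, seed=3)
        b = make_viral_genome(1_000, 0.4, seed=3)
        assert a.seq == b.seq

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            make_viral_genome(100, 1.5, seed=0)


class TestExciseFosmid:
    def test_planted_repeat_appears_at_both_ends(self, genome_20k):
        contig, truth = excise_fosmid_contig(genome_20k, repeat_len=60, seed=4)
        assert truth.planted_repeat_len == 60
        assert len(contig) == len(genome_20k) + 60
        assert contig.seq[:60] == contig.seq[-60:]

    def test_short_insert_has_no_planted_repeat(self, genome_20k):
        contig, truth = excise_fosmid_contig(genome_20k, insert_len=15_000, seed=5)
        assert truth.planted_repeat_len == 0
        assert len(contig) == 15_000

    def test_realized_repeat_matches_direct_comparison_oracle(self, genome_20k):
        contig, truth = excise_fosmid_contig(genome_20k, repeat_len=55, seed=6)
        assert brute_border(contig.seq) >= truth.planted_repeat_len == 55

    def test_contig_is_walk_along_the_circle(self, genome_20k):
        contig, _ = excise_fosmid_contig(genome_20k, repeat_len=0, seed=7)
        assert contig.seq in genome_20k.seq * 2

    def test_inconsistent_args_rejected(self, genome_20k):
        with pytest.raises(ValueError):
            excise_fosmid_contig(genome_20k, insert_len=len(genome_20k) + 10,
                                 repeat_len=20, seed=0)


class TestHosts:
    def test_att_host_plants_core_at_trna_end(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        host, hcalls, truth = make_att_host(8_000, 0.4, phage, calls,
                                            att_core_len=55, seed=8)
        assert len(truth.att_core) == 55
        assert truth.att_core in phage.seq and truth.att_core in host.seq
        trna = [c for c in hcalls if c.category is GeneCategory.TRNA][0]
        assert host.seq[trna.end - 55 : trna.end] == truth.att_core

    def test_provirus_duplication_arithmetic(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        host, hcalls, truth = make_host_with_provirus(
            8_000, 0.4, phage, calls, att_core_len=55, seed=9
        )
        assert len(host) == 8_000 + len(phage) + 55
        s, e = truth.provirus_coords
        # att core duplicated flanking the provirus (attL / attR)
        assert host.seq[s - 55 : s] == truth.att_core
        assert host.seq[e - 55 : e] == truth.att_core
        cats = {c.category for c in hcalls}
        assert GeneCategory.CELLULAR in cats and GeneCategory.TRNA in cats

    def test_missing_integrase_rejected(self, genome_20k):
        with pytest.raises(ValueError, match="integrase"):
            make_att_host(8_000, 0.4, genome_20k, [], att_core_len=55, seed=0)

    def test_core_below_31bp_rejected(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        with pytest.raises(ValueError):
            make_att_host(8_000, 0.4, phage, calls, att_core_len=30, seed=0)


class TestSimulateReads:
    def test_perfect_reads_are_substrings_or_revcomp(self, genome_20k):
        rs, _ = simulate_reads([genome_20k], [1.0], 50, 100, 1.0, seed=10)
        from bathyvir.records import revcomp

        doubled = genome_20k.seq
        for _, seq in rs.reads:
            assert seq in doubled or revcomp(seq) in doubled

    def test_mismatch_count_follows_binomial(self, genome_20k):
        n, L, ident = 2_000, 100, 0.90
        rs, truth = simulate_reads([genome_20k], [1.0], n, L, ident, seed=11)
        # mean mismatches per read ~ Binomial(L, 0.1): mean 10, and the
        # sample mean over n reads has SD sqrt(L*p*q/n)
        from bathyvir.alignment import local_align_nt

        # count realized substitutions against the source directly
        total_mm = 0
        for _, seq in rs.reads[:300]:
            h = local_align_nt(seq, genome_20k.seq)[0]
            total_mm += round((1 - h.identity) * h.align_len)
        mean_mm = total_mm / 300
        sd = (L * 0.1 * 0.9 / 300) ** 0.5
        # local alignment may trim terminal mismatches, biasing slightly low
        assert abs(mean_mm - 10) < 4 * sd + 0.5

    def test_empty_readset(self, genome_20k):
        rs, _ = simulate_reads([genome_20k], [1.0], 0, 100, 1.0, seed=12)
        assert len(rs) == 0 and rs.total_bases == 0

    def test_read_longer_than_source_rejected(self, genome_20k):
        with pytest.raises(ValueError):
            simulate_reads([genome_20k], [1.0], 10, len(genome_20k) + 1, 1.0,
                           seed=0)

    def test_truth_maps_every_read_to_its_source(self, genome_20k):
        other = make_viral_genome(5_000, 0.6, seed=13, contig_id="other")
        rs, truth = simulate_reads([genome_20k, other], [0.5, 0.5], 40, 100,
                                   1.0, seed=14)
        assert set(truth.source_genome_of_read) == {rid for rid, _ in rs.reads}
        assert set(truth.source_genome_of_read.values()) <= {"g20k", "other"}


class TestDepthCommunity:
    def test_mixture_mean_gc(self):
        rs, _ = make_depth_community(0.35, 0.60, 0.5, 3_000, 100, seed=15)
        gcs = [gc_fraction(s) for _, s in rs.reads]
        mean = float(np.mean(gcs))
        sd = float(np.std(gcs) / np.sqrt(len(gcs)))
        assert abs(mean - 0.475) < 4 * sd

    def test_weight_zero_is_low_gc_only(self):
        rs, truth = make_depth_community(0.35, 0.60, 0.0, 500, 100, seed=16)
        assert truth.mixture_weights == (1.0, 0.0)
        gcs = [gc_fraction(s) for _, s in rs.reads]
        assert max(gcs) < 0.55  # no high-GC component

    def test_byte_identical_under_seed(self):
        a, _ = make_depth_community(0.35, 0.60, 0.5, 100, 100, seed=17)
        b, _ = make_depth_community(0.35, 0.60, 0.5, 100, 100, seed=17)
        assert a.reads == b.reads
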