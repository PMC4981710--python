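"""att-site host prediction and CRISPR spacer search."""
import logging

import numpy as np
import pytest

from bathyvir.host_linking import find_att_links, spacer_search
from bathyvir.records import Contig, GeneCall, GeneCategory, revcomp
from bathyvir.synthetic import make_att_host, make_viral_genome

from conftest import random_dna
from oracles import brute_mems


class TestFindAttLinks:
    def test_planted_att_link_is_significant(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        host, hcalls, truth = make_att_host(
            8_000, 0.4, phage, calls, att_core_len=55, seed=141
        )
        links = find_att_links(phage, calls, [(host, hcalls)])
        sig = [l for l in links if l.significant]
        assert len(sig) == 1
        assert sig[0].match_len >= 55
        assert sig[0].trna_overlap
        assert sig[0].integrase_distance <= 5_000

    def test_30bp_core_rejected_by_strict_threshold(self, phage_with_integrase):
        # plant a 30-bp copy manually (make_att_host refuses cores < 31)
        phage, calls = phage_with_integrase
        rng = np.random.default_rng(142)
        core = phage.seq[3_100:3_130]
        # force mismatching bases at both core boundaries so the planted
        # match cannot chance-extend past 30 bp
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        left = random_dna(rng, 3_999) + flip[phage.seq[3_099]]
        right = flip[phage.seq[3_130]] + random_dna(rng, 3_999)
        host_seq = left + core + right
        host = Contig("h30", host_seq)
        trna = [GeneCall("h30", 3_950, 4_030, "+", GeneCategory.TRNA)]
        links = find_att_links(phage, calls, [(host, trna)], min_len=30)
        assert all(l.match_len > 30 for l in links)
        assert not any(l.significant for l in links)

    def test_match_without_trna_overlap_not_significant(
        self, phage_with_integrase
    ):
        phage, calls = phage_with_integrase
        rng = np.random.default_rng(143)
        core = phage.seq[3_100:3_140]  # 40 bp, near integrase
        host = Contig("h", random_dna(rng, 4_000) + core + random_dna(rng, 4_000))
        links = find_att_links(phage, calls, [(host, [])])
        assert len(links) >= 1
        assert not links[0].trna_overlap and not links[0].significant

    def test_no_integrase_means_no_significant_link(self, genome_20k):
        rng = np.random.default_rng(144)
        core = genome_20k.seq[5_000:5_055]
        host = Contig("h", random_dna(rng, 2_000) + core + random_dna(rng, 2_000))
        trna = [GeneCall("h", 1_990, 2_065, "+", GeneCategory.TRNA)]
        links = find_att_links(genome_20k, [], [(host, trna)])
        assert links and not any(l.significant for l in links)

    def test_unrelated_pair_yields_no_links(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        other = make_viral_genome(10_000, 0.5, seed=145, contig_id="unrelated")
        links = find_att_links(phage, calls, [(other, [])])
        assert links == []

    def test_link_survives_reverse_complementing_the_host(
        self, phage_with_integrase
    ):
        phage, calls = phage_with_integrase
        host, hcalls, _ = make_att_host(
            8_000, 0.4, phage, calls, att_core_len=55, seed=146
        )
        n = len(host)
        rc_host = Contig(host.id, revcomp(host.seq))
        rc_calls = [
            GeneCall(c.contig_id, n - c.end, n - c.start,
                     "-" if c.strand == "+" else "+", c.category)
            for c in hcalls
        ]
        fwd = [l for l in find_att_links(phage, calls, [(host, hcalls)])
               if l.significant]
        rev = [l for l in find_att_links(phage, calls, [(rc_host, rc_calls)])
               if l.significant]
        assert len(fwd) == len(rev) == 1
        assert fwd[0].match_len == rev[0].match_len

    def test_matches_equal_brute_force_enumeration(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        rng = np.random.default_rng(147)
        host_seq = (
            random_dna(rng, 800) + phage.seq[3_200:3_260]
            + random_dna(rng, 500) + revcomp(phage.seq[6_000:6_040])
            + random_dna(rng, 700)
        )
        host = Contig("h", host_seq)
        links = find_att_links(phage, calls, [(host, [])], min_len=30)
        got = {
            (l.match.a_start, l.match.a_end, l.match.b_start, l.match.b_end,
             l.match.strand)
            for l in links
        }
        expected = {
            m for m in brute_mems(phage.seq, host_seq, 31)
            if m[1] - m[0] > 30
        }
        assert got == expected

    def test_no_hosts_rejected(self, phage_with_integrase):
        phage, calls = phage_with_integrase
        with pytest.raises(ValueError):
            find_att_links(phage, calls, [])


class TestSpacerSearch:
    def test_planted_spacer_found_exactly(self, genome_20k):
        spacer = genome_20k.seq[8_000:8_032]
        hits = spacer_search([("sp1", spacer)], [genome_20k])
        exact = [h for h in hits if h.mismatches == 0 and h.strand == "+"]
        assert len(exact) == 1 and exact[0].position == 8_000

    def test_reverse_strand_hit(self, genome_20k):
        spacer = revcomp(genome_20k.seq[8_000:8_032])
        hits = spacer_search([("sp1", spacer)], [genome_20k])
        assert any(h.strand == "-" and h.position == 8_000 for h in hits)

    def test_random_spacer_no_hits(self, genome_20k):
        rng = np.random.default_rng(151)
        for i in range(10):
            spacer = random_dna(rng, 32)
            assert spacer_search([(f"s{i}", spacer)], [genome_20k]) == []

    def test_mismatch_budget(self, genome_20k):
        spacer = list(genome_20k.seq[8_000:8_032])
        spacer[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[5]]
        spacer[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[spacer[20]]
        spacer = "".join(spacer)
        assert spacer_search([("s", spacer)], [genome_20k], max_mismatch=0) == []
        hits = spacer_search([("s", spacer)], [genome_20k], max_mismatch=2)
        assert any(h.position == 8_000 and h.mismatches == 2 for h in hits)

    def test_short_spacer_skipped_with_warning(self, genome_20k, caplog):
        with caplog.at_level(logging.WARNING):
            hits = spacer_search([("tiny", "ACGTACGTACGT")], [genome_20k])
        assert hits == []
        assert any("tiny" in r.message for r in caplog.records)
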