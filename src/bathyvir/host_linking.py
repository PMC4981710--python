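"""Virus-host prediction by att-site exact matches and CRISPR spacers.

Site-specific integration duplicates a short core sequence: the phage
carries it as attP next to its integrase, the host as attB, usually at the
3' end of a tRNA gene. A significant link is an exact nucleotide match of
>30 bp (strict, 100% identity) between phage and host that overlaps a host
tRNA feature and lies close to the phage integrase. CRISPR spacers are
matched by ungapped scanning with a mismatch budget.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import ExactMatch, maximal_exact_matches
from .records import Contig, GeneCall, GeneCategory, revcomp

logger = logging.getLogger(__name__)


@dataclass
class HostLink:
    phage_id: str
    host_contig_id: str
    match: ExactMatch            # a = phage, b = host
    match_len: int
    trna_overlap: bool
    integrase_distance: float    # bp; inf when the phage has no integrase
    significant: bool


@dataclass
class SpacerHit:
    spacer_id: str
    genome_id: str
    position: int                # 0-based start on the forward genome
    mismatches: int
    strand: str = "+"


def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap."""
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def find_att_links(
    phage: Contig,
    phage_calls: Sequence[GeneCall],
    hosts: Sequence[tuple[Contig, Sequence[GeneCall]]],
    min_len: int = 30,
    integrase_window: int = 5000,
    require_containment: bool = False,
) -> list[HostLink]:
    """Enumerate candidate att links between one phage and host contigs.

    All maximal exact matches (both strands) strictly longer than
    ``min_len`` are scored for tRNA overlap on the host side (>= 1 bp, or
    full containment when ``require_containment``) and for distance to the
    nearest phage integrase. Links satisfying all three conditions are
    significant; results are ranked by match length, then integrase
    distance. A phage without an integrase call yields only non-significant
    links.
    """
    if not hosts:
        raise ValueError("no host contigs supplied")
    integrase_iv = [
        (c.start, c.end)
        for c in phage_calls
        if c.category is GeneCategory.INTEGRASE
    ]
    if not integrase_iv:
        logger.warning(
            "phage %s has no integrase call; no link can be significant",
            phage.id,
        )
    links: list[HostLink] = []
    for host, host_calls in hosts:
        trnas = [
            (c.start, c.end)
            for c in host_calls
            if c.category is GeneCategory.TRNA
        ]
        for m in maximal_exact_matches(phage.seq, host.seq, min_len + 1):
            if m.length <= min_len:
                continue
            host_iv = (m.b_start, m.b_end)
            if require_containment:
                overlap = any(t0 <= host_iv[0] and host_iv[1] <= t1
                              for t0, t1 in trnas)
            else:
                overlap = any(
                    _interval_distance(host_iv, t) == 0
                    and min(host_iv[1], t[1]) - max(host_iv[0], t[0]) >= 1
                    for t in trnas
                )
            if integrase_iv:
                dist = min(
                    _interval_distance((m.a_start, m.a_end), iv)
                    for iv in integrase_iv
                )
            else:
                dist = float("inf")
            links.append(
                HostLink(
                    phage_id=phage.id,
                    host_contig_id=host.id,
                    match=m,
                    match_len=m.length,
                    trna_overlap=overlap,
                    integrase_distance=dist,
                    significant=bool(
                        m.length > min_len
                        and overlap
                        and dist <= integrase_window
                    ),
                )
            )
    links.sort(key=lambda l: (-l.match_len, l.integrase_distance))
    return links


def spacer_search(
    spacers: Sequence[tuple[str, str]],
    genomes: Sequence[Contig],
    max_mismatch: int = 0,
    min_spacer_len: int = 20,
) -> list[SpacerHit]:
    """Ungapped scan of CRISPR spacers against genomes, both strands.

    Spacers shorter than ``min_spacer_len`` are skipped with a warning.
    Reported hits have at most ``max_mismatch`` substitutions over the full
    spacer length; N never matches.
    """
    hits: list[SpacerHit] = []
    for sid, spacer in spacers:
        if len(spacer) < min_spacer_len:
            logger.warning("spacer %s shorter than %d bp; skipped", sid,
                           min_spacer_len)
            continue
        L = len(spacer)
        for genome in genomes:
            g = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
            n = len(g)
            if n < L:
                continue
            for strand, sp in (("+", spacer), ("-", revcomp(spacer))):
                s = np.frombuffer(sp.encode(), dtype=np.uint8)
                mism = np.zeros(n - L + 1, dtype=np.int32)
                for k in range(L):
                    col = g[k : n - L + 1 + k]
                    mism += (col != s[k]) | (col == ord("N")) | (s[k] == ord("N"))
                for pos in np.nonzero(mism <= max_mismatch)[0]:
                    hits.append(
                        SpacerHit(
                            spacer_id=sid,
                            genome_id=genome.id,
                            position=int(pos),
                            mismatches=int(mism[pos]),
                            strand=strand,
                        )
                    )
    return hits


def links_to_frame(links: Sequence[HostLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "phage_id": [l.phage_id for l in links],
            "host_contig_id": [l.host_contig_id for l in links],
            "phage_start": [l.match.a_start for l in links],
            "phage_end": [l.match.a_end for l in links],
            "host_start": [l.match.b_start for l in links],
            "host_end": [l.match.b_end for l in links],
            "strand": [l.match.strand for l in links],
            "match_len": [l.match_len for l in links],
            "trna_overlap": [l.trna_overlap for l in links],
            "integrase_distance": [l.integrase_distance for l in links],
            "significant": [l.significant for l in links],
        }
    )
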