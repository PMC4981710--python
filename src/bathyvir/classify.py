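"""Contig classification from gene-call marker categories.

Codifies manual curation rules for fosmid contigs: a contig rich in
caudoviral structural proteins (terminase, portal, tail, capsid) is called
caudoviral; a viral gene block flanked or adjoined by consecutive tracts of
cellular genes is a provirus; a majority of eukaryotic-virus markers makes
the contig eukaryotic-viral; no viral markers at all makes it cellular.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .records import Contig, GeneCall, GeneCategory, VIRAL_CATEGORIES

#: categories that may be part of a provirus viral block: structural viral
#: genes plus the integrase and uncharacterized genes (phages carry many)
_BLOCK_CATEGORIES = VIRAL_CATEGORIES | {
    GeneCategory.INTEGRASE,
    GeneCategory.UNKNOWN,
}


@dataclass
class ClassifyParams:
    min_viral: int = 3  # viral-category genes to call a caudovirus/block
    min_flank: int = 2  # consecutive cellular genes to count as a flank
    euk_majority: float = 0.5


@dataclass
class ProvirusCall:
    contig_id: str
    viral_block: tuple[int, int]  # bp, half-open
    left_flank_cellular: int
    right_flank_cellular: int
    has_integrase: bool
    n_viral: int = 0


@dataclass
class ContigClass:
    contig_id: str
    label: str  # caudoviral | provirus | eukaryotic_viral | cellular | ambiguous
    evidence: dict = field(default_factory=dict)  # counts per gene category
    viral_block: Optional[tuple[int, int]] = None


def _check_calls(contig: Contig, gene_calls: Sequence[GeneCall]) -> list[GeneCall]:
    calls = sorted(gene_calls, key=lambda c: (c.start, c.end))
    for c in calls:
        if c.contig_id != contig.id:
            raise ValueError(
                f"gene call for {c.contig_id} given with contig {contig.id}"
            )
        if c.end > len(contig):
            raise ValueError(
                f"gene call [{c.start},{c.end}) exceeds contig {contig.id} "
                f"length {len(contig)}"
            )
    return calls


def call_provirus(
    contig: Contig,
    gene_calls: Sequence[GeneCall],
    params: Optional[ClassifyParams] = None,
) -> Optional[ProvirusCall]:
    """Find the maximal-scoring viral gene block with a cellular flank.

    Blocks are maximal runs of viral/integrase/unknown genes; the block with
    the most viral-category genes wins (ties -> leftmost). A qualifying
    block has at least ``min_viral`` viral genes and at least ``min_flank``
    consecutive cellular genes on one side.
    """
    params = params or ClassifyParams()
    calls = _check_calls(contig, gene_calls)
    if not calls:
        return None
    # maximal runs of block-compatible genes
    blocks: list[tuple[int, int]] = []  # index ranges [i, j)
    i = 0
    while i < len(calls):
        if calls[i].category in _BLOCK_CATEGORIES:
            j = i
            while j < len(calls) and calls[j].category in _BLOCK_CATEGORIES:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    best: Optional[ProvirusCall] = None
    best_key = None
    for i, j in blocks:
        n_viral = sum(1 for c in calls[i:j] if c.category in VIRAL_CATEGORIES)
        if n_viral < params.min_viral:
            continue
        left = 0
        k = i - 1
        while k >= 0 and calls[k].category is GeneCategory.CELLULAR:
            left += 1
            k -= 1
        right = 0
        k = j
        while k < len(calls) and calls[k].category is GeneCategory.CELLULAR:
            right += 1
            k += 1
        if max(left, right) < params.min_flank:
            continue
        key = (-n_viral, calls[i].start)
        if best_key is None or key < best_key:
            best_key = key
            best = ProvirusCall(
                contig_id=contig.id,
                viral_block=(calls[i].start, calls[j - 1].end),
                left_flank_cellular=left,
                right_flank_cellular=right,
                has_integrase=any(
                    c.category is GeneCategory.INTEGRASE for c in calls[i:j]
                ),
                n_viral=n_viral,
            )
    return best


def classify_contig(
    contig: Contig,
    gene_calls: Sequence[GeneCall],
    params: Optional[ClassifyParams] = None,
) -> ContigClass:
    """Assign exactly one label to a contig.

    Decision order: eukaryotic_viral -> provirus -> caudoviral -> cellular
    -> ambiguous.
    """
    params = params or ClassifyParams()
    calls = _check_calls(contig, gene_calls)
    evidence = Counter(c.category.value for c in calls)

    categorized = [c for c in calls if c.category is not GeneCategory.UNKNOWN]
    n_euk = sum(
        1 for c in categorized if c.category is GeneCategory.EUKARYOTIC_VIRAL
    )
    if categorized and n_euk / len(categorized) > params.euk_majority:
        return ContigClass(contig.id, "eukaryotic_viral", dict(evidence))

    prov = call_provirus(contig, calls, params)
    if prov is not None:
        return ContigClass(
            contig.id, "provirus", dict(evidence), viral_block=prov.viral_block
        )

    n_viral = sum(1 for c in calls if c.category in VIRAL_CATEGORIES)
    lead = 0
    for c in calls:
        if c.category is GeneCategory.CELLULAR:
            lead += 1
        else:
            break
    trail = 0
    for c in reversed(calls):
        if c.category is GeneCategory.CELLULAR:
            trail += 1
        else:
            break
    if n_viral >= params.min_viral and max(lead, trail) < params.min_flank:
        return ContigClass(contig.id, "caudoviral", dict(evidence))
    if n_viral == 0:
        return ContigClass(contig.id, "cellular", dict(evidence))
    return ContigClass(contig.id, "ambiguous", dict(evidence))


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: str, min_aa: int = 60) -> list[GeneCall]:
    """All maximal ATG->stop open reading frames in all 6 frames.

    Maximal: within each stop-delimited segment, the ORF starts at the first
    ATG. The gene span excludes the stop codon, so the protein length equals
    span/3. Coordinates are on the forward strand, half-open.
    """
    n = len(seq)
    calls: list[GeneCall] = []

    def scan(s: str, strand: str) -> None:
        for frame in range(3):
            start_atg = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    if start_atg is not None and (pos - start_atg) // 3 >= min_aa:
                        a, b = start_atg, pos  # stop excluded
                        if strand == "+":
                            start, end = a, b
                        else:
                            start, end = n - b, n - a
                        protein = str(Seq(s[a:b]).translate())
                        calls.append(
                            GeneCall(
                                contig_id="", start=start, end=end,
                                strand=strand,
                                category=GeneCategory.UNKNOWN,
                                protein=protein,
                            )
                        )
                    start_atg = None
                elif codon == "ATG" and start_atg is None:
                    start_atg = pos
    scan(seq, "+")
    from .records import revcomp

    scan(revcomp(seq), "-")
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return calls
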