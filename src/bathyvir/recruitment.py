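"""Fragment recruitment of read datasets against genomes.

Reads are aligned to each genome (seed-and-extend nucleotide alignment) and
hits pass the recruitment filter only with >95% identity, alignment length
>50 bp and E-value <1e-5, all strict. Each read contributes to at most one
genome (its best filtered hit) by default. Abundance is summarized as RPKG:
reads recruited per kilobase of genome per gigabase of dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .alignment import DEFAULT_NT_SCORING, LocalAlignmentHit, SeedIndex
from .records import Contig, ReadSet


@dataclass
class RecruitParams:
    min_identity: float = 0.95   # strict >
    min_len: int = 50            # strict >
    max_evalue: float = 1e-5     # strict <
    best_hit_only: bool = True
    scoring: tuple = DEFAULT_NT_SCORING
    k: int = 13                  # seed length
    display_min_rpkg: float = 2.0  # strict > for plot/report inclusion


@dataclass
class RecruitmentProfile:
    genome_id: str
    dataset_id: str
    n_recruited: int
    rpkg: float
    genome_len: int
    dataset_total_bases: int
    hits: list = field(default_factory=list)  # [(genome position bp, identity)]


@dataclass
class DepthClass:
    dataset_id: str
    depth_m: float
    label: str  # surface | mesopelagic | bathypelagic


def filter_hit(hit: LocalAlignmentHit, params: Optional[RecruitParams] = None) -> bool:
    """Recruitment filter; all three thresholds are strict."""
    p = params or RecruitParams()
    return (
        hit.identity > p.min_identity
        and hit.align_len > p.min_len
        and hit.evalue < p.max_evalue
    )


def compute_rpkg(n_recruited: int, genome_len: int, dataset_total_bases: int) -> float:
    """Reads per kilobase of genome per gigabase of dataset."""
    if genome_len < 1 or dataset_total_bases < 1:
        raise ValueError("genome_len and dataset_total_bases must be >= 1")
    return n_recruited / (genome_len / 1_000) / (dataset_total_bases / 1e9)


def recruit(
    reads: ReadSet,
    genomes: Sequence[Contig],
    params: Optional[RecruitParams] = None,
    indexes: Optional[dict] = None,
) -> list[RecruitmentProfile]:
    """Recruit a read dataset against a set of genomes.

    With ``best_hit_only`` each read counts toward the genome of its best
    filtered hit (highest score; ties broken by lowest genome id then lowest
    subject start); otherwise every filtered hit counts. Prebuilt
    ``indexes`` (genome_id -> SeedIndex) may be passed to amortize index
    construction across datasets.
    """
    if not genomes:
        raise ValueError("empty genome set")
    params = params or RecruitParams()
    if indexes is None:
        indexes = {}
    for g in genomes:
        if g.id not in indexes:
            indexes[g.id] = SeedIndex(g.seq, g.id, k=params.k)
    counts = {g.id: 0 for g in genomes}
    hitlists: dict[str, list] = {g.id: [] for g in genomes}
    order = sorted(g.id for g in genomes)
    for rid, seq in reads.reads:
        if len(seq) < params.k:
            continue
        candidates: list[tuple[float, str, int, LocalAlignmentHit]] = []
        for gid in order:
            for h in indexes[gid].search(seq, query_id=rid, scoring=params.scoring):
                if filter_hit(h, params):
                    candidates.append((-h.score, gid, h.s_start, h))
        if not candidates:
            continue
        if params.best_hit_only:
            candidates = [min(candidates)]
        for _, gid, _, h in candidates:
            counts[gid] += 1
            hitlists[gid].append(((h.s_start + h.s_end) // 2, h.identity))
    profiles = []
    for g in genomes:
        profiles.append(
            RecruitmentProfile(
                genome_id=g.id,
                dataset_id=reads.dataset_id,
                n_recruited=counts[g.id],
                rpkg=compute_rpkg(counts[g.id], len(g), reads.total_bases)
                if reads.total_bases > 0
                else 0.0,
                genome_len=len(g),
                dataset_total_bases=reads.total_bases,
                hits=hitlists[g.id],
            )
        )
    return profiles


def assign_depth_class(depth_m: float, dataset_id: str = "") -> DepthClass:
    """Depth partition: <500 m surface, exactly 500 m mesopelagic,
    >500 m bathypelagic."""
    if depth_m < 0:
        raise ValueError("depth must be non-negative")
    if depth_m < 500:
        label = "surface"
    elif depth_m == 500:
        label = "mesopelagic"
    else:
        label = "bathypelagic"
    return DepthClass(dataset_id=dataset_id, depth_m=depth_m, label=label)


def recruitment_plot_data(profile: RecruitmentProfile) -> list[tuple[int, float]]:
    """Plot series: one point per recruited read at its hit midpoint, with
    identity as a percentage."""
    return [(pos, ident * 100.0) for pos, ident in profile.hits]


def profiles_to_frame(profiles: Sequence[RecruitmentProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": [p.genome_id for p in profiles],
            "dataset_id": [p.dataset_id for p in profiles],
            "n_recruited": [p.n_recruited for p in profiles],
            "rpkg": [p.rpkg for p in profiles],
            "genome_len": [p.genome_len for p in profiles],
            "dataset_total_bases": [p.dataset_total_bases for p in profiles],
        }
    )
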