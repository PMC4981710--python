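"""Shared-protein-content genome comparison and grouping.

For every ordered genome pair (A, B) each A protein is aligned to B's
proteins; its best hit is conserved if the aligned region is >30 aa, the
E-value is <= 0.01 and identity is >30% (one hit per protein). The directed
conserved fraction f(A->B) = conserved(A,B) / conserved(A,A) x 100 is
symmetrized by arithmetic mean into a percentage matrix; genomes connected
at >20% (strict) form groups (single-linkage connected components).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import (
    _AA_IDENT,
    _AA_MATRIX,
    DEFAULT_AA_GAPS,
    KA_PARAMS,
    encode_aa,
    estimate_evalue,
    smith_waterman,
)


@dataclass
class ConservedHitParams:
    min_align_aa: int = 30       # strict: aligned region must be > this
    max_evalue: float = 0.01     # inclusive
    min_identity: float = 0.30   # strict
    prefilter_k: int = 4         # shared-k-mer prefilter; 0 disables
    symmetrize: str = "mean"     # mean | min | max


@dataclass
class ConservationMatrix:
    genome_ids: list[str]
    percent: np.ndarray  # square, symmetric, diagonal 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.round(self.percent, 1), index=self.genome_ids,
            columns=self.genome_ids,
        )

    def entry(self, a: str, b: str) -> float:
        ia, ib = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.percent[ia, ib])


@dataclass
class GenomePartition:
    groups: list[frozenset]
    threshold: float

    @property
    def multi_member_groups(self) -> list[frozenset]:
        return [g for g in self.groups if len(g) > 1]

    def group_of(self, genome_id: str) -> frozenset:
        for g in self.groups:
            if genome_id in g:
                return g
        raise KeyError(genome_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, members in enumerate(self.groups):
            for m in sorted(members):
                rows.append({"genome_id": m, "group_id": gi})
        return pd.DataFrame(rows)


def _kmers(p: str, k: int) -> set:
    return {p[i : i + k] for i in range(len(p) - k + 1)}


def _pair_table(
    protsA: Sequence[str], protsB: Sequence[str], params: ConservedHitParams
) -> dict[tuple[int, int], tuple[float, int, float]]:
    """Alignment stats (score, align_len, identity) for candidate protein
    pairs between two genomes. Pairs sharing no k-mer are skipped: a >30%
    identity hit over >30 aa essentially always shares a short word."""
    go, ge = DEFAULT_AA_GAPS
    k = params.prefilter_k
    encB = [encode_aa(p) for p in protsB]
    kmB = [_kmers(p, k) for p in protsB] if k else None
    out: dict[tuple[int, int], tuple[float, int, float]] = {}
    for i, pa in enumerate(protsA):
        ea = encode_aa(pa)
        ka = _kmers(pa, k) if k else None
        for j in range(len(protsB)):
            if k and not (ka & kmB[j]):
                continue
            res = smith_waterman(ea, encB[j], _AA_MATRIX, _AA_IDENT, go, ge)
            if res is None:
                continue
            score, _, _, _, _, alen, ident = res
            out[(i, j)] = (score, alen, ident / alen if alen else 0.0)
    return out


def _count_from_table(
    table, n_a: int, lens_a: Sequence[int], subject_total: int,
    params: ConservedHitParams,
) -> int:
    K, lam = KA_PARAMS["aa"]
    count = 0
    for i in range(n_a):
        best = None  # (score, j)
        for (ti, j), (score, alen, ident) in table.items():
            if ti != i:
                continue
            if best is None or score > best[0] or (
                score == best[0] and j < best[1]
            ):
                best = (score, j, alen, ident)
        if best is None:
            continue
        score, _, alen, ident = best
        if alen <= params.min_align_aa:
            continue
        if ident <= params.min_identity:
            continue
        if estimate_evalue(score, lens_a[i], subject_total, K, lam) > params.max_evalue:
            continue
        count += 1
    return count


def conserved_hit_count(
    protsA: Sequence[str],
    protsB: Sequence[str],
    params: Optional[ConservedHitParams] = None,
) -> int:
    """Number of A proteins whose best hit in B is conserved
    (>30 aa aligned, E <= 0.01, >30% identity; one hit per protein)."""
    if not protsA or not protsB:
        raise ValueError("protein lists must be nonempty")
    params = params or ConservedHitParams()
    table = _pair_table(protsA, protsB, params)
    return _count_from_table(
        table, len(protsA), [len(p) for p in protsA],
        sum(len(p) for p in protsB), params,
    )


def conservation_matrix(
    genomes: Sequence[tuple[str, Sequence[str]]],
    params: Optional[ConservedHitParams] = None,
) -> ConservationMatrix:
    """All-vs-all conserved-hit percentage matrix, normalized by each query
    genome's self-comparison and symmetrized (diagonal = 100)."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    params = params or ConservedHitParams()
    for gid, prots in genomes:
        if not prots:
            raise ValueError(f"genome {gid} has no proteins")
    ids = [gid for gid, _ in genomes]
    n = len(genomes)
    self_counts = [
        conserved_hit_count(prots, prots, params) for _, prots in genomes
    ]
    for gid, c in zip(ids, self_counts):
        if c == 0:
            raise ValueError(
                f"genome {gid}: self-comparison yields no conserved hits "
                "(all proteins <= 30 aa?)"
            )
    percent = np.full((n, n), 100.0)
    combine = {"mean": lambda x, y: (x + y) / 2, "min": min, "max": max}[
        params.symmetrize
    ]
    for a in range(n):
        for b in range(a + 1, n):
            protsA, protsB = genomes[a][1], genomes[b][1]
            table = _pair_table(protsA, protsB, params)
            cab = _count_from_table(
                table, len(protsA), [len(p) for p in protsA],
                sum(len(p) for p in protsB), params,
            )
            # reuse the symmetric alignment stats for the reverse direction
            rev = {(j, i): v for (i, j), v in table.items()}
            cba = _count_from_table(
                rev, len(protsB), [len(p) for p in protsB],
                sum(len(p) for p in protsA), params,
            )
            f_ab = 100.0 * cab / self_counts[a]
            f_ba = 100.0 * cba / self_counts[b]
            percent[a, b] = percent[b, a] = float(combine(f_ab, f_ba))
    return ConservationMatrix(genome_ids=ids, percent=percent)


def group_genomes(
    matrix: ConservationMatrix, threshold: float = 20.0
) -> GenomePartition:
    """Partition genomes into connected components of the graph with an
    edge wherever the conserved-hit percentage is strictly > threshold."""
    g = nx.Graph()
    g.add_nodes_from(matrix.genome_ids)
    n = len(matrix.genome_ids)
    for a in range(n):
        for b in range(a + 1, n):
            if matrix.percent[a, b] > threshold:
                g.add_edge(matrix.genome_ids[a], matrix.genome_ids[b])
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return GenomePartition(groups=comps, threshold=threshold)
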