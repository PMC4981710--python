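"""Synthetic-data generators with planted ground truth.

The generators emulate the statistical structure of fosmid-scale deep-sea
viral metagenomics: circular caudoviral genomes of 29.8-41.2 kb with GC
between 30% and 61%, fosmid contigs excised from replication concatemers
(hence carrying terminal direct repeats), host genomes with integrated
proviruses whose att core duplicates flank the insertion and overlap a tRNA
3' end, and read sets with a substitution-only error model at a controlled
per-base identity (closed-form binomial mismatch distribution).

Every operation is deterministic for a fixed seed. A global seed expands to
per-operation child seeds through :func:`child_seed` (numpy SeedSequence
spawn keys, one integer counter per operation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import Contig, GeneCall, GeneCategory, ReadSet, Topology

#: genome length and GC sampling ranges for deep-sea caudoviral genomes
GENOME_LENGTH_RANGE = (29_800, 41_200)
GENOME_GC_RANGE = (0.30, 0.61)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def child_seed(seed: int, counter: int) -> int:
    """Derive a child seed (< 2**31) from a global seed and a counter."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class SyntheticTruth:
    """Planted ground truth: the exact expected answer of each stage."""

    seed: int
    planted_repeat_len: Optional[int] = None
    provirus_coords: Optional[tuple[int, int]] = None
    att_core: Optional[str] = None
    source_genome_of_read: dict = field(default_factory=dict)
    target_identity: Optional[float] = None
    mixture_weights: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.mixture_weights is not None:
            if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
        if self.att_core is not None and len(self.att_core) < 1:
            raise ValueError("att core must be nonempty")
        if self.target_identity is not None and not (
            0.0 <= self.target_identity <= 1.0
        ):
            raise ValueError("target identity must be in [0, 1]")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=length, p=p)]
    return arr.tobytes().decode("ascii")


def make_viral_genome(
    length: int, gc: float, seed: int, contig_id: str = "genome",
    library: str = "synthetic",
) -> Contig:
    """An i.i.d. random circular genome with P(G)+P(C) = gc, split equally."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return Contig(
        id=contig_id,
        seq=_random_dna(rng, length, gc),
        library=library,
        topology=Topology.CIRCULAR,
    )


def excise_fosmid_contig(
    genome: Contig,
    insert_len: Optional[int] = None,
    repeat_len: Optional[int] = None,
    seed: int = 0,
    contig_id: Optional[str] = None,
) -> tuple[Contig, SyntheticTruth]:
    """Cut a linear fosmid-like contig from a circular genome concatemer.

    The contig is a walk of ``insert_len`` bp along the circle from a seeded
    random offset; when the walk is longer than the genome its first bases
    reappear at the end as a terminal direct repeat of length
    insert_len - genome_len. Either ``insert_len`` or ``repeat_len`` may be
    given (the other is derived); giving both inconsistently is an error.
    """
    g = len(genome)
    if insert_len is None:
        if repeat_len is None:
            raise ValueError("give insert_len or repeat_len")
        if repeat_len < 0:
            raise ValueError("repeat_len must be >= 0")
        insert_len = g + repeat_len
    if insert_len < 1:
        raise ValueError("insert_len must be >= 1")
    planted = max(0, insert_len - g)
    if repeat_len is not None and insert_len >= g and planted != repeat_len:
        raise ValueError(
            f"insert_len {insert_len} and repeat_len {repeat_len} disagree "
            f"for a {g}-bp genome"
        )
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, g))
    doubled = genome.seq * (2 + insert_len // g)
    seq = doubled[offset : offset + insert_len]
    contig = Contig(
        id=contig_id or f"{genome.id}_fosmid",
        seq=seq,
        library=genome.library,
        topology=Topology.LINEAR,
    )
    return contig, SyntheticTruth(seed=seed, planted_repeat_len=planted)


def _tile_gene_calls(
    contig_id: str,
    start: int,
    end: int,
    categories: Sequence[GeneCategory],
    rng: np.random.Generator,
    gene_span: int = 300,
    gap: int = 60,
    with_proteins: bool = False,
) -> list[GeneCall]:
    """Tile gene calls of fixed span across [start, end) cycling categories."""
    calls = []
    pos = start
    i = 0
    while pos + gene_span <= end:
        cat = categories[i % len(categories)]
        protein = None
        if with_proteins and cat is not GeneCategory.TRNA:
            protein = random_protein(rng, gene_span // 3)
        calls.append(
            GeneCall(
                contig_id=contig_id,
                start=pos,
                end=pos + gene_span,
                strand="+",
                category=cat,
                protein=protein,
            )
        )
        pos += gene_span + gap
        i += 1
    return calls


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(
        AA20[i] for i in rng.integers(0, len(AA20), size=length)
    )


def make_att_host(
    host_len: int,
    host_gc: float,
    phage: Contig,
    phage_calls: Sequence[GeneCall],
    att_core_len: int = 55,
    trna_len: int = 75,
    seed: int = 0,
    host_id: str = "host",
    integrase_offset: int = 200,
) -> tuple[Contig, list[GeneCall], SyntheticTruth]:
    """A host contig carrying an attB site but no integrated provirus.

    The att core is taken from the phage just downstream of its integrase
    (the attP side) and inserted into the host as the 3' end of a tRNA
    feature, mirroring a SAG contig that a related phage integrates into.
    The resulting host is host_len + att_core_len bp.
    """
    if att_core_len < 31:
        raise ValueError("att_core_len must be >= 31 (>30 bp exact-hit rule)")
    integrase = [c for c in phage_calls if c.category is GeneCategory.INTEGRASE]
    if not integrase:
        raise ValueError(f"phage {phage.id} lacks an integrase gene call")
    int_call = integrase[0]
    core_pos = min(int_call.end + integrase_offset, len(phage) - att_core_len)
    core = phage.seq[core_pos : core_pos + att_core_len]

    rng = np.random.default_rng(seed)
    base = _random_dna(rng, host_len, host_gc)
    # insert the core in the middle third of the host; the tRNA feature
    # covers it so the core forms the tRNA 3' end
    p = host_len // 3 + int(rng.integers(0, max(1, host_len // 10)))
    # force mismatching bases at both core boundaries so the planted exact
    # match has exactly att_core_len bp and the truth is an exact statistic
    flip = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
    if core_pos > 0 and base[p - 1] == phage.seq[core_pos - 1]:
        base = base[: p - 1] + flip[base[p - 1]] + base[p:]
    core_right = core_pos + att_core_len
    if core_right < len(phage) and base[p] == phage.seq[core_right]:
        base = base[:p] + flip[base[p]] + base[p + 1 :]
    host_seq = base[:p] + core + base[p:]
    if trna_len > att_core_len:
        trna_start = p - (trna_len - att_core_len)
    else:
        trna_start = p
    trna_end = p + att_core_len
    host = Contig(id=host_id, seq=host_seq, library="synthetic")
    calls = [
        GeneCall(host_id, trna_start, trna_end, "+", GeneCategory.TRNA,
                 label="tRNA-att")
    ]
    calls += _tile_gene_calls(
        host_id, 0, trna_start - 60, [GeneCategory.CELLULAR], rng
    )
    calls += _tile_gene_calls(
        host_id, trna_end + 60, len(host_seq), [GeneCategory.CELLULAR], rng
    )
    truth = SyntheticTruth(seed=seed, att_core=core)
    return host, sorted(calls, key=lambda c: c.start), truth


def make_host_with_provirus(
    host_len: int,
    host_gc: float,
    phage: Contig,
    phage_calls: Sequence[GeneCall],
    att_core_len: int = 55,
    trna_len: int = 75,
    seed: int = 0,
    host_id: str = "host",
    integrase_offset: int = 200,
) -> tuple[Contig, list[GeneCall], SyntheticTruth]:
    """A host contig with the phage integrated at a tRNA-anchored att site.

    Campbell-style integration: the att core (att_core_len bp taken from the
    phage near its integrase, the attP side) sits at the 3' end of a host
    tRNA; crossover within the core inserts the phage rotated to start just
    after the core, leaving identical core copies (attL/attR) flanking the
    provirus. Resulting length is host_len + phage length + att_core_len.
    Gene calls mark cellular genes outside the provirus, viral genes plus
    the integrase inside, and the tRNA.
    """
    host, host_calls, truth = make_att_host(
        host_len, host_gc, phage, phage_calls, att_core_len, trna_len, seed,
        host_id, integrase_offset,
    )
    integrase = [c for c in phage_calls if c.category is GeneCategory.INTEGRASE][0]
    core = truth.att_core
    core_pos = phage.seq.find(core, max(0, integrase.end))
    if core_pos == -1:
        core_pos = phage.seq.find(core)
    # rotate the phage to start just after the core copy that stays attL-side
    rot = phage.seq[core_pos + att_core_len :] + phage.seq[:core_pos]
    trna = [c for c in host_calls if c.category is GeneCategory.TRNA][0]
    p = trna.end  # insertion point: right after the attB core
    seq = host.seq[:p] + rot + core + host.seq[p:]
    prov_start, prov_end = p, p + len(rot) + att_core_len
    assert len(seq) == host_len + len(phage) + att_core_len

    rng = np.random.default_rng(child_seed(seed, 1))
    calls = [c for c in host_calls if c.end <= p]
    # viral block: integrase first (it abuts attL in the rotated phage),
    # then structural genes
    viral_cats = [
        GeneCategory.INTEGRASE, GeneCategory.TERMINASE, GeneCategory.PORTAL,
        GeneCategory.TAIL, GeneCategory.CAPSID, GeneCategory.OTHER_VIRAL,
    ]
    calls += _tile_gene_calls(host_id, prov_start + 10, prov_end - 10,
                              viral_cats, rng)
    for c in host_calls:
        if c.start >= p:
            calls.append(
                GeneCall(host_id, c.start + len(rot) + att_core_len,
                         c.end + len(rot) + att_core_len, c.strand,
                         c.category, c.label, c.protein)
            )
    host_out = Contig(id=host_id, seq=seq, library="synthetic")
    truth = SyntheticTruth(
        seed=seed, att_core=core, provirus_coords=(prov_start, prov_end)
    )
    return host_out, sorted(calls, key=lambda c: c.start), truth


def simulate_reads(
    contigs: Sequence[Contig],
    weights: Sequence[float],
    n_reads: int,
    read_len: int,
    identity: float,
    seed: int = 0,
    dataset_id: str = "sim",
    depth_m: Optional[float] = None,
) -> tuple[ReadSet, SyntheticTruth]:
    """Draw reads from weighted contigs with a substitution-only error model.

    Each read: source contig by weight, uniform start, uniform strand, and
    each base substituted with probability 1 - identity to one of the three
    other bases uniformly. Mismatch counts per read are therefore
    Binomial(read_len, 1 - identity).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(contigs):
        raise ValueError("one weight per contig required")
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must be in [0, 1]")
    for c, w in zip(contigs, weights):
        if w > 0 and read_len > len(c):
            raise ValueError(
                f"read_len {read_len} exceeds contig {c.id} length {len(c)}"
            )
    rng = np.random.default_rng(seed)
    reads = []
    sources: dict[str, str] = {}
    if n_reads > 0:
        src_idx = rng.choice(len(contigs), size=n_reads, p=weights)
        encoded = {
            i: np.frombuffer(contigs[i].seq.encode(), dtype=np.uint8)
            for i in np.unique(src_idx)
        }
        code = np.full(256, 4, dtype=np.uint8)
        for b, v in zip(b"ACGT", range(4)):
            code[b] = v
        starts = rng.integers(0, [len(contigs[i]) - read_len + 1 for i in src_idx])
        strands = rng.integers(0, 2, size=n_reads)
        for r in range(n_reads):
            i = int(src_idx[r])
            s = int(starts[r])
            frag = encoded[i][s : s + read_len]
            enc = code[frag].copy()
            if strands[r] == 1:  # reverse complement (N maps to itself)
                enc = np.where(enc < 4, 3 - enc[::-1], enc[::-1])
            if identity < 1.0:
                hit = rng.random(read_len) < (1.0 - identity)
                if hit.any():
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    enc[hit] = (enc[hit] + shift) % 4
            seq = _BASES[np.minimum(enc, 3)].tobytes().decode()
            seq = "".join(
                "N" if e == 4 else ch for e, ch in zip(enc, seq)
            ) if (enc == 4).any() else seq
            rid = f"{dataset_id}_r{r:06d}"
            reads.append((rid, seq))
            sources[rid] = contigs[i].id
    readset = ReadSet(dataset_id=dataset_id, reads=reads, depth_m=depth_m)
    truth = SyntheticTruth(
        seed=seed,
        source_genome_of_read=sources,
        target_identity=identity,
        mixture_weights=tuple(weights),
    )
    return readset, truth


def make_depth_community(
    low_gc: float,
    high_gc: float,
    weight_high: float,
    n_reads: int,
    read_len: int,
    seed: int = 0,
    genome_len: int = 30_000,
    dataset_id: str = "community",
    depth_m: Optional[float] = None,
    identity: float = 1.0,
) -> tuple[ReadSet, SyntheticTruth]:
    """Reads from a two-component GC mixture community.

    weight_high = 0 emulates a photic-zone dataset (single low-GC peak);
    weight_high > 0 emulates the bimodal GC distribution of deep datasets.
    """
    if not (0.0 <= weight_high <= 1.0):
        raise ValueError("weight_high must be in [0, 1]")
    low = make_viral_genome(genome_len, low_gc, child_seed(seed, 0),
                            contig_id="community_lowgc")
    high = make_viral_genome(genome_len, high_gc, child_seed(seed, 1),
                             contig_id="community_highgc")
    return simulate_reads(
        [low, high], [1.0 - weight_high, weight_high], n_reads, read_len,
        identity, seed=child_seed(seed, 2), dataset_id=dataset_id,
        depth_m=depth_m,
    )
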