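"""Canonical in-memory records shared by every pipeline stage.

All coordinates are 0-based half-open throughout the package; file formats
with other conventions (GFF3) are converted at the I/O boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction over non-N bases; raises ValueError if no non-N bases."""
    n_gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence has no non-N bases")
    return n_gc / denom


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


class GeneCategory(str, Enum):
    """Closed marker-category vocabulary for gene calls.

    Labels from external annotation pipelines are mapped onto these
    categories (anything unrecognized becomes UNKNOWN).
    """

    TERMINASE = "terminase"
    PORTAL = "portal"
    TAIL = "tail"
    CAPSID = "capsid"
    INTEGRASE = "integrase"
    OTHER_VIRAL = "other_viral"
    EUKARYOTIC_VIRAL = "eukaryotic_viral"
    CELLULAR = "cellular"
    TRNA = "tRNA"
    UNKNOWN = "unknown"


#: categories counted as caudoviral evidence (integrase is recorded
#: separately: it marks lysogeny, not virion structure)
VIRAL_CATEGORIES = frozenset(
    {
        GeneCategory.TERMINASE,
        GeneCategory.PORTAL,
        GeneCategory.TAIL,
        GeneCategory.CAPSID,
        GeneCategory.OTHER_VIRAL,
    }
)


@dataclass
class Contig:
    """A nucleotide sequence record; the unit every stage consumes."""

    id: str
    seq: str
    library: str = ""
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id}: sequence must be nonempty")
        if not VALID_BASES.issuperset(self.seq):
            bad = sorted(set(self.seq) - VALID_BASES)
            raise ValueError(f"contig {self.id}: invalid characters {bad}")
        self.topology = Topology(self.topology)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)


@dataclass
class GeneCall:
    """A located gene on a contig with a marker-category label.

    ``protein`` may be absent (e.g. tRNA features). When present its length
    must equal floor((end-start)/3), the stop codon being excluded from the
    gene span.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    category: GeneCategory = GeneCategory.UNKNOWN
    label: str = ""
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene on {self.contig_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene on {self.contig_id}: strand must be + or -")
        self.category = GeneCategory(self.category)
        if self.protein is not None:
            expect = (self.end - self.start) // 3
            if len(self.protein) != expect:
                raise ValueError(
                    f"gene on {self.contig_id} [{self.start},{self.end}): protein "
                    f"length {len(self.protein)} != floor(span/3) = {expect}"
                )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadSet:
    """A read dataset with depth metadata.

    ``total_bases`` is always recomputed from the reads so the invariant
    total_bases == sum of read lengths holds by construction.
    """

    dataset_id: str
    reads: list = field(default_factory=list)  # list[(id, seq)]
    depth_m: Optional[float] = None
    total_bases: int = 0

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be nonempty")
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError("depth_m must be non-negative")
        self.total_bases = sum(len(s) for _, s in self.reads)

    def __len__(self) -> int:
        return len(self.reads)
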