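"""Readers and writers for the external formats the pipeline consumes.

FASTA/FASTQ go through Biopython SeqIO; GFF3 through gffutils. The gene-call
TSV dialect is a plain tab table with header
``contig_id  start0  end0  strand  category  label  protein``
using 0-based half-open coordinates (this is the package's native dialect;
GFF3 input is 1-based inclusive and converted at this boundary).
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .records import Contig, GeneCall, GeneCategory, ReadSet, Topology

logger = logging.getLogger(__name__)

_NORMALIZE = re.compile(r"[^ACGTN]")

#: default mapping from free-text annotation labels to marker categories;
#: users may extend it with a label->category TSV (see read_category_map)
DEFAULT_CATEGORY_MAP = {c.value: c for c in GeneCategory}
DEFAULT_CATEGORY_MAP.update(
    {
        "trna": GeneCategory.TRNA,
        "large terminase": GeneCategory.TERMINASE,
        "terminase large subunit": GeneCategory.TERMINASE,
        "portal protein": GeneCategory.PORTAL,
        "tail protein": GeneCategory.TAIL,
        "tape measure protein": GeneCategory.TAIL,
        "major capsid protein": GeneCategory.CAPSID,
        "phage integrase": GeneCategory.INTEGRASE,
    }
)


def normalize_seq(raw: str) -> str:
    """Uppercase, U->T, anything outside {A,C,G,T,N} -> N."""
    s = raw.upper().replace("U", "T")
    return _NORMALIZE.sub("N", s)


def _resolve_category(label: str, category_map=None) -> GeneCategory:
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    key = label.strip()
    cat = cmap.get(key) or cmap.get(key.lower())
    if cat is None:
        logger.warning("unknown gene category %r mapped to 'unknown'", label)
        return GeneCategory.UNKNOWN
    return GeneCategory(cat)


def read_category_map(path) -> dict:
    """Read a two-column TSV (label, category) extending the default map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "category"])
    cmap = dict(DEFAULT_CATEGORY_MAP)
    for row in df.itertuples(index=False):
        cmap[str(row.label)] = GeneCategory(row.category)
    return cmap


# ---------------------------------------------------------------- FASTA

def read_fasta(path, library: str = "") -> list[Contig]:
    """Read contigs from FASTA; header token before first whitespace is the id.

    Sequences are uppercased, U becomes T and any other non-ACGTN symbol
    becomes N. A header tag ``topology=circular`` is honoured.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        topo = (
            Topology.CIRCULAR
            if "topology=circular" in rec.description
            else Topology.LINEAR
        )
        contigs.append(
            Contig(id=rec.id, seq=normalize_seq(str(rec.seq)), library=library,
                   topology=topo)
        )
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(path, contigs: Iterable[Contig], width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            tag = " topology=circular" if c.topology is Topology.CIRCULAR else ""
            fh.write(f">{c.id}{tag}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------- gene calls

def read_gene_calls(
    path,
    format: str = "gff3",
    contigs: Optional[Sequence[Contig]] = None,
    category_map=None,
) -> list[GeneCall]:
    """Read gene calls from GFF3 (1-based inclusive) or the TSV dialect
    (0-based half-open), converting to internal 0-based half-open coordinates.

    If ``contigs`` is supplied every call must resolve to a known contig and
    lie within its bounds.
    """
    if format == "gff3":
        calls = _read_gff3(path, category_map)
    elif format == "tsv":
        calls = _read_tsv(path, category_map)
    else:
        raise ValueError(f"unknown gene-call format {format!r}")
    if contigs is not None:
        by_id = {c.id: c for c in contigs}
        for gc in calls:
            ctg = by_id.get(gc.contig_id)
            if ctg is None:
                raise ValueError(f"gene call references unknown contig {gc.contig_id!r}")
            if gc.end > len(ctg):
                raise ValueError(
                    f"gene call [{gc.start},{gc.end}) exceeds contig "
                    f"{gc.contig_id} length {len(ctg)}"
                )
    return calls


def _read_gff3(path, category_map) -> list[GeneCall]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    calls = []
    for f in db.all_features():
        start0, end0 = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
        if end0 <= start0:
            raise ValueError(f"gene on {f.seqid}: end <= start after conversion")
        label = f.attributes.get("label", [f.featuretype])[0]
        raw_cat = f.attributes.get("category", [label])[0]
        protein = f.attributes.get("protein", [None])[0]
        calls.append(
            GeneCall(
                contig_id=f.seqid,
                start=start0,
                end=end0,
                strand=f.strand if f.strand in "+-" else "+",
                category=_resolve_category(raw_cat, category_map),
                label=label,
                protein=protein,
            )
        )
    return calls


def _read_tsv(path, category_map) -> list[GeneCall]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str}, keep_default_na=False)
    required = {"contig_id", "start0", "end0", "strand", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene-call TSV missing columns {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        end0, start0 = int(row.end0), int(row.start0)
        if end0 <= start0:
            raise ValueError(f"gene on {row.contig_id}: end <= start")
        protein = getattr(row, "protein", "") or None
        calls.append(
            GeneCall(
                contig_id=str(row.contig_id),
                start=start0,
                end=end0,
                strand=str(row.strand),
                category=_resolve_category(str(row.category), category_map),
                label=str(getattr(row, "label", "")),
                protein=protein,
            )
        )
    return calls


def write_gene_calls(path, calls: Iterable[GeneCall], format: str = "tsv") -> None:
    calls = list(calls)
    if format == "tsv":
        df = pd.DataFrame(
            {
                "contig_id": [c.contig_id for c in calls],
                "start0": [c.start for c in calls],
                "end0": [c.end for c in calls],
                "strand": [c.strand for c in calls],
                "category": [c.category.value for c in calls],
                "label": [c.label for c in calls],
                "protein": [c.protein or "" for c in calls],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in calls:
                attrs = f"category={c.category.value}"
                if c.label:
                    attrs += f";label={c.label}"
                if c.protein:
                    attrs += f";protein={c.protein}"
                ftype = "tRNA" if c.category is GeneCategory.TRNA else "CDS"
                fh.write(
                    f"{c.contig_id}\tbathyvir\t{ftype}\t{c.start + 1}\t{c.end}"
                    f"\t.\t{c.strand}\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown gene-call format {format!r}")


# ---------------------------------------------------------------- reads

def read_reads(
    path,
    format: Optional[str] = None,
    dataset_id: Optional[str] = None,
    depth_m: Optional[float] = None,
) -> ReadSet:
    """Read a FASTA/FASTQ read dataset. FASTQ qualities are checked for
    length consistency (Biopython raises on mismatch) and then discarded.
    """
    p = Path(path)
    if format is None:
        format = "fastq" if p.suffix.lower() in {".fq", ".fastq"} else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format {format!r}")
    reads = [
        (rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(str(p), format)
    ]
    if not reads:
        raise ValueError(f"no reads in {path}")
    return ReadSet(
        dataset_id=dataset_id or p.stem, reads=reads, depth_m=depth_m
    )


def write_reads(path, readset: ReadSet, format: str = "fasta") -> None:
    with open(path, "w") as fh:
        for rid, seq in readset.reads:
            if format == "fasta":
                fh.write(f">{rid}\n{seq}\n")
            elif format == "fastq":
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                raise ValueError(f"unknown read format {format!r}")


# --------------------------------------------------- coordinate conversion

def gff3_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff3(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive."""
    return start0 + 1, end0
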