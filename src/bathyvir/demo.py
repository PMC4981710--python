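"""Bundled synthetic demo: a small world with known ground truth.

The demo plants 8 caudoviral genomes (3 of them a shared-protein family,
like the largest group among the complete deep-sea genomes), 5 fosmid
contigs with terminal direct repeats (complete) and 3 without, 2 host
contigs with integrated proviruses and tRNA-anchored att sites, 3 read
datasets at 100 m / 500 m / 3,000 m with depth-dependent GC mixtures and
depth-dependent phage abundances, and a handful of CRISPR spacers with no
planted protospacer. Truth tables are written next to the inputs.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import sequence_io as sio
from .pipeline import PipelineConfig
from .records import Contig, GeneCall, GeneCategory, ReadSet
from .synthetic import (
    GENOME_GC_RANGE,
    GENOME_LENGTH_RANGE,
    child_seed,
    excise_fosmid_contig,
    make_depth_community,
    make_host_with_provirus,
    make_viral_genome,
    random_protein,
    simulate_reads,
)

#: planted terminal-repeat lengths for the 5 complete fosmid contigs
_PLANTED_REPEATS = [55, 60, 72, 90, 120]
_N_GENOMES = 8
_FAMILY = [0, 1, 2]  # genomes forming the shared-protein family


def _phage_gene_calls(
    contig_id: str, rng: np.random.Generator, family_proteins=None,
    with_integrase: bool = True,
) -> list[GeneCall]:
    """Twelve tiled gene calls with viral marker categories and proteins.

    Family members receive the same proteins in their first six slots so
    that >40% of their protein content is shared.
    """
    cats = [
        GeneCategory.TERMINASE, GeneCategory.PORTAL, GeneCategory.CAPSID,
        GeneCategory.TAIL, GeneCategory.OTHER_VIRAL, GeneCategory.UNKNOWN,
        GeneCategory.TAIL, GeneCategory.OTHER_VIRAL, GeneCategory.UNKNOWN,
        GeneCategory.OTHER_VIRAL, GeneCategory.UNKNOWN, GeneCategory.UNKNOWN,
    ]
    if with_integrase:
        cats[5] = GeneCategory.INTEGRASE
    calls = []
    pos = 120
    for i, cat in enumerate(cats):
        if family_proteins is not None and i < len(family_proteins):
            protein = family_proteins[i]
        else:
            protein = random_protein(rng, int(rng.integers(90, 160)))
        span = 3 * len(protein)
        calls.append(
            GeneCall(contig_id, pos, pos + span, "+", cat,
                     label=cat.value, protein=protein)
        )
        pos += span + 60
    return calls


def make_demo(outdir, seed: int = 0) -> Path:
    """Generate the demo dataset and config; returns the config path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(child_seed(seed, 100))

    # ------------------------------------------------------------ genomes
    genomes: list[Contig] = []
    for i in range(_N_GENOMES):
        length = int(rng.integers(*GENOME_LENGTH_RANGE))
        gc = float(rng.uniform(*GENOME_GC_RANGE))
        genomes.append(
            make_viral_genome(length, gc, child_seed(seed, i),
                              contig_id=f"uvSyn-G{i + 1}")
        )

    # family proteins shared by the first three genomes (6 of 12 slots)
    fam_rng = np.random.default_rng(child_seed(seed, 200))
    family_proteins = [
        random_protein(fam_rng, int(fam_rng.integers(90, 160)))
        for _ in range(6)
    ]

    contigs: list[Contig] = []
    gene_calls: list[GeneCall] = []
    truth_rows = []
    for i, g in enumerate(genomes):
        if i < 5:
            contig, t = excise_fosmid_contig(
                g, repeat_len=_PLANTED_REPEATS[i], seed=child_seed(seed, 300 + i)
            )
        else:
            contig, t = excise_fosmid_contig(
                g, insert_len=len(g) - 2000, seed=child_seed(seed, 300 + i)
            )
        contigs.append(contig)
        gene_calls.extend(
            _phage_gene_calls(
                contig.id,
                np.random.default_rng(child_seed(seed, 400 + i)),
                family_proteins if i in _FAMILY else None,
                with_integrase=(i < 5),
            )
        )
        truth_rows.append(
            {
                "contig_id": contig.id, "genome_id": g.id,
                "genome_len": len(g), "gc": round(g.gc, 4),
                "planted_repeat_len": t.planted_repeat_len,
            }
        )
    sio.write_fasta(out / "contigs.fasta", contigs)
    sio.write_gene_calls(out / "gene_calls.tsv", gene_calls, "tsv")
    pd.DataFrame(truth_rows).to_csv(out / "truth_contigs.tsv", sep="\t",
                                    index=False)

    # ------------------------------------------------------------ hosts
    hosts, host_calls, host_truth = [], [], []
    for hi, gi in enumerate([3, 4]):  # complete genomes with integrase calls
        phage_contig = contigs[gi]
        phage_calls = [c for c in gene_calls if c.contig_id == phage_contig.id]
        core_len = 55 if hi == 0 else 40
        # the integrating phage in the coordinate frame the pipeline sees:
        # the fosmid contig with its terminal repeat trimmed (a rotation of
        # the source genome)
        trimmed_phage = Contig(
            id=phage_contig.id, seq=phage_contig.seq[: len(genomes[gi])],
            library=phage_contig.library, topology="circular",
        )
        host, calls, t = make_host_with_provirus(
            host_len=10_000, host_gc=0.45,
            phage=trimmed_phage, phage_calls=phage_calls,
            att_core_len=core_len, seed=child_seed(seed, 500 + hi),
            host_id=f"host{hi + 1}",
        )
        hosts.append(host)
        host_calls.extend(calls)
        host_truth.append(
            {
                "host_id": host.id, "phage_id": phage_contig.id,
                "provirus_start": t.provirus_coords[0],
                "provirus_end": t.provirus_coords[1],
                "att_core_len": core_len, "att_core": t.att_core,
            }
        )
    sio.write_fasta(out / "hosts.fasta", hosts)
    sio.write_gene_calls(out / "host_gene_calls.tsv", host_calls, "tsv")
    pd.DataFrame(host_truth).to_csv(out / "truth_hosts.tsv", sep="\t",
                                    index=False)

    # ------------------------------------------------------------ reads
    # depth-dependent phage abundance: the deep datasets recruit mostly to
    # the family genomes, the surface dataset barely at all
    plans = [
        ("d100", 100.0, 0.0, 150, [(4, 150)]),
        ("d500", 500.0, 0.4, 1200, [(0, 500), (3, 150)]),
        ("d3000", 3000.0, 0.5, 1200, [(0, 800), (3, 250)]),
    ]
    manifest_rows = []
    for di, (ds, depth, w_high, n_comm, phage_plan) in enumerate(plans):
        comm, _ = make_depth_community(
            low_gc=0.35, high_gc=0.60, weight_high=w_high,
            n_reads=n_comm, read_len=100, seed=child_seed(seed, 600 + di),
            dataset_id=ds, depth_m=depth,
        )
        reads = list(comm.reads)
        src_rows = [
            {"read_id": rid, "source": comm_src}
            for rid, comm_src in ( (r, "community") for r, _ in comm.reads )
        ]
        for pj, (gi, n_phage) in enumerate(phage_plan):
            trimmed = genomes[gi]
            ph_reads, t = simulate_reads(
                [trimmed], [1.0], n_phage, 100, identity=0.98,
                seed=child_seed(seed, 700 + 10 * di + pj),
                dataset_id=f"{ds}_p{gi}",
            )
            reads.extend(ph_reads.reads)
            src_rows.extend(
                {"read_id": rid, "source": src}
                for rid, src in t.source_genome_of_read.items()
            )
        rs = ReadSet(dataset_id=ds, reads=reads, depth_m=depth)
        fmt = "fastq" if di == 0 else "fasta"
        fname = f"reads_{ds}.{'fastq' if fmt == 'fastq' else 'fasta'}"
        sio.write_reads(out / fname, rs, fmt)
        pd.DataFrame(src_rows).to_csv(out / f"truth_reads_{ds}.tsv", sep="\t",
                                      index=False)
        manifest_rows.append(
            {"dataset_id": ds, "path": fname, "format": fmt, "depth_m": depth}
        )
    pd.DataFrame(manifest_rows).to_csv(out / "reads.tsv", sep="\t", index=False)

    # ------------------------------------------------------------ spacers
    sp_rng = np.random.default_rng(child_seed(seed, 800))
    with open(out / "spacers.fasta", "w") as fh:
        for i in range(5):
            sp = "".join("ACGT"[b] for b in sp_rng.integers(0, 4, size=32))
            fh.write(f">spacer{i + 1}\n{sp}\n")

    # ------------------------------------------------------------ config
    cfg = PipelineConfig(
        contigs=str(out / "contigs.fasta"),
        gene_calls=str(out / "gene_calls.tsv"),
        gene_call_format="tsv",
        read_manifest=str(out / "reads.tsv"),
        host_contigs=str(out / "hosts.fasta"),
        host_gene_calls=str(out / "host_gene_calls.tsv"),
        spacers=str(out / "spacers.fasta"),
        outdir=str(out / "results"),
        seed=seed,
    )
    cfg_path = out / "config.yaml"
    cfg.to_yaml(cfg_path)
    return cfg_path
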