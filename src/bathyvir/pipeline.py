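"""End-to-end pipeline: completeness -> classification -> grouping ->
recruitment + GC profiles -> host linking, driven by a single YAML config.

Every stage threshold defaults to the study settings (terminal repeats
>50 bp, conserved hits >30 aa / E<=0.01 / >30% identity, grouping >20%,
recruitment >95% identity / >50 bp / E<1e-5, att hits >30 bp at 100%
identity), so the out-of-box behavior reproduces the analysis shape.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import sequence_io as sio
from .classify import ClassifyParams, classify_contig
from .completeness import circularity_report, detect_terminal_repeat, trim_circular
from .gc_profiles import detect_modes, gc_profile
from .grouping import ConservedHitParams, conservation_matrix, group_genomes
from .host_linking import find_att_links, links_to_frame, spacer_search
from .records import Contig, GeneCategory
from .recruitment import (
    RecruitParams,
    assign_depth_class,
    profiles_to_frame,
    recruit,
    recruitment_plot_data,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CompletenessParams:
    min_repeat: int = 50
    max_offset: int = 0


@dataclass
class HostLinkParams:
    min_len: int = 30
    integrase_window: int = 5000
    require_containment: bool = False
    spacer_max_mismatch: int = 0


@dataclass
class GCParams:
    bin_width: float = 1.0
    smooth_window: int = 5
    min_separation: float = 10.0
    min_prominence: float = 0.05


@dataclass
class GroupingParams(ConservedHitParams):
    threshold: float = 20.0


@dataclass
class PipelineConfig:
    contigs: str = ""
    gene_calls: str = ""
    gene_call_format: str = "tsv"
    read_manifest: str = ""          # TSV: dataset_id, path, format, depth_m
    host_contigs: str = ""
    host_gene_calls: str = ""
    spacers: str = ""
    outdir: str = "bathyvir_out"
    seed: int = 0
    completeness: CompletenessParams = field(default_factory=CompletenessParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    grouping: GroupingParams = field(default_factory=GroupingParams)
    recruitment: RecruitParams = field(default_factory=RecruitParams)
    hostlink: HostLinkParams = field(default_factory=HostLinkParams)
    gc: GCParams = field(default_factory=GCParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, type(current)(**value))
            else:
                setattr(cfg, key, value)
        # tuples survive YAML round-trips as lists
        if isinstance(cfg.recruitment.scoring, list):
            cfg.recruitment.scoring = tuple(cfg.recruitment.scoring)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["recruitment"]["scoring"] = list(d["recruitment"]["scoring"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"dataset_id", "path", "format", "depth_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"read manifest needs columns {sorted(required)}")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the summary dict (also written
    to ``outdir/summary.json``). Partial outputs are retained on failure."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    summary: dict = {"seed": config.seed}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - stage-named abort
                raise StageError(name, e) from e
        return wrap

    # ---------------------------------------------------------- inputs
    contigs = stage("read_contigs")(lambda: sio.read_fasta(config.contigs))
    calls = stage("read_gene_calls")(
        lambda: sio.read_gene_calls(
            config.gene_calls, config.gene_call_format, contigs=contigs
        )
        if config.gene_calls
        else []
    )
    calls_by_contig: dict[str, list] = {c.id: [] for c in contigs}
    for gc in calls:
        calls_by_contig[gc.contig_id].append(gc)
    summary["n_contigs"] = len(contigs)
    logger.info("loaded %d contigs, %d gene calls", len(contigs), len(calls))

    # ---------------------------------------------------------- completeness
    def _completeness():
        calls_, genomes_ = [], []
        for c in contigs:
            call = detect_terminal_repeat(
                c, config.completeness.min_repeat, config.completeness.max_offset
            )
            calls_.append(call)
            if call.is_complete:
                genomes_.append(trim_circular(c, call))
        return calls_, genomes_

    circ_calls, complete_genomes = stage("completeness")(_completeness)
    circularity_report(circ_calls).to_csv(out / "circularity.tsv", sep="\t",
                                          index=False)
    sio.write_fasta(out / "complete_genomes.fasta", complete_genomes)
    summary["n_complete_genomes"] = len(complete_genomes)
    logger.info("completeness: %d/%d contigs complete",
                len(complete_genomes), len(contigs))

    # ---------------------------------------------------------- classification
    def _classify():
        return [
            classify_contig(c, calls_by_contig[c.id], config.classify)
            for c in contigs
        ]

    classes = stage("classification")(_classify)
    pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in classes],
            "label": [c.label for c in classes],
            "viral_block_start": [
                c.viral_block[0] if c.viral_block else "" for c in classes
            ],
            "viral_block_end": [
                c.viral_block[1] if c.viral_block else "" for c in classes
            ],
        }
    ).to_csv(out / "classification.tsv", sep="\t", index=False)
    label_counts = pd.Series([c.label for c in classes]).value_counts()
    summary["classification"] = label_counts.to_dict()

    # ---------------------------------------------------------- grouping
    def _grouping():
        genomes = []
        for g in complete_genomes:
            prots = [
                c.protein for c in calls_by_contig.get(g.id, []) if c.protein
            ]
            if prots:
                genomes.append((g.id, prots))
        if len(genomes) < 2:
            return None, None
        mat = conservation_matrix(genomes, config.grouping)
        part = group_genomes(mat, config.grouping.threshold)
        return mat, part

    matrix, partition = stage("grouping")(_grouping)
    if matrix is not None:
        matrix.to_frame().to_csv(out / "conservation_matrix.tsv", sep="\t")
        partition.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
        summary["n_groups"] = len(partition.groups)
        summary["group_sizes"] = sorted(
            (len(g) for g in partition.groups), reverse=True
        )
        summary["n_multi_member_groups"] = len(partition.multi_member_groups)

    # ------------------------------------------------- recruitment + GC
    datasets = []
    if config.read_manifest:
        manifest = stage("read_manifest")(lambda: _read_manifest(config.read_manifest))
        base = Path(config.read_manifest).parent
        for row in manifest.itertuples(index=False):
            p = Path(row.path)
            if not p.is_absolute():
                p = base / p
            rs = stage("read_reads")(
                lambda p=p, row=row: sio.read_reads(
                    p, format=row.format, dataset_id=row.dataset_id,
                    depth_m=float(row.depth_m),
                )
            )
            datasets.append(rs)

    recruit_rows, depth_rows, gc_rows = [], [], []
    indexes: dict = {}
    for rs in datasets:
        depth = assign_depth_class(rs.depth_m, rs.dataset_id)
        depth_rows.append(dataclasses.asdict(depth))
        if complete_genomes:
            profiles = stage("recruitment")(
                lambda rs=rs: recruit(rs, complete_genomes,
                                      config.recruitment, indexes)
            )
            recruit_rows.append(profiles_to_frame(profiles))
            plot_rows = []
            for p in profiles:
                for pos, ident in recruitment_plot_data(p):
                    plot_rows.append(
                        {"genome_id": p.genome_id, "dataset_id": p.dataset_id,
                         "position": pos, "identity_pct": ident}
                    )
            pd.DataFrame(
                plot_rows,
                columns=["genome_id", "dataset_id", "position", "identity_pct"],
            ).to_csv(out / f"recruitment_plot_{rs.dataset_id}.tsv", sep="\t",
                     index=False)
        prof = stage("gc_profile")(
            lambda rs=rs: gc_profile(rs, config.gc.bin_width)
        )
        modes = detect_modes(
            prof, config.gc.smooth_window, config.gc.min_separation,
            config.gc.min_prominence,
        )
        gc_rows.append(
            {
                "dataset_id": rs.dataset_id,
                "depth_m": rs.depth_m,
                "depth_class": depth.label,
                "mean_gc": round(prof.mean_gc, 2),
                "n_modes": len(modes),
                "modes": ",".join(f"{m:.1f}" for m in modes),
            }
        )
        pd.DataFrame(
            {
                "bin_start": prof.bin_edges[:-1],
                "bin_end": prof.bin_edges[1:],
                "count": prof.histogram,
            }
        ).to_csv(out / f"gc_{rs.dataset_id}.tsv", sep="\t", index=False)
    if recruit_rows:
        rec = pd.concat(recruit_rows, ignore_index=True)
        rec["depth_class"] = [
            assign_depth_class(
                next(rs.depth_m for rs in datasets if rs.dataset_id == d)
            ).label
            for d in rec["dataset_id"]
        ]
        rec["display"] = rec["rpkg"] > config.recruitment.display_min_rpkg
        rec.to_csv(out / "recruitment.tsv", sep="\t", index=False)
        summary["recruitment"] = {
            ds: int(g["n_recruited"].sum())
            for ds, g in rec.groupby("dataset_id")
        }
    if gc_rows:
        pd.DataFrame(gc_rows).to_csv(out / "gc_summary.tsv", sep="\t", index=False)
        summary["gc_modes"] = {r["dataset_id"]: r["n_modes"] for r in gc_rows}
        summary["depth_classes"] = {
            r["dataset_id"]: r["depth_class"] for r in gc_rows
        }

    # ---------------------------------------------------------- host linking
    if config.host_contigs:
        hosts = stage("read_hosts")(lambda: sio.read_fasta(config.host_contigs))
        host_calls = stage("read_host_gene_calls")(
            lambda: sio.read_gene_calls(
                config.host_gene_calls, config.gene_call_format, contigs=hosts
            )
            if config.host_gene_calls
            else []
        )
        hc_by_id: dict[str, list] = {h.id: [] for h in hosts}
        for gc in host_calls:
            hc_by_id[gc.contig_id].append(gc)
        host_pairs = [(h, hc_by_id[h.id]) for h in hosts]

        hclasses = stage("host_classification")(
            lambda: [
                classify_contig(h, hc_by_id[h.id], config.classify)
                for h in hosts
            ]
        )
        pd.DataFrame(
            {
                "contig_id": [c.contig_id for c in hclasses],
                "label": [c.label for c in hclasses],
                "viral_block_start": [
                    c.viral_block[0] if c.viral_block else "" for c in hclasses
                ],
                "viral_block_end": [
                    c.viral_block[1] if c.viral_block else "" for c in hclasses
                ],
            }
        ).to_csv(out / "host_classification.tsv", sep="\t", index=False)
        summary["n_proviruses"] = sum(
            1 for c in list(classes) + hclasses if c.label == "provirus"
        )

        def _links():
            all_links = []
            for g in complete_genomes:
                pc = calls_by_contig.get(g.id, [])
                if not any(c.category is GeneCategory.INTEGRASE for c in pc):
                    continue
                all_links.extend(
                    find_att_links(
                        g, pc, host_pairs,
                        min_len=config.hostlink.min_len,
                        integrase_window=config.hostlink.integrase_window,
                        require_containment=config.hostlink.require_containment,
                    )
                )
            return all_links

        links = stage("host_linking")(_links)
        links_to_frame(links).to_csv(out / "host_links.tsv", sep="\t", index=False)
        summary["n_significant_links"] = sum(1 for l in links if l.significant)

    if config.spacers:
        spacer_contigs = stage("read_spacers")(lambda: sio.read_fasta(config.spacers))
        spacers = [(c.id, c.seq) for c in spacer_contigs]
        s_hits = stage("spacer_search")(
            lambda: spacer_search(
                spacers, complete_genomes,
                max_mismatch=config.hostlink.spacer_max_mismatch,
            )
        )
        pd.DataFrame(
            [dataclasses.asdict(h) for h in s_hits],
            columns=["spacer_id", "genome_id", "position", "mismatches", "strand"],
        ).to_csv(out / "spacer_hits.tsv", sep="\t", index=False)
        summary["n_spacer_hits"] = len(s_hits)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
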