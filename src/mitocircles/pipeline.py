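"""End-to-end orchestration: screen -> resolve -> validate -> repeats ->
synteny -> report, from one plain-text config.

Stages whose optional inputs are missing are skipped with a logged
notice (no reads: junction validation is skipped; no annotations: the
gene report is skipped).  A manifest records the effective config hash
and a checksum per output file; identical config and inputs give a
byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .graph import assign_multiplicities, prune_graph, resolve_circles, stitch_sequences
from .io import (
    read_connection_graph,
    read_fasta,
    read_feature_table,
    write_fasta,
)
from .junctions import JunctionConfig, find_break_sites, spanning_read_test
from .repeats import (
    SSRConfig,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_summary_table,
)
from .report import gc_content, gene_inventory, partition_coding, trans_chromosomal_genes
from .screen import Contig, ScreenConfig, classify_contigs, estimate_modal_depth
from .synteny import SyntenyConfig, chain_to_lcbs, coverage_and_rearrangements, dotplot_table, find_anchors

logger = logging.getLogger("mitocircles")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str
    contigs: str | None = None  # FASTA
    graph: str | None = None
    graph_dialect: str = "newbler"
    mt_references: list[str] = field(default_factory=list)
    cp_references: list[str] = field(default_factory=list)
    reads: str | None = None
    reference: str | None = None  # close single-circle reference genome
    annotations: str | None = None  # feature-table-lite
    seed: int = 0
    keep_contigs: list[str] = field(default_factory=list)
    drop_contigs: list[str] = field(default_factory=list)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    junction: JunctionConfig = field(default_factory=JunctionConfig)
    ssr: SSRConfig = field(default_factory=SSRConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    dispersed_min_len: int = 30
    dispersed_max_mismatch: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("screen", ScreenConfig),
            ("junction", JunctionConfig),
            ("ssr", SSRConfig),
            ("synteny", SyntenyConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def effective_dict(self) -> dict:
        def unpack(v):
            if dataclasses.is_dataclass(v):
                return dataclasses.asdict(v)
            return v

        return {k: unpack(v) for k, v in dataclasses.asdict(self).items()}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are present; return the manifest.

    Stage errors propagate with the stage name attached; outputs of
    earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mitocircles",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config.effective_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    def record(stage: str, status: str, outputs: list[Path] = ()) -> None:
        manifest["stages"][stage] = {
            "status": status,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def run_stage(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- inputs ----------------------------------------------------------
    if not config.contigs or not config.graph:
        raise ValueError("pipeline requires contigs and a connection graph")
    contig_records = read_fasta(config.contigs)
    graph = read_connection_graph(config.graph, config.graph_dialect)
    contigs: list[Contig] = []
    for rec in contig_records:
        node = graph.nodes.get(rec.id)
        if node is None:
            graph.add_contig(rec.id, length=len(rec.sequence), sequence=rec.sequence)
            node = graph.nodes[rec.id]
        node.sequence = rec.sequence
        node.length = len(rec.sequence)
        contigs.append(
            Contig(rec.id, len(rec.sequence), node.depth, node.n_reads, rec.sequence)
        )

    # ---- screen ----------------------------------------------------------
    model = run_stage(
        "screen",
        estimate_modal_depth,
        contigs,
        config.screen.tolerance,
        config.screen.anomaly_factor,
    )
    if config.mt_references:
        mt_refs = [r for p in config.mt_references for r in read_fasta(p)]
        cp_refs = (
            [r for p in config.cp_references for r in read_fasta(p)]
            if config.cp_references
            else None
        )
        labels = run_stage(
            "screen", classify_contigs, contigs, mt_refs, model, config.screen, cp_refs
        )
    else:
        logger.info("no mt references given; all contigs assumed mitochondrial")
        labels = {c.id: "mt" for c in contigs}
    screen_tsv = out / "screen.tsv"
    pd.DataFrame(
        [
            {
                "id": c.id,
                "length": c.length,
                "depth": c.depth,
                "n_reads": c.n_reads,
                "label": labels[c.id],
            }
            for c in contigs
        ]
    ).to_csv(screen_tsv, sep="\t", index=False)
    record("screen", "run", [screen_tsv])

    # ---- resolve ---------------------------------------------------------
    log: list[str] = []
    pruned = run_stage(
        "resolve",
        prune_graph,
        graph,
        labels,
        model,
        keep=frozenset(config.keep_contigs),
        drop=frozenset(config.drop_contigs),
        log=log,
    )
    mult = run_stage("resolve", assign_multiplicities, pruned, model)
    paths = run_stage("resolve", resolve_circles, pruned, mult)
    chromosomes = run_stage(
        "resolve",
        stitch_sequences,
        paths,
        {cid: node.sequence for cid, node in pruned.nodes.items()},
    )
    chrom_fa = out / "chromosomes.fasta"
    write_fasta(chromosomes, chrom_fa)
    paths_tsv = out / "paths.tsv"
    pd.DataFrame(
        [
            {
                "chromosome": rec.id,
                "n_contigs": len(path.members),
                "length": len(rec.sequence),
                "path": ",".join(f"{c}{o}" for c, o in path.members),
            }
            for rec, path in zip(chromosomes, paths)
        ]
    ).to_csv(paths_tsv, sep="\t", index=False)
    prune_log = out / "pruning.log"
    prune_log.write_text("".join(line + "\n" for line in log))
    record("resolve", "run", [chrom_fa, paths_tsv, prune_log])

    # ---- validate --------------------------------------------------------
    if config.reads and config.reference:
        reference = read_fasta(config.reference)[0]
        reference.topology = "circular"
        reads = read_fasta(config.reads)
        windows = run_stage(
            "validate",
            find_break_sites,
            chromosomes,
            reference,
            flank=config.junction.flank,
        )
        rows = []
        for window in windows:
            verdict = run_stage(
                "validate", spanning_read_test, window, reads, config.junction
            )
            rows.append(
                {
                    "junction": window.id,
                    "ref_position": window.position,
                    "matched": verdict.matched_reads,
                    "spanning": verdict.spanning_reads,
                    "verdict": "supported" if verdict.supported else "not_supported",
                }
            )
        junctions_tsv = out / "junctions.tsv"
        pd.DataFrame(
            rows, columns=["junction", "ref_position", "matched", "spanning", "verdict"]
        ).to_csv(junctions_tsv, sep="\t", index=False)
        record("validate", "run", [junctions_tsv])
    else:
        logger.info("junction validation skipped: reads or reference missing")
        record("validate", "skipped")

    # ---- repeats ---------------------------------------------------------
    ssr_rows, tandem_rows = [], []
    for rec in chromosomes:
        for s in find_ssrs(rec, config.ssr):
            ssr_rows.append(dataclasses.asdict(s))
        for t in find_tandem_repeats(rec):
            tandem_rows.append(dataclasses.asdict(t))
    pairs = run_stage(
        "repeats",
        find_dispersed_repeats,
        chromosomes,
        config.dispersed_min_len,
        config.dispersed_max_mismatch,
    )
    ssr_tsv = out / "ssrs.tsv"
    pd.DataFrame(
        ssr_rows, columns=["chromosome", "motif", "unit_length", "copies", "start", "end"]
    ).to_csv(ssr_tsv, sep="\t", index=False)
    tandem_tsv = out / "tandems.tsv"
    pd.DataFrame(
        tandem_rows, columns=["chromosome", "period", "copies", "start", "end", "consensus"]
    ).to_csv(tandem_tsv, sep="\t", index=False)
    dispersed_tsv = out / "dispersed.tsv"
    pd.DataFrame(
        [dataclasses.asdict(p) for p in pairs],
        columns=[
            "chrom1",
            "start1",
            "chrom2",
            "start2",
            "length",
            "mismatches",
            "orientation",
        ],
    ).to_csv(dispersed_tsv, sep="\t", index=False)
    genome_len = sum(len(r.sequence) for r in chromosomes)
    summary = repeat_summary_table({"assembly": (pairs, genome_len)})
    repeat_summary_tsv = out / "repeat_summary.tsv"
    summary.to_csv(repeat_summary_tsv, sep="\t")
    record("repeats", "run", [ssr_tsv, tandem_tsv, dispersed_tsv, repeat_summary_tsv])

    # ---- synteny ---------------------------------------------------------
    if config.reference:
        reference = read_fasta(config.reference)[0]
        lcbs = []
        for rec in chromosomes:
            anchors = find_anchors(reference, rec, config.synteny)
            lcbs.extend(
                chain_to_lcbs(anchors, config.synteny, ref=reference, query=rec)
            )
        lcb_tsv = out / "lcbs.tsv"
        dotplot_table(lcbs).to_csv(lcb_tsv, sep="\t", index=False)
        stats = coverage_and_rearrangements(
            lcbs, {r.id: len(r.sequence) for r in chromosomes}
        )
        summary_tsv = out / "synteny_summary.tsv"
        pd.DataFrame([stats]).to_csv(summary_tsv, sep="\t", index=False)
        record("synteny", "run", [lcb_tsv, summary_tsv])
    else:
        logger.info("synteny skipped: no reference genome")
        record("synteny", "skipped")

    # ---- report ----------------------------------------------------------
    if config.annotations:
        features = read_feature_table(config.annotations)
        sizes = {r.id: len(r.sequence) for r in chromosomes}
        known = [f for f in features if all(e[0] in sizes for e in f.exons)]
        stats = run_stage("report", partition_coding, known, sizes)
        inventory = gene_inventory(known, {r.id: r for r in chromosomes})
        trans = trans_chromosomal_genes(known)
        report_tsv = out / "genome_stats.tsv"
        pd.DataFrame(
            [
                {
                    "genome_size": stats.genome_size,
                    "gc_pct": gc_content(chromosomes),
                    "coding_bp": stats.coding_bp,
                    "coding_pct": stats.coding_pct,
                    "intergenic_bp": stats.intergenic_bp,
                    "n_pcg": stats.n_pcg,
                    "n_trna": stats.n_trna,
                    "n_rrna": stats.n_rrna,
                    "cis_introns": inventory["total_cis_introns"],
                    "trans_chromosomal_genes": ",".join(sorted(trans)),
                }
            ]
        ).to_csv(report_tsv, sep="\t", index=False)
        record("report", "run", [report_tsv])
    else:
        logger.info("gene report skipped: no annotations")
        record("report", "skipped")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
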