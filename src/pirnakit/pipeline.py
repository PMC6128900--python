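"""End-to-end orchestration of the small-RNA analysis stages.

Stage order: collapse/filter reads -> map and filter alignments ->
hierarchical annotation (and 3'-tRF detection) -> ping-pong statistics
(all reads, and the mRNA-matching subset) -> piRNA cluster
prediction/merging/quantification/classification -> repeat landscapes,
enrichment and gene content -> 5'U primary-piRNA fraction estimate.
All tables are written to the output directory and summarized in a JSON
run report.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from pirnakit import __version__, align, annotate, clusters as cl, pingpong as pp
from pirnakit import reads as rd, repeats as rp

log = logging.getLogger("pirnakit")

_KNOWN_KEYS = {
    "genome", "datasets", "repeats_out", "gff3", "references",
    "seed", "outdir", "params",
}
_KNOWN_PARAM_SECTIONS = {
    "collapse", "duster", "map", "filter", "annotate", "pingpong", "clusters",
}


@dataclass
class PipelineConfig:
    genome: str
    datasets: dict[str, str]
    outdir: str
    repeats_out: str | None = None
    gff3: str | None = None
    references: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.params.get(stage, {}))

    def stage_seed(self, stage: str) -> int:
        return (self.seed ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF

    def to_dict(self) -> dict:
        return {
            "genome": self.genome,
            "datasets": self.datasets,
            "outdir": self.outdir,
            "repeats_out": self.repeats_out,
            "gff3": self.gff3,
            "references": self.references,
            "seed": self.seed,
            "params": self.params,
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("genome", "datasets", "outdir"):
        if key not in raw:
            raise ValueError(f"missing required config key: {key!r}")
    if not isinstance(raw["datasets"], dict) or not raw["datasets"]:
        raise ValueError("datasets must be a non-empty mapping label -> path")
    params = raw.get("params", {}) or {}
    bad = set(params) - _KNOWN_PARAM_SECTIONS
    if bad:
        raise ValueError(f"unknown params sections: {sorted(bad)}")
    cfg = PipelineConfig(
        genome=str(raw["genome"]),
        datasets={str(k): str(v) for k, v in raw["datasets"].items()},
        outdir=str(raw["outdir"]),
        repeats_out=raw.get("repeats_out"),
        gff3=raw.get("gff3"),
        references={str(k): str(v) for k, v in (raw.get("references") or {}).items()},
        seed=int(raw.get("seed", 0)),
        params=params,
    )
    missing = [
        p
        for p in [cfg.genome, *cfg.datasets.values(), cfg.repeats_out, cfg.gff3,
                  *cfg.references.values()]
        if p and not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"input paths not found: {missing}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-run summary of every stage's headline numbers."""

    version: str
    config: dict
    datasets: dict[str, dict] = field(default_factory=dict)
    clusters: dict[str, Any] = field(default_factory=dict)
    repeats: dict[str, Any] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "datasets": self.datasets,
                    "clusters": self.clusters,
                    "repeats": self.repeats,
                    "skipped": self.skipped,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _load_reads(path: str) -> rd.RawReadSet:
    p = path[:-3] if path.endswith(".gz") else path
    if p.endswith((".fastq", ".fq")):
        return rd.read_fastq(path)
    return rd.read_fasta(path)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=config.to_dict())
    if not config.datasets:
        raise ValueError("config has no datasets")

    genome = align.Genome.from_fasta(config.genome)
    refs = [
        annotate.ReferenceSet.from_fasta(cls, path)
        for cls, path in config.references.items()
    ]
    p_collapse = config.stage_params("collapse")
    p_duster = config.stage_params("duster")
    p_map = config.stage_params("map")
    p_filter = config.stage_params("filter")
    p_pp = config.stage_params("pingpong")
    p_cl = config.stage_params("clusters")
    k = int(p_cl.pop("k", 4))
    top_n = int(p_cl.pop("top_n", 100))

    mapped_by_ds: dict[str, align.MappedReadSet] = {}
    intergenic_by_ds: dict[str, align.MappedReadSet] = {}
    candidates = []
    for label, path in config.datasets.items():
        ds_dir = outdir / label
        ds_dir.mkdir(exist_ok=True)
        stage = f"{label}:reads"
        raw = _load_reads(path)
        collapsed = rd.collapse_and_filter(raw, **p_collapse)
        filtered = rd.filter_low_complexity(collapsed, **p_duster)
        log.info("%s: %d raw -> %d collapsed -> %d after duster",
                 stage, len(raw), len(collapsed), len(filtered))
        rd.write_collapsed_fasta(filtered, ds_dir / "collapsed.fa")

        alns = align.map_reads(filtered, genome, **p_map)
        mapped = align.filter_alignments(alns, all_reads=filtered, **p_filter)
        mapped_by_ds[label] = mapped
        align.write_alignment_table(mapped, ds_dir / "alignments.tsv")
        log.info("%s: %d reads mapped, %d unmapped",
                 label, len(mapped.reads), len(mapped.unmapped))

        records = annotate.annotate_reads(mapped.reads, refs) if refs else [
            annotate.AnnotationRecord(r, annotate.INTERGENIC) for r in mapped.reads
        ]
        trna = next((r for r in refs if r.class_name == "tRNA"), None)
        if trna is not None:
            annotate.detect_3p_trfs(records, trna)
        summary = annotate.class_summary(records)
        annotate.write_annotation_tsv(records, ds_dir / "annotation.tsv")
        annotate.write_class_summary_tsv(summary, ds_dir / "class_summary.tsv")

        hist = pp.overlap_histogram(mapped)
        z10, pval = pp.zscore_pvalue(hist)
        stats = pp.bootstrap_pingpong(
            mapped, seed=config.stage_seed(f"pingpong:{label}"), **p_pp
        )
        matrix = pp.pingpong_matrix(mapped)
        pair_reads = pp.pingpong_pair_reads(mapped)
        bias = pp.base_bias_bits(pair_reads) if pair_reads else None
        pp.write_histogram_tsv(hist, ds_dir / "pingpong_histogram.tsv")
        pp.write_stats_tsv(stats, ds_dir / "pingpong_stats.tsv")
        pp.write_matrix_tsv(matrix, ds_dir / "pingpong_matrix.tsv")

        mrna_stats = {}
        if any(r.class_name == "mRNA" for r in refs):
            mrna_seqs = {
                rec.read.sequence for rec in records if rec.assigned_class == "mRNA"
            }
            if mrna_seqs:
                sub = mapped.subset(mrna_seqs)
                zm, pm = pp.zscore_pvalue(pp.overlap_histogram(sub))
                mrna_stats = {"z10": zm, "p_value": pm}

        intergenic = {
            rec.read.sequence
            for rec in records
            if rec.assigned_class == annotate.INTERGENIC
        }
        inter_mapped = mapped.subset(intergenic)
        intergenic_by_ds[label] = inter_mapped
        cands = cl.predict_clusters(
            inter_mapped,
            total_mapped_count=mapped.total_count,
            dataset=label,
            **p_cl,
        )
        candidates.append(cands)

        report.datasets[label] = {
            "n_raw": len(raw),
            "n_collapsed": len(collapsed),
            "n_after_duster": len(filtered),
            "n_mapped_reads": len(mapped.reads),
            "n_unmapped": len(mapped.unmapped),
            "total_mapped_count": mapped.total_count,
            "class_summary": summary,
            "pingpong": {
                "z10": z10,
                "p_value": pval,
                "pps_mbr": stats.pps_mbr,
                "ppr_mbr": stats.ppr_mbr,
                "pps_sd": stats.pps_sd,
                "ppr_sd": stats.ppr_sd,
            },
            "pingpong_mrna_subset": mrna_stats,
            "pingpong_mode_cell": matrix.mode_cell,
            "bias_bits": {"1U": bias.bits_1U, "10A": bias.bits_10A} if bias else None,
            "n_cluster_candidates": len(cands),
        }

    merged = cl.merge_clusters(candidates)
    matrix = cl.quantify_clusters(merged, mapped_by_ds)
    try:
        cl.classify_expression(matrix, k=min(k, len(merged)), top_n=top_n)
        report.clusters["n_classes"] = min(k, len(merged))
    except ValueError as exc:
        report.skipped["classify_expression"] = str(exc)
    cl.write_bed(merged, outdir / "clusters.bed")
    cl.write_gff3(merged, outdir / "clusters.gff3")
    matrix.rpm.to_csv(outdir / "cluster_rpm.tsv", sep="\t")
    report.clusters.update(
        {
            "n_clusters": len(merged),
            "total_bp": sum(c.length for c in merged),
            "clustered_fraction": matrix.clustered_fraction,
        }
    )

    # primary-piRNA fraction estimate per dataset, using cluster-mapped reads
    for label, mapped in mapped_by_ds.items():
        clustered_seqs = set()
        for a in intergenic_by_ds[label].alignments:
            for c in merged:
                if a.chrom == c.chrom and c.start <= a.five_prime < c.end:
                    clustered_seqs.add(a.read.sequence)
                    break
        records_path = outdir / label / "annotation.tsv"
        recs = _reload_annotation(records_path, mapped)
        try:
            est = annotate.estimate_primary_fraction(
                recs, [r for r in mapped.reads if r.sequence in clustered_seqs]
            )
            report.datasets[label]["primary_fraction"] = {
                "u_obs": est.u_obs, "u_bg": est.u_bg, "u_ref": est.u_ref,
                "f_pi": est.f_pi, "undefined": est.undefined,
            }
        except ValueError as exc:
            report.skipped[f"primary_fraction:{label}"] = str(exc)

    if config.repeats_out:
        annot = rp.parse_repeatmasker_out(config.repeats_out)
        ls_genome = rp.te_landscape(annot)
        ls_cluster = rp.te_landscape(
            annot, [(c.chrom, c.start, c.end) for c in merged]
        )
        rp.write_landscape_tsv(ls_genome, outdir / "te_landscape_genome.tsv")
        rp.write_landscape_tsv(ls_cluster, outdir / "te_landscape_clusters.tsv")
        if merged:
            et = rp.enrichment_fold(annot, merged, genome.total_length)
            rp.write_enrichment_tsv(et, outdir / "te_enrichment.tsv")
            rp.cluster_repeat_content(annot, merged)
            report.repeats = {
                "genome_repeat_content": et.genome_repeat_content,
                "cluster_repeat_content": et.cluster_repeat_content,
                "top_enriched": et.table["fold"].head(5).to_dict(),
            }
        else:
            report.skipped["te_enrichment"] = "no clusters"
    else:
        report.skipped["repeats"] = "no RepeatMasker .out provided"

    if config.gff3 and merged:
        _, aggregate = rp.gene_content(merged, config.gff3)
        report.clusters["gene_content"] = aggregate
    elif not config.gff3:
        report.skipped["gene_content"] = "no GFF3 provided"

    report.save(outdir / "report.json")
    dump_config(config, outdir / "config_snapshot.yaml")
    return report


def _reload_annotation(path: Path, mapped: align.MappedReadSet):
    """Rebuild AnnotationRecords for the estimator from the written TSV."""
    by_seq = {r.sequence: r for r in mapped.reads}
    recs = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            seq, _count, cls, subtype, ref = line.rstrip("\n").split("\t")
            if seq in by_seq:
                recs.append(annotate.AnnotationRecord(by_seq[seq], cls, subtype, ref))
    return recs
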