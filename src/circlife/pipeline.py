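"""End-to-end orchestration: classify -> quantify -> targets -> network.

The pipeline consumes files only (genome FASTA, GFF3, BSJ table, count
matrices, miRNA FASTA, known-circRNA list), runs every stage with the
thresholds from one :class:`PipelineConfig`, and writes per-stage outputs
plus a single JSON report. Identical config and inputs give byte-identical
outputs; timings go to the log, never into the report.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import annotate, io_formats, network, quantify, sponge_targets
from .quantify import StageConfig, Stage, default_stage_config

log = logging.getLogger("circlife")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    gff3: str
    genome_fasta: str
    bsj_table: str
    gene_counts: str
    mirna_counts: str
    mirna_fasta: str
    outdir: str
    known_circs: str | None = None
    library_sizes: str | None = None   # sidecar; else embedded library_size rows
    stage_config: StageConfig = field(default_factory=default_stage_config)
    fc_threshold: float = 2.0
    min_samples: int = 2
    min_reads: int = 1
    boundary_tolerance: int = 0
    novelty_slack: int = 0
    cutoff_mrna: float = 4.0
    cutoff_circ: float = 4.5
    rho_max: float = -0.5
    gate_mirna: float = 1.0
    gate_circ: float = 2.0
    gate_mrna: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stage_config" in raw:
            sc = raw["stage_config"]
            raw["stage_config"] = StageConfig(
                time_points=tuple(sc["time_points"]),
                stages=tuple(
                    Stage(s["name"], tuple(s["days"]), s["reference"])
                    for s in sc["stages"]
                ),
            )
        return cls(**raw)

    def validate_paths(self) -> None:
        fields = ["gff3", "genome_fasta", "bsj_table", "gene_counts",
                  "mirna_counts", "mirna_fasta", "known_circs", "library_sizes"]
        for name in fields:
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise PipelineError(f"config: input path for {name!r} does not exist: {p}")


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage's name."""
    class _Guard:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False
    return _Guard()


def run_all(config: PipelineConfig) -> dict:
    """Run the whole pipeline; returns the report dict (also written to disk)."""
    config.validate_paths()
    os.makedirs(config.outdir, exist_ok=True)
    cfg = config.stage_config
    labels = cfg.sample_labels

    with _stage("load"):
        annotation = io_formats.read_gff3(config.gff3)
        genome = io_formats.read_fasta(config.genome_fasta)
        junctions = io_formats.read_bsj_table(config.bsj_table, len(labels))
        gene_raw, gene_lib = io_formats.read_count_matrix(
            config.gene_counts, config.library_sizes
        )
        mirna_raw, mirna_lib = io_formats.read_count_matrix(
            config.mirna_counts, config.library_sizes
        )
        mirna_seqs = io_formats.read_fasta(config.mirna_fasta)
        known = (
            io_formats.read_known_circs(config.known_circs)
            if config.known_circs
            else None
        )

    with _stage("classify"):
        records = [
            annotate.classify_bsj(j, annotation, config.boundary_tolerance)
            for j in junctions
        ]
        if known is not None:
            records = annotate.flag_novel(records, known, config.novelty_slack)
        summary = annotate.summarize_classes(records)
        _write_records(records, os.path.join(config.outdir, "records.tsv"))

    with _stage("quantify"):
        circ_raw = pd.DataFrame(
            [list(j.counts) for j in junctions],
            index=[j.circ_id for j in junctions],
            columns=labels,
        )
        # back-splice reads come from the same libraries as the linear genes
        circ_expr = quantify.normalize_expression(circ_raw, gene_lib)
        gene_expr = quantify.normalize_expression(gene_raw, gene_lib)
        mirna_expr = quantify.normalize_expression(mirna_raw, mirna_lib)

        detection = quantify.detection_summary(
            circ_raw, cfg, config.min_samples, config.min_reads
        )
        retained = detection.retained

        circ_fc, circ_de = {}, {}
        gene_fc, gene_de = {}, {}
        mirna_fc, mirna_de = {}, {}
        for st in cfg.stage_names:
            circ_fc[st] = quantify.log2_fold_changes(circ_expr, cfg, st).loc[retained]
            circ_de[st] = quantify.call_de(circ_fc[st], config.fc_threshold)
            gene_fc[st] = quantify.log2_fold_changes(gene_expr, cfg, st)
            gene_de[st] = quantify.call_de(gene_fc[st], config.fc_threshold)
            mirna_fc[st] = quantify.log2_fold_changes(mirna_expr, cfg, st)
            mirna_de[st] = quantify.call_de(mirna_fc[st], config.fc_threshold)
            circ_de[st].to_csv(
                os.path.join(config.outdir, f"de_circ_{_safe(st)}.tsv"), sep="\t"
            )
        _write_detection(detection, os.path.join(config.outdir, "detection.tsv"))

    with _stage("host_concordance"):
        host_map = {
            r.circ_id: r.host_gene for r in records if r.host_gene is not None
        }
        concordance = quantify.host_concordance(
            circ_de, gene_de, circ_expr, gene_expr, host_map
        )

    with _stage("targets"):
        rec_by_id = {r.circ_id: r for r in records}
        gated_circ = {
            st: network.gate_features(circ_fc[st], config.gate_circ)
            for st in cfg.stage_names
        }
        gated_mrna = {
            st: network.gate_features(gene_fc[st], config.gate_mrna)
            for st in cfg.stage_names
        }
        gated_mirna = {
            st: network.gate_features(mirna_fc[st], config.gate_mirna)
            for st in cfg.stage_names
        }
        circ_union = sorted(set().union(*gated_circ.values()))
        mrna_union = sorted(set().union(*gated_mrna.values()))
        mirna_union = sorted(set().union(*gated_mirna.values()))

        circ_seqs = {}
        for cid in circ_union:
            seq, _window = annotate.extract_circ_sequence(
                rec_by_id[cid], genome, annotation
            )
            circ_seqs[cid] = seq
        mrna_seqs = {
            gid: annotate.extract_transcript(annotation.genes[gid], genome)
            for gid in mrna_union
            if gid in annotation.genes
        }
        scan_mirnas = {m: mirna_seqs[m] for m in mirna_union if m in mirna_seqs}

        kinds = {cid: "circRNA" for cid in circ_seqs}
        kinds.update({gid: "mRNA" for gid in mrna_seqs})
        cutoffs = {"mRNA": config.cutoff_mrna, "circRNA": config.cutoff_circ}
        hits = sponge_targets.predict_targets(
            scan_mirnas, {**circ_seqs, **mrna_seqs}, kinds, cutoffs
        )
        circ_hits = [h for h in hits if h.kind == "circRNA"]
        mrna_hits = [h for h in hits if h.kind == "mRNA"]
        target_expr = pd.concat([circ_expr.normalized, gene_expr.normalized])
        circ_filtered = sponge_targets.anticorrelation_filter(
            circ_hits, mirna_expr.normalized, target_expr, config.rho_max
        )
        mrna_filtered = sponge_targets.anticorrelation_filter(
            mrna_hits, mirna_expr.normalized, target_expr, config.rho_max
        )

    with _stage("network"):
        triplets = {}
        for st in cfg.stage_names:
            triplets[st] = network.assemble_triplets(
                circ_filtered, mrna_filtered,
                gated_circ[st], gated_mrna[st], gated_mirna[st], st,
            )
            io_formats.write_network(
                triplets[st], os.path.join(config.outdir, f"network_{_safe(st)}.sif"), "sif"
            )
            io_formats.write_network(
                triplets[st], os.path.join(config.outdir, f"network_{_safe(st)}.tsv"), "tsv"
            )
        net_stats = network.network_stats(triplets)

    with _stage("report"):
        de_block = {}
        de_sets = {}
        for st in cfg.stage_names:
            d = circ_de[st]
            de_ids = [str(i) for i in d.index[d["is_de"]]]
            de_sets[st] = set(de_ids)
            de_block[st] = {
                "n_de": len(de_ids),
                "n_up": int(((d["is_de"]) & (d["direction"] == "up")).sum()),
                "n_down": int(((d["is_de"]) & (d["direction"] == "down")).sum()),
            }
        shared_de = len(set.intersection(*de_sets.values())) if de_sets else 0

        report = {
            "classification": {
                "total": summary.total,
                "counts": {c.value: n for c, n in summary.counts.items()},
                "percentages": {c.value: p for c, p in summary.percentages.items()},
                "exonic_count": summary.exonic_count,
                "exonic_pct": summary.exonic_pct,
                "pct_of_exonic": {c.value: p for c, p in summary.pct_of_exonic.items()},
                "exonic_span_1_5": summary.exonic_span_1_5,
                "pct_span_1_5": summary.pct_span_1_5,
                "organelle_counts": summary.organelle_counts,
                "novelty_counts": summary.novelty_counts,
            },
            "detection": {
                "n_singletons": detection.n_singletons,
                "pct_singletons": detection.pct_singletons,
                "n_gt10": detection.n_gt10,
                "pct_gt10": detection.pct_gt10,
                "n_retained": len(detection.retained),
                "stage_sizes": {k: len(v) for k, v in detection.stage_sets.items()},
                "stage_pcts": detection.stage_pcts,
                "intersection": detection.intersection,
                "union": detection.union,
                "intersection_exclusive": detection.intersection_exclusive,
            },
            "de": {**de_block, "shared": shared_de},
            "host_concordance": {
                st: {
                    "n_up_circ": c.n_up_circ,
                    "n_concordant": c.n_concordant,
                    "fraction": c.fraction,
                }
                for st, c in concordance.per_stage.items()
            },
            "network": net_stats,
        }
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")
    return report


def _safe(name: str) -> str:
    return name.replace("/", "_").replace(" ", "_")


def _write_records(records, path: str) -> None:
    cols = ["chrom", "start", "end", "strand", "category", "host_gene",
            "exon_span", "organelle", "is_novel"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            j = r.junction
            novel = "" if r.is_novel is None else str(r.is_novel)
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{r.category.value}\t"
                f"{r.host_gene or ''}\t{r.exon_span}\t{r.organelle}\t{novel}\n"
            )


def _write_detection(det, path: str) -> None:
    out = det.detection.to_frame("n_samples_detected")
    out["retained"] = out.index.astype(str).isin(set(det.retained))
    for stage, members in det.stage_sets.items():
        out[f"detected_{_safe(stage)}"] = out.index.astype(str).isin(members)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def config_to_yaml(config: PipelineConfig, path: str) -> None:
    """Serialize a config (stage windows included) back to YAML."""
    d = asdict(config)
    sc = config.stage_config
    d["stage_config"] = {
        "time_points": list(sc.time_points),
        "stages": [
            {"name": s.name, "days": list(s.days), "reference": s.reference}
            for s in sc.stages
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
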