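"""End-to-end orchestration: simulate -> classify -> quantify -> diffexp ->
apa -> correlate -> isoforms, with per-stage TSV outputs, a machine-readable
summary, and a run log carrying the seed and a hash of the serialized config.

Stages communicate only through their written/returned artifacts; re-running a
stage from the same upstream artifacts reproduces its outputs exactly, and two
runs with the same config and seed produce byte-identical summaries.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import apa as apa_mod
from . import correlate as corr_mod
from . import diffexp as de_mod
from . import io as io_mod
from . import isoforms as iso_mod
from . import quantify as q_mod
from . import synthetic as syn_mod
from .catalog import (
    AnnotationTrackSet,
    ConfidenceThresholds,
    TranscriptCatalog,
    classification_report,
)
from .errors import ConfigurationError, StageError

ALL_STAGES = ("simulate", "classify", "quantify", "diffexp", "apa", "correlate", "isoforms")


@dataclass
class RunConfig:
    """Everything a reproducible run needs, serializable to YAML."""

    outdir: str = "strandtx_run"
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    # external inputs (all optional when the simulate stage is on)
    annotation_gtf: Optional[str] = None
    cleavage_bed: Optional[str] = None
    alignments_tsv: Optional[str] = None
    counts_tsv: Optional[str] = None
    groups: Dict[str, str] = field(default_factory=dict)
    # simulation
    sim: syn_mod.SimConfig = field(default_factory=syn_mod.SimConfig)
    use_default_effects: bool = True
    # thresholds
    expression_filter: de_mod.ExpressionFilter = field(default_factory=de_mod.ExpressionFilter)
    confidence: ConfidenceThresholds = field(default_factory=ConfidenceThresholds)
    apa_thresholds: apa_mod.ApaThresholds = field(default_factory=apa_mod.ApaThresholds)
    shift_thresholds: iso_mod.ShiftThresholds = field(default_factory=iso_mod.ShiftThresholds)
    neighbor_spec: corr_mod.NeighborBinSpec = field(default_factory=corr_mod.NeighborBinSpec)
    loess_span: float = 0.5
    de_p_cutoff: float = 0.01
    de_q_cutoff: float = 0.2

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for sample, group in self.groups.items():
            if group not in ("control", "case"):
                raise ConfigurationError(
                    f"sample {sample!r} must be in exactly one of control|case, got {group!r}"
                )

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        payload["stages"] = list(self.stages)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        for key, typ in (
            ("sim", syn_mod.SimConfig),
            ("expression_filter", de_mod.ExpressionFilter),
            ("confidence", ConfidenceThresholds),
            ("apa_thresholds", apa_mod.ApaThresholds),
            ("shift_thresholds", iso_mod.ShiftThresholds),
            ("neighbor_spec", corr_mod.NeighborBinSpec),
        ):
            if key in payload and isinstance(payload[key], dict):
                sub = payload[key]
                for f_ in dataclasses.fields(typ):
                    if f_.name in sub and isinstance(sub[f_.name], list):
                        sub[f_.name] = tuple(sub[f_.name])
                payload[key] = typ(**sub)
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        if "neighbor_spec" in payload and isinstance(payload["neighbor_spec"], dict):
            payload["neighbor_spec"] = corr_mod.NeighborBinSpec(**payload["neighbor_spec"])
        return cls(**payload)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


@dataclass
class RunResult:
    outdir: Path
    summary: Dict[str, object]
    tables: Dict[str, pd.DataFrame]


def _config_hash(config: RunConfig) -> str:
    payload = yaml.safe_load(config.to_yaml())
    payload.pop("outdir", None)  # the hash identifies the analysis, not its destination
    return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


def run(config: RunConfig) -> RunResult:
    """Execute the configured stages; see the module docstring.

    On stage failure a FAILED marker naming the stage is written next to any
    partial outputs and a :class:`StageError` is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log(f"strandtx run; seed={config.seed}; config_hash={_config_hash(config)}")
    log(f"python={sys.version.split()[0]} numpy={np.__version__} pandas={pd.__version__}")
    (outdir / "config.yaml").write_text(config.to_yaml())

    stages = set(config.stages)
    tables: Dict[str, pd.DataFrame] = {}
    summary: Dict[str, object] = {"seed": config.seed, "config_hash": _config_hash(config)}

    catalog: Optional[TranscriptCatalog] = None
    sites = None
    alignments = None
    tcounts = None  # transcript-level sense counts
    anticounts = None
    groups = dict(config.groups)
    apa_usage = None
    truth = None
    current = "setup"

    try:
        if "simulate" in stages:
            current = "simulate"
            catalog, sites = syn_mod.generate_catalog(config.sim, seed=config.seed)
            effects = (
                syn_mod.default_effects(catalog, sites, seed=config.seed)
                if config.use_default_effects
                else syn_mod.EffectSpec()
            )
            sim, truth = syn_mod.simulate_counts(
                catalog, config.sim, effects, seed=config.seed, sites=sites
            )
            alignments = syn_mod.simulate_alignments(
                catalog, sim, config.sim, seed=config.seed, sites=sites
            )
            tcounts, anticounts, groups = sim.sense, sim.antisense, sim.groups
            io_mod.write_gtf(catalog, outdir / "annotation.gtf")
            io_mod.write_cleavage_bed(sites, outdir / "cleavage_sites.bed")
            io_mod.write_alignments(alignments, outdir / "alignments.tsv")
            io_mod.write_counts(tcounts, outdir / "counts_sense.tsv")
            io_mod.write_counts(anticounts, outdir / "counts_antisense.tsv")
            io_mod.write_ground_truth(truth, outdir / "ground_truth.yaml")
            log(f"simulate: {len(catalog)} transcripts, {len(alignments)} reads")
        else:
            current = "setup"
            if config.annotation_gtf:
                catalog = io_mod.read_gtf(config.annotation_gtf)
            if config.cleavage_bed:
                sites = io_mod.read_cleavage_bed(config.cleavage_bed)
            if config.alignments_tsv:
                alignments = io_mod.read_alignments(config.alignments_tsv)
            if config.counts_tsv:
                tcounts = io_mod.read_counts(config.counts_tsv)
            if not groups and tcounts is not None:
                raise ConfigurationError("group assignment required when not simulating")

        if "classify" in stages:
            current = "classify"
            if catalog is None:
                raise ConfigurationError("classify stage needs an annotation")
            known = catalog.subset(
                lambda t: t.major_class not in ("novel_locus", "novel_isoform")
            )
            queries = [
                t for t in catalog if t.major_class in ("novel_locus", "novel_isoform")
            ]
            tracks = AnnotationTrackSet.from_dict({"reference": known})
            unique_counts = (
                tcounts
                if tcounts is not None
                else pd.DataFrame(index=[t.transcript_id for t in queries])
            )
            report = classification_report(
                queries, known, tracks, unique_counts, config.confidence,
                read_length=config.sim.read_length,
            )
            tables["classification"] = report
            report.to_csv(outdir / "classification.tsv", sep="\t", index=False)
            if len(report):
                summary["classify"] = {
                    "n_queries": int(len(report)),
                    "codes": {k: int(v) for k, v in report["code"].value_counts().items()},
                    "n_high_novelty": int(report["high_novelty"].sum()),
                    "n_high_confidence": int(report["high_confidence"].sum()),
                }
            log(f"classify: {len(report)} queries")

        if "quantify" in stages:
            current = "quantify"
            if catalog is None or alignments is None:
                raise ConfigurationError("quantify stage needs annotation and alignments")
            cm = q_mod.count(alignments, catalog, samples=sorted(groups))
            cls_summary = q_mod.summarize_classes(cm, catalog)
            tables["gene_counts"] = cm.gene
            tables["antisense_counts"] = cm.antisense
            tables["class_totals"] = cls_summary.totals
            io_mod.write_counts(cm.sense, outdir / "quantified_sense.tsv")
            io_mod.write_counts(cm.gene, outdir / "quantified_gene.tsv")
            io_mod.write_counts(cm.antisense, outdir / "quantified_antisense.tsv")
            cls_frame = cls_summary.totals.copy()
            cls_frame["length"] = cls_summary.length
            cls_frame["concentration"] = cls_summary.concentration
            cls_frame.to_csv(outdir / "class_summary.tsv", sep="\t", index_label="class")
            summary["quantify"] = {
                "n_reads": int(len(alignments)),
                "n_excluded": int(cm.excluded.values.sum()),
            }
            log(f"quantify: {len(alignments)} reads")

        if "diffexp" in stages:
            current = "diffexp"
            if tcounts is None:
                raise ConfigurationError("diffexp stage needs a counts matrix")
            de = de_mod.de_table(
                tcounts, groups, filt=config.expression_filter, span=config.loess_span
            )
            de["rna_class"] = [
                catalog.get(t).rna_class if (catalog is not None and t in catalog) else ""
                for t in de.index
            ]
            tables["diffexp"] = de
            de.to_csv(outdir / "diffexp.tsv", sep="\t", index_label="id")
            flagged = de[(de["p"] < config.de_p_cutoff) & (de["q"] < config.de_q_cutoff)]
            summary["diffexp"] = {
                "n_tested": int(len(de)),
                "n_de": int(len(flagged)),
            }
            if catalog is not None:
                norm, _ = de_mod.normalize_totals(
                    tcounts.loc[de_mod.filter_expressed(tcounts, config.expression_filter)]
                )
                changes = {}
                for cls in ("coding", "lncRNA", "smallRNA", "repeat", "novel_locus",
                            "smallRNA:priMiRNA"):
                    try:
                        cc = de_mod.class_change(norm, catalog, cls, groups)
                    except ValueError:
                        continue
                    changes[cls] = {"percent_change": round(cc.percent_change * 100, 2),
                                    "p": cc.p}
                summary["class_changes"] = changes
                pd.DataFrame(changes).T.to_csv(outdir / "class_changes.tsv", sep="\t",
                                               index_label="class")
            log(f"diffexp: {summary['diffexp']}")

        if "apa" in stages:
            current = "apa"
            if sites is None or alignments is None:
                raise ConfigurationError("apa stage needs cleavage sites and alignments")
            apa_frame, skipped = apa_mod.apa_analysis(
                sites, alignments, groups, config.apa_thresholds
            )
            tables["apa"] = apa_frame
            apa_frame.to_csv(outdir / "apa.tsv", sep="\t", index=False)
            calls = apa_frame["call"].value_counts() if len(apa_frame) else {}
            summary["apa"] = {
                "n_genes": int(len(apa_frame)),
                "n_unanalyzable": int(skipped),
                "n_longer": int(calls.get("longer", 0)),
                "n_shorter": int(calls.get("shorter", 0)),
            }
            log(f"apa: {summary['apa']}")

        if "correlate" in stages:
            current = "correlate"
            if tcounts is None or catalog is None:
                raise ConfigurationError("correlate stage needs counts and annotation")
            norm, _ = de_mod.normalize_totals(tcounts)
            # gene-level sense counts for coding genes
            coding_genes = [g for g in catalog.gene_ids if catalog.gene_class(g) == "coding"]
            gene_sense = pd.DataFrame(
                {
                    g: norm.loc[
                        [t.transcript_id for t in catalog.transcripts_of_gene(g)
                         if t.transcript_id in norm.index]
                    ].sum(axis=0)
                    for g in coding_genes
                }
            ).T
            if anticounts is not None and len(anticounts):
                anti_norm, _ = de_mod.normalize_totals(tcounts)  # same factors scale both
                anti = anticounts.reindex(gene_sense.index).fillna(0)
                sa_frame, sa_summary = corr_mod.sense_antisense_profile(
                    gene_sense, anti, groups
                )
                tables["sense_antisense"] = sa_frame
                sa_frame.to_csv(outdir / "sense_antisense.tsv", sep="\t")
                summary["sense_antisense"] = sa_summary
            lnc_ids = [t.transcript_id for t in catalog.by_class("lncRNA")
                       if t.transcript_id in norm.index]
            if lnc_ids:
                binned, baseline, pair_frame = corr_mod.neighbor_correlation(
                    catalog, norm.loc[lnc_ids], gene_sense, groups,
                    config.neighbor_spec, seed=config.seed,
                )
                tables["lnc_neighbors"] = binned
                binned.to_csv(outdir / "lnc_neighbor_bins.tsv", sep="\t", index=False)
                summary["lnc_neighbors"] = {
                    "random_pair_baseline": baseline,
                    "n_pairs": int(len(pair_frame)),
                }
            if truth is not None and truth.target_sets and "diffexp" in tables:
                stat = tables["diffexp"]["log2fc"]
                gene_stat = stat.groupby(
                    [catalog.get(t).gene_id for t in stat.index]
                ).mean()
                coding_stat = gene_stat[gene_stat.index.isin(coding_genes)]
                shift = corr_mod.target_set_shift(truth.target_sets, coding_stat)
                tables["target_sets"] = shift
                shift.to_csv(outdir / "target_sets.tsv", sep="\t")
                summary["target_sets"] = {
                    name: {"mean": row["mean"], "p": row["p"]}
                    for name, row in shift.iterrows()
                }
            log("correlate: done")

        if "isoforms" in stages:
            current = "isoforms"
            if tcounts is None or catalog is None:
                raise ConfigurationError("isoforms stage needs counts and annotation")
            props, skipped = iso_mod.isoform_proportions(
                tcounts, catalog, groups, config.shift_thresholds
            )
            tables["isoforms"] = props
            props.to_csv(outdir / "isoform_shifts.tsv", sep="\t", index=False)
            complexity = iso_mod.exon_complexity_compare(props, catalog)
            flagged_genes = sorted(props.loc[props["flagged"], "gene_id"].unique())
            summary["isoforms"] = {
                "n_genes_tested": int(props["gene_id"].nunique()),
                "n_skipped": int(skipped),
                "n_flagged_genes": len(flagged_genes),
                "exon_complexity_diff": complexity.mean_diff,
                "exon_complexity_p": complexity.p,
            }
            log(f"isoforms: {summary['isoforms']}")

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        (outdir / "run.log").write_text("\n".join(log_lines) + f"\nFAILED at {current}: {exc}\n")
        raise StageError(current, exc) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True,
                                                    default=float) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return RunResult(outdir=outdir, summary=summary, tables=tables)
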