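"""End-to-end orchestration: lncRNA catalog -> DE gate -> duplex discovery
(spliced and pre-mRNA spaces) -> mechanism annotation -> condition-specific
filter -> summaries.

Given identical configuration and inputs the pipeline is fully deterministic;
the run log (timings) is the only output that varies between reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from . import cohort_stats, duplex_align, lnc_identify, mechanisms
from .genomic_model import (
    AnnotationTrack,
    ScoringParams,
    premrna_sequence,
    read_bed,
    read_expression,
    read_fasta,
    read_gtf,
    spliced_sequence,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    genome: str
    gtf: str
    tpm: str
    groups: str
    de_tables: Dict[str, str]
    outdir: str
    clip: Optional[str] = None
    alu: Optional[str] = None
    editing: Optional[str] = None
    mirnas: Optional[str] = None
    params: Dict[str, float] = field(default_factory=dict)
    excluded_biotypes: Optional[List[str]] = None
    stranded: bool = False
    span_region: bool = False
    de_mode: str = "intersection"

    def scoring_params(self) -> ScoringParams:
        base = ScoringParams().to_dict()
        base.update(self.params)
        return ScoringParams.from_dict(base)

    def validate(self) -> None:
        required = {"genome": self.genome, "gtf": self.gtf, "tpm": self.tpm,
                    "groups": self.groups}
        required.update({f"de_tables[{k}]": v for k, v in self.de_tables.items()})
        for label, path in required.items():
            if not os.path.exists(path):
                raise PipelineError(f"config: {label} path {path!r} does not exist")
        for label, path in (("clip", self.clip), ("alu", self.alu),
                            ("editing", self.editing), ("mirnas", self.mirnas)):
            if path is not None and not os.path.exists(path):
                raise PipelineError(f"config: {label} path {path!r} does not exist")
        if not self.de_tables:
            raise PipelineError("config: at least one DE table is required")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise PipelineError(f"config: unknown keys {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def config_for_dataset(dataset_dir: str, outdir: str, **overrides) -> PipelineConfig:
    """Pipeline configuration pointing at a synthetic dataset directory."""
    d = dataset_dir
    cfg = PipelineConfig(
        genome=os.path.join(d, "genome.fa"),
        gtf=os.path.join(d, "annotation.gtf"),
        tpm=os.path.join(d, "expression_tpm.tsv"),
        groups=os.path.join(d, "sample_groups.tsv"),
        de_tables={
            "deseq2": os.path.join(d, "de_deseq2.tsv"),
            "edger": os.path.join(d, "de_edger.tsv"),
        },
        clip=os.path.join(d, "clip.bed"),
        alu=os.path.join(d, "alu.bed"),
        editing=os.path.join(d, "editing.bed"),
        mirnas=os.path.join(d, "mirnas.fa"),
        outdir=outdir,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _stage(name: str, timings: List[Tuple[str, float]]):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings.append((name, dt))
            if exc is not None:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute all stages and write the output tables; returns a report with
    the in-memory results (catalog, records, summaries, file paths)."""
    config.validate()
    params = config.scoring_params()
    os.makedirs(config.outdir, exist_ok=True)
    timings: List[Tuple[str, float]] = []
    excluded = (
        set(config.excluded_biotypes)
        if config.excluded_biotypes is not None
        else None
    )

    with _stage("load_inputs", timings):
        genome = read_fasta(config.genome)
        genes = read_gtf(config.gtf)
        expr = read_expression(config.tpm, config.groups)
        de_tables = [
            cohort_stats.read_de_table(path, method)
            for method, path in sorted(config.de_tables.items())
        ]
        tracks = mechanisms.MechanismTracks(
            clip=read_bed(config.clip, "clip") if config.clip else None,
            alu=read_bed(config.alu, "alu") if config.alu else None,
            editing=read_bed(config.editing, "editing") if config.editing else None,
        )
        mirnas = read_fasta(config.mirnas) if config.mirnas else None

    with _stage("identify_lncrnas", timings):
        catalog = lnc_identify.build_lnc_catalog(
            genes, genome, expr, params, excluded
        )
        lnc_ids = {d.transcript_id for d in catalog if d.is_lncrna}
        lnc_gene_ids = {d.gene_id for d in catalog if d.is_lncrna}

    with _stage("de_gate", timings):
        de = cohort_stats.de_gate(de_tables, params, config.de_mode)

    with _stage("duplex_discovery", timings):
        tx_index = {t.transcript_id: t for g in genes for t in g.transcripts}
        lnc_seqs = {
            tid: spliced_sequence(tx_index[tid], genome) for tid in sorted(lnc_ids)
        }
        target_ids = sorted(
            t.transcript_id
            for g in genes
            for t in g.transcripts
            if g.gene_id in de and t.transcript_id not in lnc_ids
        )
        spliced_targets = {
            tid: (spliced_sequence(tx_index[tid], genome), "spliced")
            for tid in target_ids
        }
        premrna_targets = {
            tid: (
                premrna_sequence(tx_index[tid], genome, params.intron_margin),
                "premrna",
            )
            for tid in target_ids
            if len(tx_index[tid].exons) > 1
        }
        duplexes = duplex_align.enumerate_interactions(
            lnc_seqs, spliced_targets, params
        ) + duplex_align.enumerate_interactions(lnc_seqs, premrna_targets, params)
        for d in duplexes:
            d.genome_blocks = mechanisms.transcript_to_genome(
                tx_index[d.target_id], d.target_span[0], d.target_span[1],
                d.target_space,
            )

    with _stage("mechanism_annotation", timings):
        records = mechanisms.annotate_interactions(
            duplexes,
            genes,
            tracks,
            mirnas=mirnas,
            genome=genome,
            params=params,
            span_region=config.span_region,
            stranded=config.stranded,
        )

    with _stage("condition_specific_filter", timings):
        cs_records = cohort_stats.condition_specific(records, expr, params)

    with _stage("summaries", timings):
        summary = {
            "n_transcripts": sum(len(g.transcripts) for g in genes),
            "n_lncrnas": len(lnc_ids),
            "n_de_genes": len(de),
            "n_scanned_targets": len(target_ids),
            "mechanism_summary": cohort_stats.mechanism_summary(records),
            "n_condition_specific_interactions": len(cs_records),
            "overlap_concordance": cohort_stats.overlap_concordance(
                de, genes, lnc_gene_ids
            ),
        }

    with _stage("write_outputs", timings):
        out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
        files = {
            "lnc_catalog": out("lncrna_catalog.tsv"),
            "interactions": out("interactions.tsv"),
            "interactions_condition_specific": out(
                "interactions_condition_specific.tsv"
            ),
            "alignments": out("alignments.tsv"),
            "alignments_bed": out("alignments.bed12"),
            "summary": out("summary.json"),
        }
        lnc_identify.write_catalog(catalog, files["lnc_catalog"])
        mechanisms.write_interactions_tsv(records, files["interactions"])
        mechanisms.write_interactions_tsv(
            cs_records, files["interactions_condition_specific"]
        )
        duplex_align.write_alignments_tsv(duplexes, files["alignments"])
        duplex_align.write_alignments_bed12(duplexes, files["alignments_bed"])
        with open(files["summary"], "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out("run_log.txt"), "w") as fh:
            for name, dt in timings:
                fh.write(f"{name}\t{dt:.3f}s\n")
            fh.write(f"interaction_records\t{len(records)}\n")

    return {
        "catalog": catalog,
        "lnc_ids": lnc_ids,
        "de": de,
        "duplexes": duplexes,
        "records": records,
        "condition_specific": cs_records,
        "summary": summary,
        "files": files,
    }
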