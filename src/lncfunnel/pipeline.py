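"""End-to-end pipeline: simulate/load → annotate → test → consensus →
candidacy → co-express → enrich, with config validation and a run manifest.

Every stage writes its outputs to files under the run directory so any stage
can be re-run or audited in isolation; the manifest records the config
snapshot, the funnel survivor counts and a checksum of every output file.
Identical config + seed gives byte-identical outputs (timestamps live only in
the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import parse_gtf, unique_lncrna_exons, classify_biotypes, write_bed
from .candidacy import CandidacyThresholds, assess_candidates, read_bedgraph
from .coexpression import (correlation_table, pca_summary, plot_matrix_data,
                           select_targets)
from .consensus import (Thresholds, biotype_recheck, candidate_table,
                        combine_evidence, funnel_report)
from .diffexpr import (exon_layer_test, fpkm, fpkm_group_test, nb_wald_test,
                       normalized_log_expression)
from .enrichment import enrichment_gene_table, hypergeom_enrich, read_gmt
from .matrix import CASE, CONTROL, CountMatrix
from .simulate import SimConfig, simulate_all

log = logging.getLogger("lncfunnel")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class CoexpressionParams:
    r_min: float = 0.85
    alpha: float = 0.05
    fallback_k: int = 30


@dataclass
class EnrichmentParams:
    min_set: int = 5
    max_set: int = 500
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 1
    log_level: str = "INFO"
    simulate: SimConfig | None = field(default_factory=SimConfig)
    inputs: dict | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    candidacy: CandidacyThresholds = field(default_factory=CandidacyThresholds)
    coexpression: CoexpressionParams = field(default_factory=CoexpressionParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_SECTION_TYPES = {
    "simulate": SimConfig,
    "thresholds": Thresholds,
    "candidacy": CandidacyThresholds,
    "coexpression": CoexpressionParams,
    "enrichment": EnrichmentParams,
}
_INPUT_KEYS = {"gtf", "counts_gene", "counts_transcript", "counts_exon",
               "groups", "transcript_lengths", "coverage_case",
               "coverage_control", "genesets", "biotype_map"}


def validate_config(path) -> RunConfig:
    """Load and type-check a YAML run config; unknown keys and out-of-range
    values are collected and reported together."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    errors: list[str] = []
    known_top = {"seed", "log_level", "inputs"} | set(_SECTION_TYPES)
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown config key: {key}")

    kwargs: dict = {}
    for name in ("seed", "log_level"):
        if name in raw:
            kwargs[name] = raw[name]
    for section, cls in _SECTION_TYPES.items():
        sub = raw.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            errors.append(f"section {section} must be a mapping")
            continue
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(sub) - valid_fields)
        errors.extend(f"unknown key {section}.{k}" for k in unknown)
        try:
            kwargs[section] = cls(**{k: v for k, v in sub.items()
                                     if k in valid_fields})
        except (ValueError, TypeError) as exc:
            errors.append(f"section {section}: {exc}")
    if "inputs" in raw and raw["inputs"] is not None:
        inputs = raw["inputs"]
        unknown = sorted(set(inputs) - _INPUT_KEYS)
        errors.extend(f"unknown key inputs.{k}" for k in unknown)
        missing = sorted(_INPUT_KEYS - set(inputs))
        errors.extend(f"missing input path: inputs.{k}" for k in missing)
        kwargs["inputs"] = inputs
        kwargs["simulate"] = None
    if errors:
        raise ConfigError(errors)
    cfg = RunConfig(**kwargs)
    if cfg.simulate is not None and "seed" in kwargs:
        cfg.simulate.seed = cfg.seed
    return cfg


@dataclass
class RunManifest:
    config: dict
    stage_counts: list[dict]
    checksums: dict[str, str]
    version: str
    timestamp: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig, outdir: Path) -> dict:
    """Stage 0: simulate into <outdir>/inputs, or take paths from config."""
    if cfg.simulate is not None:
        indir = outdir / "inputs"
        simulate_all(cfg.simulate, indir)
        paths = {
            "gtf": indir / "annotation.gtf",
            "counts_gene": indir / "counts_gene.tsv",
            "counts_transcript": indir / "counts_transcript.tsv",
            "counts_exon": indir / "counts_exon.tsv",
            "groups": indir / "groups.tsv",
            "transcript_lengths": indir / "transcript_lengths.tsv",
            "coverage_case": indir / f"coverage_{CASE}.bedgraph",
            "coverage_control": indir / f"coverage_{CONTROL}.bedgraph",
            "genesets": indir / "genesets.gmt",
            "biotype_map": indir / "biotype_map.tsv",
        }
    else:
        paths = {k: Path(v) for k, v in cfg.inputs.items()}
    return paths


def run_pipeline(cfg: RunConfig, outdir) -> RunManifest:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    stage = "inputs"
    stage_counts: list[dict] = []
    try:
        paths = _load_inputs(cfg, outdir)

        stage = "annotation"
        ann = parse_gtf(paths["gtf"])
        part = classify_biotypes(ann)
        uniq = unique_lncrna_exons(ann)
        write_bed(uniq, outdir / "unique_exons.bed")
        log.info("annotation: %d lncRNA / %d coding / %d other transcripts",
                 len(part.lncRNA), len(part.protein_coding), len(part.other))

        stage = "load counts"
        groups = CountMatrix.read_groups(paths["groups"])
        gene_cm = CountMatrix(
            pd.read_csv(paths["counts_gene"], sep="\t", index_col="feature_id"),
            groups)
        tx_counts = pd.read_csv(paths["counts_transcript"], sep="\t",
                                index_col="feature_id")
        tx_fm = pd.DataFrame(
            {"gene_id": [ann.transcripts[t].gene_id for t in tx_counts.index]},
            index=tx_counts.index)
        tx_cm = CountMatrix(tx_counts, groups, tx_fm)
        exon_counts = pd.read_csv(paths["counts_exon"], sep="\t",
                                  index_col="feature_id")
        exon_owner = {e.exon_id: t.transcript_id
                      for t in ann.transcripts.values() for e in t.exons}
        exon_fm = pd.DataFrame(
            {"transcript_id": [exon_owner[e] for e in exon_counts.index]},
            index=exon_counts.index)
        exon_cm = CountMatrix(exon_counts, groups, exon_fm)
        lengths = pd.read_csv(paths["transcript_lengths"], sep="\t",
                              index_col="transcript_id")["length"]

        stage = "differential expression"
        gene_res = nb_wald_test(gene_cm)
        tx_res = nb_wald_test(tx_cm)
        fpkm_mat = fpkm(tx_cm, lengths)
        fpkm_res = fpkm_group_test(fpkm_mat, groups)
        retained_ids = [e.exon_id for tid in sorted(uniq) for e in uniq[tid]]
        uniq_cm = exon_cm.subset(retained_ids)
        exon_agg = exon_layer_test(uniq_cm, alpha=cfg.thresholds.alpha_exon)
        gene_res.to_csv(outdir / "de_gene.tsv", sep="\t")
        tx_res.to_csv(outdir / "de_transcript.tsv", sep="\t")
        fpkm_res.to_csv(outdir / "de_fpkm.tsv", sep="\t")
        exon_agg.to_csv(outdir / "de_exon_aggregate.tsv", sep="\t")

        stage = "consensus"
        evidence = combine_evidence(gene_res, tx_res, fpkm_res, exon_agg,
                                    tx_cm, ann, part.lncRNA, cfg.thresholds)
        evidence = biotype_recheck(evidence, paths["biotype_map"])
        evidence.to_csv(outdir / "evidence.tsv", sep="\t")
        funnel = funnel_report(evidence, cfg.thresholds)
        survivors = list(evidence.index[evidence["passes"]])
        log.info("consensus: %d of %d lncRNA transcripts pass",
                 len(survivors), len(evidence))

        stage = "coverage candidacy"
        tracks = {
            CASE: read_bedgraph(paths["coverage_case"], ann.contigs, CASE),
            CONTROL: read_bedgraph(paths["coverage_control"], ann.contigs, CONTROL),
        }
        cand = assess_candidates(tracks, ann, uniq, survivors, cfg.candidacy)
        cand.to_csv(outdir / "candidacy.tsv", sep="\t")
        final = list(cand.index[cand["accept"]])
        funnel = pd.concat(
            [funnel, pd.DataFrame([{"stage": "coverage candidacy",
                                    "survivors": len(final)}])],
            ignore_index=True)
        funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
        stage_counts = funnel.to_dict("records")
        final_evidence = evidence.loc[final]
        candidate_table(final_evidence).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False)
        log.info("candidacy: %d final candidates", len(final))

        stage = "coexpression"
        expr = normalized_log_expression(tx_cm)
        coding_expr = expr.loc[[t for t in part.protein_coding
                                if t in expr.index]]
        if final:
            lnc_expr = expr.loc[final]
            cor = correlation_table(lnc_expr, coding_expr)
            selection = select_targets(cor, cfg.coexpression.r_min,
                                       cfg.coexpression.alpha,
                                       cfg.coexpression.fallback_k)
            pca = pca_summary(lnc_expr, groups)
            labels = groups.loc[list(expr.columns)].to_numpy()
            gmeans = pd.DataFrame({
                CASE: expr.loc[:, labels == CASE].mean(axis=1),
                CONTROL: expr.loc[:, labels == CONTROL].mean(axis=1),
            })
            plot_table = plot_matrix_data(
                selection[selection["passes_threshold"]], gmeans,
                cfg.coexpression.r_min)
        else:
            cor = pd.DataFrame(columns=["lnc_id", "coding_id", "r", "p_value"])
            selection = select_targets(cor)
            pca = None
            plot_table = pd.DataFrame()
        cor.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        selection.to_csv(outdir / "coexpression_targets.tsv", sep="\t", index=False)
        plot_table.to_csv(outdir / "plot_matrix.tsv", sep="\t")
        if pca is not None:
            pca.scores.assign(group=pca.groups.to_numpy()).to_csv(
                outdir / "pca_scores.tsv", sep="\t")
            pd.Series(pca.variance_fraction, name="variance_fraction").rename_axis(
                "component").to_csv(outdir / "pca_variance.tsv", sep="\t")

        stage = "enrichment"
        coding_gene_universe = sorted({
            ann.transcripts[t].gene_id for t in part.protein_coding})
        collection = read_gmt(paths["genesets"], universe=coding_gene_universe)
        thresh_pairs = selection[selection["passes_threshold"]] if len(selection) \
            else selection
        query = sorted({ann.transcripts[c].gene_id
                        for c in thresh_pairs.get("coding_id", pd.Series(dtype=str))})
        if query:
            enr = hypergeom_enrich(query, collection, cfg.enrichment.min_set,
                                   cfg.enrichment.max_set, cfg.enrichment.alpha)
            gene_of_tx = {t: ann.transcripts[t].gene_id for t in part.protein_coding}
            gene_table = enrichment_gene_table(enr, thresh_pairs, gene_of_tx)
        else:
            enr = pd.DataFrame(columns=["set_name", "k", "K", "n", "N", "p_value",
                                        "genes", "padj", "q_value", "significant"])
            gene_table = pd.DataFrame(columns=["set_name", "gene", "lnc_ids"])
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        gene_table.to_csv(outdir / "enrichment_genes.tsv", sep="\t", index=False)

        stage = "manifest"
        checksums = {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        manifest = RunManifest(cfg.to_dict(), stage_counts, checksums,
                               __version__, time.time())
        manifest.to_json(outdir / "manifest.json")
        return manifest
    except Exception:
        partial = RunManifest(cfg.to_dict(), stage_counts,
                              {"failed_stage": stage}, __version__, time.time())
        partial.to_json(outdir / "manifest.json")
        log.error("pipeline aborted in stage: %s", stage)
        raise
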