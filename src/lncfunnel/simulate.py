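"""Synthetic data generator with planted ground truth.

Generates, from one seed, an internally consistent bundle emulating the
inputs of a two-group (14 UC vs 16 control) lncRNA discovery study:

* a toy genome annotation in which *true* candidate lncRNAs carry fully
  non-overlapping exons, *decoy* lncRNAs have every exon same-strand inside a
  protein-coding exon (so their apparent signal is of coding origin), and
  some null lncRNAs overlap coding exons antisense;
* negative-binomial count matrices at gene, transcript and exon level, exactly
  layer-consistent (gene = sum of transcripts = sum of exons), with the
  planted log2 fold change applied to true lncRNAs on all exons and to decoys
  only on their (all-overlapping) exons;
* per-group coverage tracks consistent with the exon counts (count spread
  uniformly over the exon span, plus a uniform background floor);
* a latent-factor co-expression structure linking each true lncRNA to a few
  coding transcripts;
* GMT gene sets, two of which are enriched by construction in the linked
  coding genes.

Everything is deterministic under the config seed; sub-generators derive
child seeds from one SeedSequence so partial re-runs reproduce.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Exon, Gene, GenomeAnnotation, Transcript, write_bed, write_gtf
from .candidacy import write_bedgraph
from .enrichment import GeneSetCollection, write_gmt
from .matrix import CASE, CONTROL, CountMatrix


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-scale defaults: 14 cases vs 16 controls, ~200 coding genes,
    15 true / 15 decoy / 50 null lncRNAs, NB dispersion 0.1, planted
    log2FC 2."""

    n_case: int = 14
    n_control: int = 16
    n_coding_genes: int = 200
    n_lnc_true: int = 15
    n_lnc_decoy: int = 15
    n_lnc_null: int = 50
    nb_dispersion: float = 0.1
    effect_log2fc: float = 2.0
    #: relative per-sample library depth multiplier
    depth_mean: float = 1.0
    corr_strength: float = 0.95
    seed: int = 1
    # secondary knobs
    links_per_lnc: int = 3
    background_floor: float = 0.01
    library_sd: float = 0.15
    #: log2-scale amplitudes of the shared latent factor (group / noise parts)
    latent_group_amp: float = 0.32
    latent_noise_amp: float = 0.85
    reclassify_fraction: float = 0.0
    n_enriched_sets: int = 2
    n_background_sets: int = 8
    geneset_size: int = 15
    antisense_every: int = 5
    contig_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_coding_genes", "n_lnc_true",
                     "n_lnc_decoy", "n_lnc_null", "links_per_lnc"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        needed = self.n_lnc_decoy + self.n_lnc_true * self.links_per_lnc
        if self.n_coding_genes < needed:
            raise SimulationError(
                f"need at least {needed} coding genes for decoy hosts and links"
            )


@dataclass
class TruthSet:
    """Planted ground truth recorded by the generator."""

    true_de_lnc: list[str] = field(default_factory=list)
    decoy_lnc: list[str] = field(default_factory=list)
    null_lnc: list[str] = field(default_factory=list)
    #: (lncRNA transcript, coding transcript, intended sign ±1)
    coexpr_links: list[tuple[str, str, int]] = field(default_factory=list)
    enriched_pathways: list[str] = field(default_factory=list)
    unique_exon_count: int = 0
    reclassified: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sets = [set(self.true_de_lnc), set(self.decoy_lnc), set(self.null_lnc)]
        if sum(map(len, sets)) != len(set().union(*sets)):
            raise SimulationError("truth ID sets must be disjoint")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["coexpr_links"] = [tuple(x) for x in d["coexpr_links"]]
        return cls(**d)


# ----------------------------------------------------------------- annotation

def _make_transcript(gene_id: str, tid: str, biotype: str, contig: str,
                     strand: str, exon_coords: list[tuple[int, int]]) -> Transcript:
    exons = [Exon(f"{tid}.e{i + 1}", contig, s, e, strand, tid)
             for i, (s, e) in enumerate(exon_coords)]
    return Transcript(tid, gene_id, biotype, exons)


def simulate_annotation(config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[GenomeAnnotation, TruthSet]:
    """Build the toy annotation and the structural part of the truth record."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ann = GenomeAnnotation()
    contigs = ["chrS1", "chrS2"]
    cursor = {c: 1000 for c in contigs}
    gap = 1500

    def place(contig: str, n_exons: int) -> list[tuple[int, int]]:
        coords = []
        pos = cursor[contig]
        for _ in range(n_exons):
            span = int(rng.integers(150, 400))
            coords.append((pos, pos + span))
            pos += span + int(rng.integers(200, 500))
        cursor[contig] = coords[-1][1] + gap
        return coords

    def add(t: Transcript, gene_biotype: str) -> None:
        ann.genes.setdefault(t.gene_id, Gene(t.gene_id, gene_biotype))
        ann.genes[t.gene_id].transcript_ids.append(t.transcript_id)
        ann.transcripts[t.transcript_id] = t

    coding_tx: list[Transcript] = []
    for i in range(config.n_coding_genes):
        contig = contigs[i % 2]
        strand = "+" if (i // 2) % 2 == 0 else "-"
        t = _make_transcript(f"PC_G{i:04d}", f"PC_T{i:04d}", "protein_coding",
                             contig, strand, place(contig, 3))
        add(t, "protein_coding")
        coding_tx.append(t)

    truth = TruthSet()
    unique_exons = 0

    # decoys: every exon strictly inside a host coding exon, same strand
    for j in range(config.n_lnc_decoy):
        host = coding_tx[j]
        coords = [(e.start + 15, e.end - 15) for e in host.exons[:2]]
        t = _make_transcript(f"LNCD_G{j:04d}", f"LNCD_T{j:04d}", "lncRNA",
                             host.contig, host.strand, coords)
        add(t, "lncRNA")
        truth.decoy_lnc.append(t.transcript_id)

    # true candidates: intergenic, all exons non-overlapping
    for j in range(config.n_lnc_true):
        contig = contigs[j % 2]
        strand = "+" if j % 2 == 0 else "-"
        t = _make_transcript(f"LNCT_G{j:04d}", f"LNCT_T{j:04d}", "lncRNA",
                             contig, strand, place(contig, 3))
        add(t, "lncRNA")
        truth.true_de_lnc.append(t.transcript_id)
        unique_exons += 3

    # nulls: mostly intergenic; every k-th is antisense over a coding gene
    anti_hosts = coding_tx[::-1]
    for j in range(config.n_lnc_null):
        if config.antisense_every and j % config.antisense_every == 0:
            host = anti_hosts[j // config.antisense_every]
            strand = "-" if host.strand == "+" else "+"
            coords = [(e.start, e.end) for e in host.exons[:2]]
            t = _make_transcript(f"LNCN_G{j:04d}", f"LNCN_T{j:04d}", "lncRNA",
                                 host.contig, strand, coords)
        else:
            contig = contigs[j % 2]
            strand = "+" if j % 2 == 0 else "-"
            t = _make_transcript(f"LNCN_G{j:04d}", f"LNCN_T{j:04d}", "lncRNA",
                                 contig, strand, place(contig, 2))
        add(t, "lncRNA")
        truth.null_lnc.append(t.transcript_id)
        unique_exons += 2

    truth.unique_exon_count = unique_exons

    for c in contigs:
        ann.contigs[c] = cursor[c] + 2000
        if config.contig_length is not None:
            if cursor[c] > config.contig_length:
                raise SimulationError(
                    f"contig {c} too short ({config.contig_length}) to place "
                    f"requested genes (needs {cursor[c]})"
                )
            ann.contigs[c] = config.contig_length

    # co-expression links: distinct coding genes past the decoy hosts
    next_host = config.n_lnc_decoy
    for i, lnc_tid in enumerate(truth.true_de_lnc):
        for j in range(config.links_per_lnc):
            coding = coding_tx[next_host]
            next_host += 1
            sign = 1 if (i + j) % 2 == 0 else -1
            truth.coexpr_links.append((lnc_tid, coding.transcript_id, sign))

    ann.validate()
    return ann, truth


# --------------------------------------------------------------------- counts

def _sample_names(config: SimConfig) -> tuple[list[str], pd.Series]:
    cases = [f"UC{i + 1:02d}" for i in range(config.n_case)]
    ctrls = [f"N{i + 1:02d}" for i in range(config.n_control)]
    groups = pd.Series([CASE] * len(cases) + [CONTROL] * len(ctrls),
                       index=cases + ctrls, name="group")
    return cases + ctrls, groups


def simulate_counts(
    ann: GenomeAnnotation,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """NB counts at exon level, summed up to transcript and gene level.

    Per-exon mean: the transcript base expression split over exons
    proportionally to length, times a per-sample library factor, times
    2**offset where the offset carries the planted group effect and the
    shared latent co-expression factor.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    samples, groups = _sample_names(config)
    n = len(samples)
    g = np.where(groups.to_numpy() == CASE, 1.0, -1.0)

    tids = sorted(ann.transcripts)
    base = {}
    for tid in tids:
        if tid.startswith("PC_"):
            lo, hi = 50.0, 500.0
        elif tid.startswith(("LNCT_", "LNCD_")):
            lo, hi = 40.0, 400.0
        else:
            lo, hi = 5.0, 400.0
        base[tid] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    lib = config.depth_mean * np.exp(rng.normal(0.0, config.library_sd, size=n))

    # per-transcript log2 offsets (features × samples)
    half = config.effect_log2fc / 2.0
    offsets = {tid: np.zeros(n) for tid in tids}
    linked_signal = {}
    for lnc_tid in truth.true_de_lnc:
        e = rng.normal(0.0, 1.0, size=n)
        # the group part of the shared factor scales with the planted effect,
        # so effect_log2fc = 0 yields a genuine two-group null
        f = config.corr_strength * (config.latent_group_amp * half * g
                                    + config.latent_noise_amp * e)
        linked_signal[lnc_tid] = half * g + f
        offsets[lnc_tid] = linked_signal[lnc_tid]
    for lnc_tid, coding_tid, sign in truth.coexpr_links:
        offsets[coding_tid] = sign * linked_signal[lnc_tid]
    for decoy_tid in truth.decoy_lnc:
        # decoy exons are all protein-overlapping by construction, so the
        # planted effect on "overlapping exons only" is the whole transcript
        offsets[decoy_tid] = half * g

    exon_ids, exon_mu, exon_meta = [], [], []
    for tid in tids:
        t = ann.transcripts[tid]
        total = t.length
        mult = np.exp2(offsets[tid]) * lib
        for e in t.exons:
            exon_ids.append(e.exon_id)
            exon_mu.append(base[tid] * (e.span / total) * mult)
            exon_meta.append((e.exon_id, tid, t.gene_id))
    mu = np.vstack(exon_mu)

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    exon_counts = pd.DataFrame(counts, index=pd.Index(exon_ids, name="feature_id"),
                               columns=samples)
    exon_fm = pd.DataFrame(exon_meta, columns=["feature_id", "transcript_id",
                                               "gene_id"]).set_index("feature_id")
    exon_fm["level"] = "exon"

    tx_counts = exon_counts.groupby(exon_fm["transcript_id"]).sum()
    tx_counts.index.name = "feature_id"
    tx_counts = tx_counts.loc[tids]
    tx_fm = pd.DataFrame(
        {"gene_id": [ann.transcripts[t].gene_id for t in tids], "level": "transcript"},
        index=pd.Index(tids, name="feature_id"))

    gene_counts = tx_counts.groupby(tx_fm["gene_id"]).sum()
    gene_counts.index.name = "feature_id"
    gene_fm = pd.DataFrame({"level": "gene"},
                           index=pd.Index(gene_counts.index, name="feature_id"))

    lengths = pd.Series({t: ann.transcripts[t].length for t in tids},
                        name="length").rename_axis("transcript_id")
    return {
        "gene": CountMatrix(gene_counts, groups, gene_fm),
        "transcript": CountMatrix(tx_counts, groups, tx_fm),
        "exon": CountMatrix(exon_counts, groups, exon_fm),
        "lengths": lengths,
        "groups": groups,
    }


# ------------------------------------------------------------------- coverage

def simulate_coverage(
    ann: GenomeAnnotation,
    exon_counts: CountMatrix,
    background_floor: float = 0.01,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-group dense depth: group-mean exon count spread uniformly over the
    exon span (reads of length one model-unit), plus a uniform background
    floor.  Overlapping exons add up, as real ambiguous coverage does."""
    exon_by_id = {e.exon_id: e for t in ann.transcripts.values() for e in t.exons}
    out: dict[str, dict[str, np.ndarray]] = {}
    for group in (CASE, CONTROL):
        cols = exon_counts.group_samples(group)
        means = exon_counts.counts[cols].mean(axis=1)
        tracks = {c: np.zeros(length) for c, length in ann.contigs.items()}
        for eid, m in means.items():
            e = exon_by_id[eid]
            tracks[e.contig][e.start:e.end] += m / e.span
        for c in tracks:
            tracks[c] += background_floor
        out[group] = tracks
    return out


# ------------------------------------------------------------------ gene sets

def simulate_genesets(
    truth: TruthSet,
    config: SimConfig,
    ann: GenomeAnnotation,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Gene sets over the coding-gene universe; the enriched sets are packed
    with coexpression-linked coding genes, background sets are uniform draws."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    universe = sorted(g for g in ann.genes if g.startswith("PC_G"))
    linked = sorted({ann.transcripts[c].gene_id for _, c, _ in truth.coexpr_links})
    non_linked = [g for g in universe if g not in set(linked)]

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    truth.enriched_pathways = []
    if truth.coexpr_links:
        n_from_linked = max(1, int(round(config.geneset_size * 0.8)))
        for i in range(config.n_enriched_sets):
            name = f"PW_ENRICHED_{i + 1:02d}"
            members = list(rng.choice(linked, size=min(n_from_linked, len(linked)),
                                      replace=False))
            fill = config.geneset_size - len(members)
            if fill > 0 and non_linked:
                members += list(rng.choice(non_linked, size=min(fill, len(non_linked)),
                                           replace=False))
            sets[name] = sorted(members)
            descriptions[name] = "planted enriched pathway"
            truth.enriched_pathways.append(name)
    for i in range(config.n_background_sets):
        name = f"PW_BACKGROUND_{i + 1:02d}"
        sets[name] = sorted(rng.choice(universe, size=config.geneset_size,
                                       replace=False))
        descriptions[name] = "background pathway"
    return GeneSetCollection(sets, descriptions, universe)


# ------------------------------------------------------------------- biotypes

def simulate_biotype_map(
    ann: GenomeAnnotation,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Current-annotation biotype map; a configurable fraction of lncRNA
    transcripts is reclassified to 'TEC' to emulate annotation churn."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    tids = sorted(ann.transcripts)
    biotypes = {t: ann.transcripts[t].biotype for t in tids}
    truth.reclassified = []
    if config.reclassify_fraction > 0:
        lnc = [t for t in tids if biotypes[t] == "lncRNA"]
        k = int(round(config.reclassify_fraction * len(lnc)))
        for t in sorted(rng.choice(lnc, size=k, replace=False)):
            biotypes[t] = "TEC"
            truth.reclassified.append(t)
    return pd.DataFrame({"transcript_id": tids,
                         "biotype": [biotypes[t] for t in tids]})


# ------------------------------------------------------------------ all-in-one

@dataclass
class SimBundle:
    annotation: GenomeAnnotation
    truth: TruthSet
    matrices: dict
    genesets: GeneSetCollection
    biotype_map: pd.DataFrame
    coverage: dict[str, dict[str, np.ndarray]]


def simulate_all(config: SimConfig, outdir=None) -> SimBundle:
    """Run all generators from one seed; optionally write the file bundle."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    ann, truth = simulate_annotation(config, np.random.default_rng(children[0]))
    matrices = simulate_counts(ann, truth, config, np.random.default_rng(children[1]))
    coverage = simulate_coverage(ann, matrices["exon"], config.background_floor)
    genesets = simulate_genesets(truth, config, ann, np.random.default_rng(children[2]))
    biotype_map = simulate_biotype_map(ann, truth, config,
                                       np.random.default_rng(children[3]))
    bundle = SimBundle(ann, truth, matrices, genesets, biotype_map, coverage)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: SimBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(bundle.annotation, outdir / "annotation.gtf")
    for level in ("gene", "transcript", "exon"):
        bundle.matrices[level].to_tsv(outdir / f"counts_{level}.tsv")
    bundle.matrices["groups"].rename("group").to_csv(
        outdir / "groups.tsv", sep="\t", index_label="sample")
    bundle.matrices["lengths"].to_csv(outdir / "transcript_lengths.tsv", sep="\t")
    for group, tracks in bundle.coverage.items():
        write_bedgraph(tracks, outdir / f"coverage_{group}.bedgraph")
    write_gmt(bundle.genesets, outdir / "genesets.gmt")
    bundle.biotype_map.to_csv(outdir / "biotype_map.tsv", sep="\t", index=False)
    bundle.truth.to_json(outdir / "truth.json")
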