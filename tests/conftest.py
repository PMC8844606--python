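"""Shared fixtures: tiny GTF fixtures, random-annotation factory with a
per-base brute-force overlap oracle, and session-scoped default simulation
and pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

from lncfunnel.annotation import Exon, Gene, GenomeAnnotation, Transcript, parse_gtf
from lncfunnel.pipeline import RunConfig, run_pipeline
from lncfunnel.simulate import SimConfig, simulate_all

# 3 genes / 5 transcripts / 12 exons; one transcript is lncRNA by
# transcript_type despite a protein_coding gene_type
SMALL_GTF = """\
chr1\tt\tgene\t100\t2000\t.\t+\t.\tgene_id "G1"; gene_type "protein_coding";
chr1\tt\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "G1T1"; transcript_type "protein_coding";
chr1\tt\texon\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "G1T1"; transcript_type "protein_coding";
chr1\tt\texon\t500\t700\t.\t+\t.\tgene_id "G1"; transcript_id "G1T1"; transcript_type "protein_coding";
chr1\tt\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "G1T2"; transcript_type "lncRNA";
chr1\tt\texon\t800\t900\t.\t+\t.\tgene_id "G1"; transcript_id "G1T2"; transcript_type "lncRNA";
chr1\tt\tgene\t3000\t5000\t.\t-\t.\tgene_id "G2"; gene_type "lncRNA";
chr1\tt\texon\t3000\t3200\t.\t-\t.\tgene_id "G2"; transcript_id "G2T1";
chr1\tt\texon\t3400\t3600\t.\t-\t.\tgene_id "G2"; transcript_id "G2T1";
chr1\tt\texon\t3000\t3100\t.\t-\t.\tgene_id "G2"; transcript_id "G2T2";
chr1\tt\texon\t4000\t4500\t.\t-\t.\tgene_id "G2"; transcript_id "G2T2";
chr2\tt\tgene\t50\t900\t.\t+\t.\tgene_id "G3"; gene_biotype "misc_RNA";
chr2\tt\texon\t50\t300\t.\t+\t.\tgene_id "G3"; transcript_id "G3T1";
chr2\tt\texon\t400\t500\t.\t+\t.\tgene_id "G3"; transcript_id "G3T1";
chr2\tt\texon\t600\t900\t.\t+\t.\tgene_id "G3"; transcript_id "G3T1";
"""


@pytest.fixture
def small_gtf(tmp_path):
    path = tmp_path / "small.gtf"
    path.write_text(SMALL_GTF)
    return path


@pytest.fixture
def small_annotation(small_gtf):
    return parse_gtf(small_gtf)


def make_annotation(spec: list[tuple[str, str, str, str, list[tuple[int, int]]]]
                    ) -> GenomeAnnotation:
    """Build an annotation from (gene_id, transcript_id, biotype, strand,
    exon coords) tuples; single contig 'c'."""
    ann = GenomeAnnotation()
    end_max = 0
    for gid, tid, biotype, strand, coords in spec:
        ann.genes.setdefault(gid, Gene(gid, biotype))
        ann.genes[gid].transcript_ids.append(tid)
        exons = [Exon(f"{tid}.e{i}", "c", s, e, strand, tid)
                 for i, (s, e) in enumerate(sorted(coords))]
        ann.transcripts[tid] = Transcript(tid, gid, biotype, exons)
        end_max = max(end_max, max(e for _s, e in coords))
    ann.contigs["c"] = end_max + 100
    ann.validate()
    return ann


def random_annotation(rng: np.random.Generator, n_genes: int = 20,
                      contig_len: int = 5000) -> GenomeAnnotation:
    """Random annotation with overlapping structures on both strands."""
    spec = []
    for i in range(n_genes):
        biotype = rng.choice(["lncRNA", "protein_coding", "misc_RNA"],
                             p=[0.45, 0.45, 0.1])
        strand = rng.choice(["+", "-"])
        n_exons = int(rng.integers(1, 4))
        # non-overlapping exons within the transcript, anywhere on the contig
        pos = int(rng.integers(0, contig_len // 2))
        coords = []
        for _ in range(n_exons):
            span = int(rng.integers(10, 200))
            coords.append((pos, pos + span))
            pos += span + int(rng.integers(5, 150))
        spec.append((f"g{i}", f"t{i}", str(biotype), str(strand), coords))
    return make_annotation(spec)


def brute_force_unique_exons(ann: GenomeAnnotation) -> dict[str, list[str]]:
    """Per-base oracle: mark every base covered by a same-strand
    protein-coding exon; retain lncRNA exons with no marked base."""
    cover = {}
    for tid, t in ann.transcripts.items():
        if ann.transcript_class(tid) != "protein_coding":
            continue
        for e in t.exons:
            key = (e.contig, e.strand)
            if key not in cover:
                cover[key] = np.zeros(ann.contigs[e.contig], dtype=bool)
            cover[key][e.start:e.end] = True
    out = {}
    for tid, t in ann.transcripts.items():
        if ann.transcript_class(tid) != "lncRNA":
            continue
        kept = []
        for e in t.exons:
            mask = cover.get((e.contig, e.strand))
            if mask is None or not mask[e.start:e.end].any():
                kept.append(e.exon_id)
        out[tid] = kept
    return out


@pytest.fixture(scope="session")
def default_bundle():
    """Default-config synthetic bundle (seed 1), shared across modules."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Default-config end-to-end pipeline run (seed 1)."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    manifest = run_pipeline(RunConfig(seed=1), outdir)
    return outdir, manifest
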