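"""Synthetic-data generator: determinism, planted structure, layer
consistency, coverage and gene-set construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncfunnel.annotation import parse_gtf, unique_lncrna_exons, write_gtf
from lncfunnel.enrichment import read_gmt, write_gmt
from lncfunnel.matrix import CASE, CONTROL
from lncfunnel.simulate import (SimConfig, SimulationError, simulate_all,
                                simulate_annotation, simulate_coverage,
                                simulate_counts, simulate_genesets)

from conftest import brute_force_unique_exons


def small_config(**kw) -> SimConfig:
    defaults = dict(n_coding_genes=40, n_lnc_true=5, n_lnc_decoy=5,
                    n_lnc_null=10, links_per_lnc=2, seed=3)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_negative_counts_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(n_lnc_true=-1)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(nb_dispersion=0.0)

    def test_too_few_coding_genes_for_links_rejected(self):
        with pytest.raises(SimulationError, match="coding genes"):
            SimConfig(n_coding_genes=10, n_lnc_true=15, n_lnc_decoy=15)

    def test_too_short_contig_rejected(self):
        with pytest.raises(SimulationError, match="too short"):
            simulate_annotation(small_config(contig_length=2000))


class TestAnnotationStructure:
    def test_seed_determinism_gives_byte_identical_gtf(self, tmp_path):
        for d in ("a", "b"):
            ann, _ = simulate_annotation(small_config())
            write_gtf(ann, tmp_path / f"{d}.gtf")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_decoys_have_no_unique_exons_and_true_have_all(self, default_bundle):
        uniq = unique_lncrna_exons(default_bundle.annotation)
        truth = default_bundle.truth
        for tid in truth.decoy_lnc:
            assert uniq[tid] == []
        for tid in truth.true_de_lnc:
            assert len(uniq[tid]) == len(default_bundle.annotation.transcripts[tid].exons)

    def test_without_decoys_every_lncrna_keeps_an_exon(self):
        ann, _ = simulate_annotation(small_config(n_lnc_decoy=0))
        uniq = unique_lncrna_exons(ann)
        assert all(len(v) >= 1 for v in uniq.values())

    def test_overlap_pattern_matches_per_base_oracle_and_record(self, default_bundle):
        oracle = brute_force_unique_exons(default_bundle.annotation)
        total = sum(len(v) for v in oracle.values())
        assert total == default_bundle.truth.unique_exon_count

    def test_some_lncrnas_overlap_coding_antisense(self, default_bundle):
        ann = default_bundle.annotation
        uniq = unique_lncrna_exons(ann)
        # antisense nulls sit exactly on coding exon coordinates yet are kept
        anti = [t for t in default_bundle.truth.null_lnc
                if ann.transcripts[t].exons[0].exon_id.startswith("LNCN")
                and any(ann.transcripts[t].start == c.start
                        for c in ann.transcripts.values()
                        if c.transcript_id.startswith("PC_"))]
        assert anti and all(len(uniq[t]) > 0 for t in anti)


class TestCounts:
    def test_layer_consistency_exact(self, default_bundle):
        m = default_bundle.matrices
        ann = default_bundle.annotation
        fm = m["exon"].feature_meta
        tx_sum = m["exon"].counts.groupby(fm["transcript_id"]).sum()
        assert (tx_sum.loc[m["transcript"].counts.index]
                == m["transcript"].counts).all().all()
        gsum = m["transcript"].counts.groupby(
            m["transcript"].feature_meta["gene_id"]).sum()
        assert (gsum.loc[m["gene"].counts.index] == m["gene"].counts).all().all()

    def test_lengths_match_annotation(self, default_bundle):
        ann = default_bundle.annotation
        lengths = default_bundle.matrices["lengths"]
        for tid, t in ann.transcripts.items():
            assert lengths[tid] == t.length

    def test_null_effect_gives_calibrated_group_differences(self):
        cfg = small_config(effect_log2fc=0.0, n_coding_genes=100, n_lnc_true=10,
                           n_lnc_null=40, seed=5)
        ann, truth = simulate_annotation(cfg)
        m = simulate_counts(ann, truth, cfg)
        y = np.log2(m["transcript"].counts.to_numpy() + 1.0)
        labels = m["groups"].to_numpy()
        t, p = stats.ttest_ind(y[:, labels == CASE], y[:, labels == CONTROL],
                               axis=1)
        frac = (p < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_latent_factor_yields_high_linked_correlation(self):
        # large-sample limit: 100 + 100 samples, corr_strength 0.95
        cfg = small_config(n_case=100, n_control=100, seed=9)
        ann, truth = simulate_annotation(cfg)
        m = simulate_counts(ann, truth, cfg)
        y = np.log2(m["transcript"].counts + 1.0)
        rs = [abs(stats.pearsonr(y.loc[l], y.loc[c])[0])
              for l, c, _ in truth.coexpr_links]
        assert min(rs) > 0.85

    def test_planted_fold_change_has_expected_sign_and_size(self, default_bundle):
        m = default_bundle.matrices["transcript"]
        labels = m.groups.loc[m.samples].to_numpy()
        y = np.log2(m.counts.to_numpy() + 1.0)
        lfc = y[:, labels == CASE].mean(1) - y[:, labels == CONTROL].mean(1)
        lfc = pd.Series(lfc, index=m.counts.index)
        true_lfc = lfc.loc[default_bundle.truth.true_de_lnc]
        assert (true_lfc > 1.0).all()  # planted log2FC 2 plus latent group part


class TestCoverage:
    def test_zero_counts_and_zero_floor_give_zero_track(self, default_bundle):
        ann = default_bundle.annotation
        zero = default_bundle.matrices["exon"].counts * 0
        cm = default_bundle.matrices["exon"]
        zero_cm = type(cm)(zero, cm.groups, cm.feature_meta)
        cov = simulate_coverage(ann, zero_cm, background_floor=0.0)
        assert all(track.sum() == 0 for tracks in cov.values()
                   for track in tracks.values())

    def test_uniform_spread_is_definitional(self, default_bundle):
        # depth over an exon equals group-mean count / span (+ floor)
        ann = default_bundle.annotation
        cov = simulate_coverage(ann, default_bundle.matrices["exon"], 0.0)
        tid = default_bundle.truth.true_de_lnc[0]
        e = ann.transcripts[tid].exons[0]
        cols = default_bundle.matrices["exon"].group_samples(CASE)
        mean = default_bundle.matrices["exon"].counts.loc[e.exon_id, cols].mean()
        depth = cov[CASE][e.contig][e.start:e.end]
        assert np.allclose(depth, mean / e.span)

    def test_track_mass_proportional_to_exon_count_sums(self, default_bundle):
        ann = default_bundle.annotation
        cov = simulate_coverage(ann, default_bundle.matrices["exon"], 0.0)
        cols = default_bundle.matrices["exon"].group_samples(CONTROL)
        # intergenic true lncRNAs do not share bases with other transcripts
        for tid in default_bundle.truth.true_de_lnc[:5]:
            t = ann.transcripts[tid]
            mass = sum(cov[CONTROL][t.contig][e.start:e.end].sum()
                       for e in t.exons)
            expected = default_bundle.matrices["exon"].counts.loc[
                [e.exon_id for e in t.exons], cols].mean(axis=1).sum()
            assert mass == pytest.approx(expected, rel=1e-9)


class TestGeneSets:
    def test_no_links_means_no_enriched_sets(self):
        cfg = small_config(links_per_lnc=0)
        ann, truth = simulate_annotation(cfg)
        gs = simulate_genesets(truth, cfg, ann)
        assert truth.enriched_pathways == []
        assert all(n.startswith("PW_BACKGROUND") for n in gs.sets)

    def test_enriched_sets_overlap_matches_record(self, default_bundle):
        truth = default_bundle.truth
        ann = default_bundle.annotation
        linked = {ann.transcripts[c].gene_id for _, c, _ in truth.coexpr_links}
        for name in truth.enriched_pathways:
            members = set(default_bundle.genesets.sets[name])
            assert len(members & linked) >= 0.5 * len(members)

    def test_gmt_round_trip_is_lossless(self, default_bundle, tmp_path):
        path = tmp_path / "sets.gmt"
        write_gmt(default_bundle.genesets, path)
        back = read_gmt(path)
        assert back.sets == default_bundle.genesets.sets


class TestBundleDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = small_config()
        for d in ("a", "b"):
            simulate_all(cfg, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seed_changes_counts(self, tmp_path):
        m1 = simulate_all(small_config(seed=3)).matrices["gene"].counts
        m2 = simulate_all(small_config(seed=4)).matrices["gene"].counts
        assert not m1.equals(m2)

    def test_biotype_reclassification_count_matches_record(self):
        cfg = small_config(reclassify_fraction=0.2)
        bundle = simulate_all(cfg)
        bmap = bundle.biotype_map.set_index("transcript_id")["biotype"]
        demoted = bmap[bmap == "TEC"].index
        assert sorted(demoted) == sorted(bundle.truth.reclassified)
        n_lnc = sum(1 for t in bundle.annotation.transcripts.values()
                    if t.biotype == "lncRNA")
        assert len(demoted) == round(0.2 * n_lnc)
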