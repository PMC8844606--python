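"""NB Wald test, BH adjustment, FPKM and the exon evidence layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lncfunnel.diffexpr import (DiffExprError, bh_adjust, exon_layer_test,
                                fpkm, fpkm_group_test, nb_wald_test,
                                size_factors)
from lncfunnel.matrix import CASE, CONTROL, CountMatrix


def bh_step_up(p):
    """Independent oracle: direct step-up formula min_i>=j (p(i) * n / i)."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(monotone, 1.0)
    return out


def make_cm(counts: np.ndarray, n_case: int, n_ctrl: int,
            features=None, meta=None) -> CountMatrix:
    samples = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_ctrl)]
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_ctrl, index=samples)
    idx = features if features is not None else [f"f{i}" for i in range(len(counts))]
    df = pd.DataFrame(counts, index=pd.Index(idx, name="feature_id"),
                      columns=samples)
    return CountMatrix(df, groups, meta if meta is not None else pd.DataFrame())


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3], "c": [5, 10, 3]})
        assert np.allclose(size_factors(cm), 1.0)

    def test_scale_equivariance(self):
        a = np.array([4, 8, 100, 7], float)
        df = pd.DataFrame({"A": a, "B": 2 * a})
        f = size_factors(df)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_hand_computed_median_of_ratios(self):
        # 4 features x 3 samples, all positive
        df = pd.DataFrame({"s1": [2, 4, 6, 8], "s2": [4, 8, 12, 16],
                           "s3": [2, 4, 12, 8]}, dtype=float)
        logs = np.log(df.to_numpy())
        ref = logs.mean(axis=1, keepdims=True)
        expected = np.exp(np.median(logs - ref, axis=0))
        assert np.allclose(size_factors(df), expected)

    def test_no_all_positive_feature_errors_and_fallback_works(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]}, dtype=float)
        with pytest.raises(DiffExprError, match="pseudo_reference"):
            size_factors(df)
        f = size_factors(df, pseudo_reference=True)
        assert (f > 0).all()


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffExprError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_matches_step_up_oracle_and_inflates(self, p):
        got = bh_adjust(p)
        assert np.allclose(got, bh_step_up(p))
        assert (got >= np.asarray(p) - 1e-12).all()

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=37)
        perm = rng.permutation(37)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestNbWaldTest:
    def test_constant_feature_is_exact_null(self):
        # identical columns: size factors are 1, so a feature constant across
        # samples has log2fc exactly 0 and p ~ 1
        counts = np.vstack([np.full(8, 20), np.full(8, 7)])
        res = nb_wald_test(make_cm(counts, 4, 4))
        assert res.loc["f0", "log2fc"] == 0.0
        assert res.loc["f0", "p_value"] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        counts = np.ones((3, 3)) * 5
        with pytest.raises(DiffExprError):
            nb_wald_test(make_cm(counts, 1, 2))

    def test_all_zero_features_excluded_from_family(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(10, 8))
        counts[3] = 0
        res = nb_wald_test(make_cm(counts, 4, 4))
        assert "f3" not in res.index and len(res) == 9

    def test_label_swap_flips_lfc_and_keeps_p(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(10, 0.1, size=(50, 10))
        cm = make_cm(counts, 5, 5)
        swapped = CountMatrix(cm.counts, cm.groups.map(
            {CASE: CONTROL, CONTROL: CASE}), cm.feature_meta)
        a, b = nb_wald_test(cm), nb_wald_test(swapped)
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(10)
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + 100.0), size=(800, 30))
        res = nb_wald_test(make_cm(counts, 14, 16))
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_fold_change(self):
        # 200 DE features (log2FC 2) embedded among 800 nulls so that
        # normalization is anchored by the null majority
        rng = np.random.default_rng(11)
        r = 1 / 0.05
        mu_up = np.concatenate([np.full(14, 400.0), np.full(16, 100.0)])
        mu_dn = np.concatenate([np.full(14, 100.0), np.full(16, 400.0)])
        up = rng.negative_binomial(r, r / (r + mu_up), size=(100, 30))
        dn = rng.negative_binomial(r, r / (r + mu_dn), size=(100, 30))
        null = rng.negative_binomial(r, r / (r + 100.0), size=(800, 30))
        res = nb_wald_test(make_cm(np.vstack([up, dn, null]), 14, 16))
        de_res = res.loc[[f"f{i}" for i in range(200)]]
        assert (de_res["padj"] < 0.05).mean() >= 0.9
        assert de_res["log2fc"].abs().mean() == pytest.approx(2.0, abs=0.2)


class TestFpkm:
    def test_definitional_value(self):
        df = pd.DataFrame({"s": [10, 10**6 - 10]}, index=["t1", "t2"], dtype=float)
        lengths = pd.Series({"t1": 1000, "t2": 500})
        assert fpkm(df, lengths).loc["t1", "s"] == pytest.approx(10.0)

    def test_zero_counts_give_zero(self):
        df = pd.DataFrame({"s": [0, 100]}, index=["t1", "t2"], dtype=float)
        lengths = pd.Series({"t1": 1000, "t2": 500})
        assert fpkm(df, lengths).loc["t1", "s"] == 0.0

    def test_hand_evaluated_fixture(self):
        df = pd.DataFrame({"s1": [5, 10, 20], "s2": [50, 100, 200]},
                          index=["a", "b", "c"], dtype=float)
        lengths = pd.Series({"a": 100, "b": 200, "c": 400})
        got = fpkm(df, lengths)
        expected = df.to_numpy() * 1e9 / (df.sum(0).to_numpy()[None, :]
                                          * lengths.to_numpy()[:, None])
        assert np.allclose(got, expected)

    def test_missing_length_names_transcript(self):
        df = pd.DataFrame({"s": [5, 5]}, index=["a", "zz"], dtype=float)
        with pytest.raises(DiffExprError, match="zz"):
            fpkm(df, pd.Series({"a": 100}))

    def test_rows_scale_inversely_with_length(self):
        df = pd.DataFrame({"s": [10, 10]}, index=["a", "b"], dtype=float)
        out = fpkm(df, pd.Series({"a": 100, "b": 200}))
        assert out.loc["a", "s"] == pytest.approx(2 * out.loc["b", "s"])


class TestFpkmGroupTest:
    @staticmethod
    def _groups(n1, n0):
        idx = [f"c{i}" for i in range(n1)] + [f"n{i}" for i in range(n0)]
        return pd.Series([CASE] * n1 + [CONTROL] * n0, index=idx)

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        groups = self._groups(14, 16)
        mat = pd.DataFrame(rng.lognormal(3, 1, size=(1000, 30)),
                           columns=groups.index)
        res = fpkm_group_test(mat, groups)
        assert 0.03 <= (res["p_value"] < 0.05).mean() <= 0.07

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(4)
        groups = self._groups(5, 5)
        vals = np.hstack([rng.normal(1000, 10, (20, 5)), rng.normal(10, 1, (20, 5))])
        res = fpkm_group_test(pd.DataFrame(vals, columns=groups.index), groups)
        assert (res["q_value"] < 0.05).all()

    def test_single_sample_group_rejected(self):
        groups = self._groups(1, 3)
        mat = pd.DataFrame(np.ones((2, 4)), columns=groups.index)
        with pytest.raises(DiffExprError):
            fpkm_group_test(mat, groups)

    def test_constant_transcript_flagged_with_q_one(self):
        rng = np.random.default_rng(5)
        groups = self._groups(3, 3)
        mat = pd.DataFrame(np.vstack([np.full(6, 7.0),
                                      rng.lognormal(1, 1, 6)]),
                           columns=groups.index)
        res = fpkm_group_test(mat, groups)
        assert bool(res.iloc[0]["constant"]) is True
        assert res.iloc[0]["q_value"] == 1.0


class TestExonLayer:
    def test_empty_matrix_gives_empty_map(self):
        cm = make_cm(np.empty((0, 6)), 3, 3, features=[])
        assert exon_layer_test(cm).empty

    def test_aggregation_min_and_count(self):
        rng = np.random.default_rng(6)
        # one transcript with one strongly DE exon and one null exon,
        # plus null filler exons from other transcripts
        n1, n0 = 7, 7
        de = rng.poisson(np.concatenate([np.full(n1, 400), np.full(n0, 40)]))
        rows = [de, rng.poisson(60, n1 + n0)]
        owners = ["tA", "tA"]
        for i in range(30):
            rows.append(rng.poisson(60, n1 + n0))
            owners.append(f"t{i}")
        meta = pd.DataFrame({"transcript_id": owners},
                            index=[f"e{i}" for i in range(len(rows))])
        cm = make_cm(np.vstack(rows), n1, n0,
                     features=list(meta.index), meta=meta)
        agg = exon_layer_test(cm, alpha=0.05)
        assert agg.loc["tA", "n_signif_exons"] == 1
        res = nb_wald_test(cm)
        assert agg.loc["tA", "min_exon_padj"] == pytest.approx(
            res.loc[["e0", "e1"], "padj"].min())

    def test_transcript_without_retained_exons_absent(self):
        cm = make_cm(np.full((1, 6), 9), 3, 3, features=["e0"],
                     meta=pd.DataFrame({"transcript_id": ["tX"]}, index=["e0"]))
        agg = exon_layer_test(cm)
        assert "tOther" not in agg.index

    def test_true_lncrna_exons_detected_on_synthetic_data(self, default_bundle):
        from lncfunnel.annotation import unique_lncrna_exons
        uniq = unique_lncrna_exons(default_bundle.annotation)
        retained = [e.exon_id for t in sorted(uniq) for e in uniq[t]]
        cm = default_bundle.matrices["exon"].subset(retained)
        agg = exon_layer_test(cm)
        hits = sum(agg.loc[t, "n_signif_exons"] >= 1
                   for t in default_bundle.truth.true_de_lnc)
        assert hits >= 0.9 * len(default_bundle.truth.true_de_lnc)
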