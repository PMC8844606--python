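"""Generic two-group differential-expression tests on count matrices.

Three statistical layers mirror the classic gene / transcript / unique-exon
count analyses, plus an FPKM-based group test:

* :func:`nb_wald_test` — negative-binomial Wald test with median-of-ratios
  normalization and per-feature method-of-moments dispersion.  This is a
  transparent generic equivalent of the standard NB count test, without
  empirical-Bayes dispersion shrinkage or outlier machinery.
* :func:`fpkm_group_test` — nested-model F-test of the group label on
  log2(FPKM + 1).
* :func:`exon_layer_test` — the NB test applied to unique-exon counts,
  aggregated per owning transcript.

Multiple testing is controlled by Benjamini–Hochberg throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CASE, CONTROL, CountMatrix

#: floor for the method-of-moments dispersion estimate
MIN_DISPERSION = 1e-8
#: pseudocount added to group mean normalized counts before taking log2
LFC_PSEUDOCOUNT = 0.5


class DiffExprError(ValueError):
    pass


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffExprError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame | CountMatrix,
                 pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-feature geometric mean over features with
    all-positive counts.  If no such feature exists, pass
    ``pseudo_reference=True`` to compute the reference over counts offset by
    0.5 instead.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    if pseudo_reference:
        mat = mat + 0.5
        usable = np.ones(mat.shape[0], dtype=bool)
    else:
        usable = (mat > 0).all(axis=1)
        if not usable.any():
            raise DiffExprError(
                "no feature has positive counts in every sample; "
                "re-run with pseudo_reference=True"
            )
    logs = np.log(mat[usable])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _group_index(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    labels = cm.groups.loc[list(cm.counts.columns)].to_numpy()
    return labels == CASE, labels == CONTROL


def nb_wald_test(cm: CountMatrix, pseudo_reference: bool = False) -> pd.DataFrame:
    """Two-group NB Wald test per feature.

    Counts are scaled by median-of-ratios size factors; a per-feature
    dispersion ``alpha`` is estimated by method of moments from the pooled
    within-group variance, ``alpha = max((s2 - mu) / mu^2, 1e-8)``; the Wald
    statistic ``log2fc / SE(log2fc)`` is referred to the standard normal.
    Features with zero counts in every sample are excluded from testing and
    from the BH family.

    Returns a DataFrame indexed by feature with columns
    ``base_mean, log2fc, se, stat, p_value, padj``.
    """
    is_case, is_ctrl = _group_index(cm)
    if is_case.sum() < 2 or is_ctrl.sum() < 2:
        raise DiffExprError("each group needs at least 2 samples to estimate dispersion")

    sf = size_factors(cm.counts, pseudo_reference=pseudo_reference)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    nonzero = norm.sum(axis=1) > 0
    features = np.asarray(cm.features)[nonzero]
    norm = norm[nonzero]

    n1, n0 = int(is_case.sum()), int(is_ctrl.sum())
    mu1 = norm[:, is_case].mean(axis=1)
    mu0 = norm[:, is_ctrl].mean(axis=1)
    base_mean = norm.mean(axis=1)

    ss1 = ((norm[:, is_case] - mu1[:, None]) ** 2).sum(axis=1)
    ss0 = ((norm[:, is_ctrl] - mu0[:, None]) ** 2).sum(axis=1)
    s2 = (ss1 + ss0) / (n1 + n0 - 2)
    mu_bar = (n1 * mu1 + n0 * mu0) / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu_bar > 0, (s2 - mu_bar) / np.square(mu_bar), 0.0)
    alpha = np.maximum(alpha, MIN_DISPERSION)

    m1 = mu1 + LFC_PSEUDOCOUNT
    m0 = mu0 + LFC_PSEUDOCOUNT
    log2fc = np.log2(m1 / m0)
    # delta method on log2 of the group mean; NB variance mu + alpha mu^2
    var_l1 = (m1 + alpha * m1**2) / (n1 * m1**2)
    var_l0 = (m0 + alpha * m0**2) / (n0 * m0**2)
    se = np.sqrt(var_l1 + var_l0) / np.log(2)
    stat = np.where(log2fc == 0.0, 0.0, log2fc / se)
    p = 2 * stats.norm.sf(np.abs(stat))
    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p_value": p,
            "padj": bh_adjust(p),
        },
        index=pd.Index(features, name="feature_id"),
    )
    return res


def fpkm(transcript_counts: pd.DataFrame | CountMatrix,
         lengths: pd.Series) -> pd.DataFrame:
    """FPKM[t, s] = counts[t, s] * 1e9 / (total_counts[s] * length[t]).

    Library size is the raw column sum of the transcript count matrix.
    """
    df = transcript_counts.counts if isinstance(transcript_counts, CountMatrix) \
        else transcript_counts
    missing = [t for t in df.index if t not in lengths.index]
    if missing:
        raise DiffExprError(f"missing transcript length for: {missing[:5]}")
    lens = lengths.loc[df.index].to_numpy(dtype=float)
    if (lens <= 0).any():
        raise DiffExprError("transcript lengths must be positive")
    totals = df.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise DiffExprError("every sample must have positive total counts")
    vals = df.to_numpy(dtype=float) * 1e9 / (totals[None, :] * lens[:, None])
    return pd.DataFrame(vals, index=df.index, columns=df.columns)


def fpkm_group_test(fpkm_matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Nested-model F-test of group on log2(FPKM + 1), per transcript.

    Compares the two-group mean model against intercept-only; BH-adjusted
    p-values are reported as ``q_value``.  Transcripts with zero residual
    variance under both models are flagged ``constant`` and given q_value 1.
    """
    labels = groups.loc[list(fpkm_matrix.columns)].to_numpy()
    is_case = labels == CASE
    is_ctrl = labels == CONTROL
    n1, n0 = int(is_case.sum()), int(is_ctrl.sum())
    if n1 < 2 or n0 < 2:
        raise DiffExprError("each group needs at least 2 samples for the F-test")
    n = n1 + n0

    y = np.log2(fpkm_matrix.to_numpy(dtype=float) + 1.0)
    grand = y.mean(axis=1)
    rss0 = ((y - grand[:, None]) ** 2).sum(axis=1)
    m1 = y[:, is_case].mean(axis=1)
    m0 = y[:, is_ctrl].mean(axis=1)
    rss1 = ((y[:, is_case] - m1[:, None]) ** 2).sum(axis=1) + \
           ((y[:, is_ctrl] - m0[:, None]) ** 2).sum(axis=1)

    constant = rss0 <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss0 - rss1) / np.maximum(rss1 / (n - 2), 1e-300)
    p = stats.f.sf(f, 1, n - 2)
    p = np.where(constant, 1.0, p)
    res = pd.DataFrame(
        {
            "mean_case": m1,
            "mean_control": m0,
            "f_stat": np.where(constant, 0.0, f),
            "p_value": p,
            "q_value": bh_adjust(p),
            "constant": constant,
        },
        index=fpkm_matrix.index.rename("feature_id"),
    )
    return res


def exon_layer_test(unique_exon_matrix: CountMatrix, alpha: float = 0.05,
                    pseudo_reference: bool = False) -> pd.DataFrame:
    """NB test on unique-exon counts, aggregated per owning transcript.

    Returns a DataFrame indexed by transcript with ``min_exon_padj`` and
    ``n_signif_exons`` (count of exons with padj < ``alpha``).  Transcripts
    with no retained exons are absent from the result — downstream they fail
    the exon-evidence condition.
    """
    if unique_exon_matrix.counts.shape[0] == 0:
        return pd.DataFrame(columns=["min_exon_padj", "n_signif_exons"],
                            index=pd.Index([], name="transcript_id"))
    if "transcript_id" not in unique_exon_matrix.feature_meta.columns:
        raise DiffExprError("unique-exon matrix needs feature_meta['transcript_id']")
    res = nb_wald_test(unique_exon_matrix, pseudo_reference=pseudo_reference)
    owners = unique_exon_matrix.feature_meta.loc[res.index, "transcript_id"]
    agg = res.assign(transcript_id=owners.to_numpy()).groupby("transcript_id")["padj"].agg(
        min_exon_padj="min", n_signif_exons=lambda s: int((s < alpha).sum())
    )
    agg["n_signif_exons"] = agg["n_signif_exons"].astype(int)
    return agg


def normalized_log_expression(cm: CountMatrix,
                              pseudo_reference: bool = False) -> pd.DataFrame:
    """log2(size-factor-normalized count + 1), the expression scale used for
    co-expression and PCA."""
    sf = size_factors(cm.counts, pseudo_reference=pseudo_reference)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(np.log2(norm + 1.0), index=cm.counts.index,
                        columns=cm.counts.columns)
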