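"""Co-expression target selection and PCA summaries.

Candidate lncRNAs are correlated (Pearson, on log2 normalized expression)
against every protein-coding transcript.  Targets are coding transcripts with
|r| above a threshold (0.85) at p < 0.05; when fewer than ``fallback_k`` (30)
pass for a lncRNA, the top ``fallback_k`` by |r| are taken instead and the
selection is flagged so downstream consumers can distinguish the two modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CASE, CONTROL


class CoexpressionError(ValueError):
    pass


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p-value of the t-statistic
    ``r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CoexpressionError("vectors must have equal length n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CoexpressionError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(lnc_expr: pd.DataFrame, coding_expr: pd.DataFrame) -> pd.DataFrame:
    """All lncRNA × coding Pearson correlations with p-values.

    Rows of both inputs are transcripts, columns the shared samples.
    Constant transcripts are skipped (correlation undefined).
    """
    samples = list(lnc_expr.columns)
    cod = coding_expr[samples]
    n = len(samples)
    rows = []
    cod_mat = cod.to_numpy(dtype=float)
    cod_ok = np.ptp(cod_mat, axis=1) > 0
    cod_c = cod_mat - cod_mat.mean(axis=1, keepdims=True)
    cod_norm = np.sqrt((cod_c**2).sum(axis=1))
    for lnc_id in lnc_expr.index:
        x = lnc_expr.loc[lnc_id].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        xc = x - x.mean()
        xn = np.sqrt((xc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (cod_c @ xc) / (cod_norm * xn)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        for cid, ok, ri, pi in zip(cod.index, cod_ok, r, p):
            if ok:
                rows.append({"lnc_id": lnc_id, "coding_id": cid,
                             "r": float(ri), "p_value": float(pi)})
    return pd.DataFrame(rows, columns=["lnc_id", "coding_id", "r", "p_value"])


def select_targets(cor_table: pd.DataFrame, r_min: float = 0.85,
                   alpha: float = 0.05, fallback_k: int = 30) -> pd.DataFrame:
    """Per-lncRNA target selection.

    Threshold mode keeps every coding transcript with |r| > r_min and
    p < alpha.  If fewer than ``fallback_k`` pass, the top ``fallback_k`` by
    |r| (ties broken by coding ID ascending) are taken instead, flagged
    ``selection_mode = fallback_topk``.  Output order is deterministic and
    independent of input row order.
    """
    out = []
    for lnc_id, sub in cor_table.groupby("lnc_id", sort=True):
        sub = sub.assign(abs_r=sub["r"].abs())
        sub = sub.sort_values(["abs_r", "coding_id"],
                              ascending=[False, True], kind="mergesort")
        passing = sub[(sub["abs_r"] > r_min) & (sub["p_value"] < alpha)]
        if len(passing) >= fallback_k:
            sel, mode = passing, "threshold"
        else:
            sel, mode = sub.head(fallback_k), "fallback_topk"
        sel = sel.assign(selected=True, selection_mode=mode,
                         passes_threshold=(sel["abs_r"] > r_min)
                         & (sel["p_value"] < alpha))
        out.append(sel.drop(columns="abs_r"))
    if not out:
        return pd.DataFrame(columns=["lnc_id", "coding_id", "r", "p_value",
                                     "selected", "selection_mode",
                                     "passes_threshold"])
    return pd.concat(out, ignore_index=True)


@dataclass
class PcaSummary:
    variance_fraction: np.ndarray  # per component, sums to 1
    scores: pd.DataFrame           # samples × first two components
    groups: pd.Series


def pca_summary(expr_matrix: pd.DataFrame, groups: pd.Series) -> PcaSummary:
    """PCA with samples as observations and features as variables.

    Features are centered but not scaled; variance fractions come from the
    squared singular values of the centered sample × feature matrix.
    """
    if expr_matrix.shape[1] < 2:
        raise CoexpressionError("PCA needs at least 2 samples")
    x = expr_matrix.to_numpy(dtype=float).T  # samples × features
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    k = min(2, s.size)
    scores = pd.DataFrame(
        (u[:, :k] * s[:k]),
        index=pd.Index(expr_matrix.columns, name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaSummary(frac, scores, groups.loc[list(expr_matrix.columns)])


def plot_matrix_data(selection: pd.DataFrame, group_means: pd.DataFrame,
                     r_min: float = 0.85) -> pd.DataFrame:
    """Dot-matrix table: rows coding transcripts, columns lncRNAs, cells the
    sign of r where |r| > r_min (0 elsewhere).

    Transcript labels carry a '+' suffix when the case-group mean exceeds the
    control mean, '-' otherwise.  ``group_means`` is indexed by transcript
    with columns ``case`` and ``control``.
    """
    strong = selection[selection["r"].abs() > r_min]

    def _label(tid: str) -> str:
        up = group_means.loc[tid, CASE] > group_means.loc[tid, CONTROL]
        return f"{tid}{'+' if up else '-'}"

    lncs = sorted(strong["lnc_id"].unique())
    cods = sorted(strong["coding_id"].unique())
    table = pd.DataFrame(0, index=[_label(c) for c in cods],
                         columns=[_label(l) for l in lncs], dtype=int)
    for _, row in strong.iterrows():
        table.loc[_label(row["coding_id"]), _label(row["lnc_id"])] = \
            int(np.sign(row["r"]))
    return table


def plot_dot_matrix(table: pd.DataFrame, path) -> None:
    """Render the plot-matrix table: red positive, blue negative cells."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1 + 0.35 * table.shape[1], 1 + 0.25 * table.shape[0]))
    for i, cod in enumerate(table.index):
        for j, lnc in enumerate(table.columns):
            v = table.loc[cod, lnc]
            if v:
                ax.scatter(j, i, color="red" if v > 0 else "blue", s=30)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
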