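"""Four-layer evidence consensus: the candidate funnel.

A lncRNA transcript becomes a candidate only if it is significant
simultaneously in all four statistical layers — gene-level NB padj,
transcript-level NB padj, FPKM group-test q-value, and at least one
significant non-protein-overlapping exon — and its raw mean transcript count
exceeds an expression floor (strictly greater than 16 by default).  Missing
evidence in any layer is treated as failure, never imputed: the consensus is
deliberately conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .matrix import CountMatrix

# evidence-failure reason labels used in reports
R_GENE = "gene_padj"
R_TX = "transcript_padj"
R_FPKM = "fpkm_q"
R_EXON = "exon_evidence"
R_COUNT = "mean_count"
R_BIOTYPE = "biotype_changed"
R_NOTFOUND = "not_found"


@dataclass
class Thresholds:
    """Significance and expression thresholds for the consensus step.

    Setting an alpha to 1.0 disables that layer's condition, and setting
    ``min_mean_count`` to 0 disables the expression floor — the no-filter
    limit used for auditing the funnel.
    """

    alpha_gene: float = 0.05
    alpha_transcript: float = 0.05
    q_fpkm: float = 0.05
    alpha_exon: float = 0.05
    min_mean_count: float = 16.0

    def __post_init__(self) -> None:
        for name in ("alpha_gene", "alpha_transcript", "q_fpkm", "alpha_exon"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be >= 0")


def _below(value, alpha: float) -> bool:
    """Strict significance check; an alpha of 1.0 disables the condition."""
    if alpha >= 1.0:
        return True
    return bool(value < alpha)


def combine_evidence(
    gene_results: pd.DataFrame,
    transcript_results: pd.DataFrame,
    fpkm_results: pd.DataFrame,
    exon_aggregates: pd.DataFrame,
    transcript_counts: CountMatrix,
    annotation: GenomeAnnotation,
    lnc_transcripts: list[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Build the per-transcript evidence table.

    Gene-level evidence is attached to every transcript of the gene (the gene
    layer is gene-level by construction).  ``passes`` is True iff all five
    conditions hold; any missing layer fails with an explicit reason.
    Returns a DataFrame indexed by transcript with the evidence columns,
    ``passes`` and semicolon-joined ``reasons``.
    """
    mean_counts = transcript_counts.feature_means()
    rows = []
    for tid in sorted(lnc_transcripts):
        gid = annotation.transcripts[tid].gene_id
        gene_padj = gene_results["padj"].get(gid, np.nan)
        tx_padj = transcript_results["padj"].get(tid, np.nan)
        tx_lfc = transcript_results["log2fc"].get(tid, np.nan)
        base_mean = gene_results["base_mean"].get(gid, np.nan)
        fpkm_q = fpkm_results["q_value"].get(tid, np.nan)
        if tid in exon_aggregates.index:
            min_exon = exon_aggregates.loc[tid, "min_exon_padj"]
            n_sig = int(exon_aggregates.loc[tid, "n_signif_exons"])
        else:
            min_exon, n_sig = np.nan, 0
        mean_count = mean_counts.get(tid, np.nan)

        reasons = []
        if not _below(gene_padj, thresholds.alpha_gene):
            reasons.append(R_GENE)
        if not _below(tx_padj, thresholds.alpha_transcript):
            reasons.append(R_TX)
        if not _below(fpkm_q, thresholds.q_fpkm):
            reasons.append(R_FPKM)
        if thresholds.alpha_exon < 1.0 and not n_sig >= 1:
            reasons.append(R_EXON)
        if thresholds.min_mean_count > 0 and \
                not mean_count > thresholds.min_mean_count:  # strictly greater
            reasons.append(R_COUNT)
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "biotype_current": annotation.transcripts[tid].biotype,
                "gene_padj": gene_padj,
                "gene_base_mean": base_mean,
                "transcript_padj": tx_padj,
                "transcript_log2fc": tx_lfc,
                "fpkm_q": fpkm_q,
                "min_exon_padj": min_exon,
                "n_signif_exons": n_sig,
                "mean_transcript_count": mean_count,
                "passes": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    cols = ["transcript_id", "gene_id", "biotype_current", "gene_padj",
            "gene_base_mean", "transcript_padj", "transcript_log2fc", "fpkm_q",
            "min_exon_padj", "n_signif_exons", "mean_transcript_count",
            "passes", "reasons"]
    df = pd.DataFrame(rows, columns=cols)
    return df.set_index("transcript_id")


def biotype_recheck(evidence: pd.DataFrame, biotype_map_path) -> pd.DataFrame:
    """Demote passing transcripts whose *current* biotype is no longer lncRNA.

    ``biotype_map_path`` is a two-column TSV (transcript_id, biotype) standing
    in for a live annotation query.  Passing transcripts absent from the map
    are demoted with reason ``not_found``.
    """
    bmap = pd.read_csv(biotype_map_path, sep="\t")
    current = dict(zip(bmap.iloc[:, 0].astype(str), bmap.iloc[:, 1].astype(str)))
    out = evidence.copy()
    for tid in out.index[out["passes"]]:
        bt = current.get(tid)
        if bt is None:
            out.loc[tid, ["passes", "reasons"]] = False, R_NOTFOUND
        elif bt != "lncRNA":
            out.loc[tid, ["passes", "reasons"]] = False, R_BIOTYPE
            out.loc[tid, "biotype_current"] = bt
        else:
            out.loc[tid, "biotype_current"] = bt
    return out


def funnel_report(evidence: pd.DataFrame,
                  thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Survivor counts down the funnel, applied as successive intersections.

    Because every stage intersects the previous survivor set with one more
    condition, counts are monotone non-increasing by construction.
    """
    everything = pd.Series(True, index=evidence.index)

    def layer(col: str, alpha: float) -> pd.Series:
        return evidence[col] < alpha if alpha < 1.0 else everything

    stages = [
        ("lncRNA transcripts", everything),
        ("mean count > floor",
         evidence["mean_transcript_count"] > thresholds.min_mean_count
         if thresholds.min_mean_count > 0 else everything),
        ("gene padj", layer("gene_padj", thresholds.alpha_gene)),
        ("transcript padj", layer("transcript_padj", thresholds.alpha_transcript)),
        ("FPKM q", layer("fpkm_q", thresholds.q_fpkm)),
        ("unique-exon evidence",
         evidence["n_signif_exons"] >= 1 if thresholds.alpha_exon < 1.0
         else everything),
        ("consensus + biotype", evidence["passes"]),
    ]
    surviving = pd.Series(True, index=evidence.index)
    rows = []
    for label, cond in stages:
        surviving = surviving & cond.fillna(False)
        rows.append({"stage": label, "survivors": int(surviving.sum())})
    return pd.DataFrame(rows)


#: Table-1-style output column order
CANDIDATE_TABLE_COLUMNS = [
    "Transcript ID", "Gene_Name", "Ballgown (qvalue)", "Kallisto (FC)",
    "Kallisto (padj)", "Star (baseMean)", "Star (padj)", "Exon (padj)",
]


def candidate_table(evidence: pd.DataFrame) -> pd.DataFrame:
    """Passing candidates in the classic report schema.

    The fold-change column is log2; a linear-scale column is appended since
    the convention differs between tools.
    """
    passing = evidence[evidence["passes"]].sort_values("transcript_padj")
    df = pd.DataFrame(
        {
            "Transcript ID": passing.index,
            "Gene_Name": passing["gene_id"].to_numpy(),
            "Ballgown (qvalue)": passing["fpkm_q"].to_numpy(),
            "Kallisto (FC)": passing["transcript_log2fc"].to_numpy(),
            "Kallisto (padj)": passing["transcript_padj"].to_numpy(),
            "Star (baseMean)": passing["gene_base_mean"].to_numpy(),
            "Star (padj)": passing["gene_padj"].to_numpy(),
            "Exon (padj)": passing["min_exon_padj"].to_numpy(),
        },
        columns=CANDIDATE_TABLE_COLUMNS,
    )
    df["FC (linear)"] = 2.0 ** df["Kallisto (FC)"]
    return df
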