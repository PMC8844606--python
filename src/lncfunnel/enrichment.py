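"""Hypergeometric over-representation of gene sets (GMT) with BH padj and
Storey q-values.

Significance requires *both* padj < alpha and q_value < alpha, mirroring the
dual-column contract of the common pathway-enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


class GmtError(ValueError):
    pass


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None


def read_gmt(path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read GMT (name, description, members...); duplicate members are
    deduplicated preserving order.  Universe defaults to the union of members
    unless given."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtError(f"line {lineno}: GMT needs >= 3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
    return GeneSetCollection(sets, descriptions, list(universe))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


def storey_q(p_values, lam: float = 0.5, min_tests_for_pi0: int = 20) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda.

    ``pi0 = min(1, #(p > lam) / (m * (1 - lam)))``; with fewer than
    ``min_tests_for_pi0`` tests the estimate is unstable and pi0 defaults to
    1, making q equal to the BH-adjusted p.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p
    if m < min_tests_for_pi0:
        pi0 = 1.0
    else:
        pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
        pi0 = max(pi0, 1.0 / m)
    return np.clip(pi0 * bh_adjust(p), 0.0, 1.0)


def hypergeom_enrich(
    query: list[str],
    collection: GeneSetCollection,
    min_set: int = 5,
    max_set: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of the query against every set.

    With N the universe size, K the (restricted) set size, n the (restricted)
    query size and k the overlap, p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).  Sets outside [min_set, max_set] after
    restriction to the universe are skipped.  Returns results sorted by
    p ascending with BH ``padj``, Storey ``q_value`` and the dual-criterion
    ``significant`` flag.
    """
    universe = set(collection.universe or
                   {g for members in collection.sets.values() for g in members})
    q = sorted(set(query) & universe)
    if not q:
        raise EnrichmentError("no mappable genes: query is disjoint from the universe")
    N, n = len(universe), len(q)
    qset = set(q)
    rows = []
    for name in sorted(collection.sets):
        members = sorted(set(collection.sets[name]) & universe)
        K = len(members)
        if not min_set <= K <= max_set:
            continue
        overlap = sorted(qset & set(members))
        k = len(overlap)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0), "genes": ";".join(overlap)})
    res = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                      "p_value", "genes"])
    if len(res):
        res["padj"] = bh_adjust(res["p_value"].to_numpy())
        res["q_value"] = storey_q(res["p_value"].to_numpy())
        res["significant"] = (res["padj"] < alpha) & (res["q_value"] < alpha)
        res = res.sort_values(["p_value", "set_name"], kind="mergesort",
                              ignore_index=True)
    else:
        res["padj"] = res["q_value"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    return res


def enrichment_gene_table(results: pd.DataFrame,
                          selection: pd.DataFrame,
                          gene_of_transcript: dict[str, str]) -> pd.DataFrame:
    """Per-significant-pathway gene list with the lncRNAs each gene was
    co-expression-selected for.

    ``selection`` is the co-expression selection table (columns ``lnc_id``,
    ``coding_id``); ``gene_of_transcript`` maps coding transcript → gene
    symbol.  A gene co-expressed with several lncRNAs appears once, with all
    of them listed.
    """
    gene_to_lncs: dict[str, set[str]] = {}
    for _, row in selection.iterrows():
        gene = gene_of_transcript.get(row["coding_id"], row["coding_id"])
        gene_to_lncs.setdefault(gene, set()).add(row["lnc_id"])
    rows = []
    for _, res in results[results["significant"]].iterrows():
        for gene in res["genes"].split(";") if res["genes"] else []:
            rows.append({
                "set_name": res["set_name"],
                "gene": gene,
                "lnc_ids": ";".join(sorted(gene_to_lncs.get(gene, []))),
            })
    return pd.DataFrame(rows, columns=["set_name", "gene", "lnc_ids"])
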