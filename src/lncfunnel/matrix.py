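"""Integer feature × sample count matrices with group labels and metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


class MatrixError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Counts (features × samples) plus sample group labels and feature metadata.

    ``counts`` rows are feature IDs, columns sample IDs.  ``groups`` maps every
    sample to ``case`` or ``control``.  ``feature_meta`` (optional, indexed by
    feature) carries the hierarchy: ``level`` in {gene, transcript, exon} and
    parent IDs (``gene_id``, ``transcript_id``).
    """

    counts: pd.DataFrame
    groups: pd.Series
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise MatrixError("counts must be finite and non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise MatrixError(f"samples without group label: {missing}")
        bad = set(self.groups.loc[list(self.counts.columns)]) - {CASE, CONTROL}
        if bad:
            raise MatrixError(f"unknown group labels: {sorted(bad)}")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        labels = self.groups.loc[list(self.counts.columns)]
        return [s for s in self.counts.columns if labels[s] == group]

    def subset(self, features, meta: pd.DataFrame | None = None) -> "CountMatrix":
        features = list(features)
        missing = [f for f in features if f not in self.counts.index]
        if missing:
            raise MatrixError(f"features missing from count matrix: {missing[:5]}")
        fm = meta if meta is not None else (
            self.feature_meta.loc[features] if len(self.feature_meta) else pd.DataFrame()
        )
        return CountMatrix(self.counts.loc[features], self.groups, fm)

    def feature_means(self) -> pd.Series:
        """Raw mean count per feature across all samples."""
        return self.counts.mean(axis=1)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, counts_path, groups_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        if groups_path is not None:
            self.groups.rename("group").to_csv(
                groups_path, sep="\t", index_label="sample"
            )

    @staticmethod
    def read_groups(groups_path) -> pd.Series:
        df = pd.read_csv(groups_path, sep="\t")
        return pd.Series(df["group"].to_numpy(), index=df["sample"].astype(str))

    @classmethod
    def from_tsv(cls, counts_path, groups_path,
                 feature_meta: pd.DataFrame | None = None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        groups = cls.read_groups(groups_path)
        return cls(counts, groups,
                   feature_meta if feature_meta is not None else pd.DataFrame())
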