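"""Quantitative coverage-based candidacy scoring.

Visual inspection of read coverage over the annotation is formalized as three
scale-free metrics per transcript and group track:

* ``exon_alignment_fraction`` — share of the signal mass over the transcript
  span that lies inside the transcript's annotated exons (peaks align with
  exons rather than introns);
* ``background_ratio`` — mean exonic depth divided by the mean depth over
  flanking windows outside any annotated exon (signal above local background);
* ``unique_fraction`` — share of exonic signal mass falling in the retained
  non-protein-overlapping exons (signal not explainable by an overlapping
  coding transcript).

A transcript is accepted if all three metrics clear their thresholds in at
least one group's track: a genuine candidate may be expressed in only one
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Exon, GenomeAnnotation

#: guard for divisions; background_ratio cap for zero-background loci
EPSILON = 1e-6
RATIO_CAP = 1e6


class BedGraphError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Dense per-base depth over one contig for one sample/group."""

    contig: str
    depth: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise BedGraphError(f"{self.contig}: negative depth")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass
class CandidacyThresholds:
    min_alignment: float = 0.5
    min_background_ratio: float = 2.0
    min_unique_fraction: float = 0.5
    flank_bp: int = 500


@dataclass
class CandidacyReport:
    transcript_id: str
    group: str
    exon_alignment_fraction: float
    background_ratio: float
    unique_fraction: float
    accept: bool = False
    reasons: list[str] = field(default_factory=list)


def read_bedgraph(path, contig_lengths: dict[str, int] | None = None,
                  label: str = "") -> dict[str, CoverageTrack]:
    """Read a bedGraph (0-based half-open) into dense per-contig tracks.

    Bases not covered by any interval have depth 0.  Overlapping intervals
    are a format error.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise BedGraphError(f"line {lineno}: expected 4 fields")
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if end <= start:
                raise BedGraphError(f"line {lineno}: end <= start")
            intervals.setdefault(contig, []).append((start, end, value))

    tracks: dict[str, CoverageTrack] = {}
    lengths = contig_lengths or {}
    for contig in sorted(set(intervals) | set(lengths)):
        ivs = sorted(intervals.get(contig, []))
        for (s1, e1, _), (s2, _e2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise BedGraphError(
                    f"{contig}: overlapping bedGraph intervals at {s2} < {e1}"
                )
        size = max(lengths.get(contig, 0), ivs[-1][1] if ivs else 0)
        depth = np.zeros(size)
        for s, e, v in ivs:
            depth[s:e] = v
        tracks[contig] = CoverageTrack(contig, depth, label)
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray] | dict[str, CoverageTrack], path) -> None:
    """Run-length encode dense tracks to bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for contig in sorted(tracks):
            t = tracks[contig]
            depth = t.depth if isinstance(t, CoverageTrack) else np.asarray(t, float)
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0.0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:.6g}\n")


def _exon_mask(exons: list[Exon], offset: int, size: int) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for e in exons:
        lo, hi = max(e.start - offset, 0), min(e.end - offset, size)
        if hi > lo:
            mask[lo:hi] = True
    return mask


def candidacy_metrics(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    unique_exons: dict[str, list[Exon]],
    transcript_id: str,
    flank_bp: int = 500,
) -> CandidacyReport:
    """Compute the three candidacy metrics for one transcript on one track."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    t = annotation.transcripts[transcript_id]
    if t.contig != track.contig or t.end > track.length:
        raise ValueError(
            f"transcript {transcript_id} span exceeds track extent on {track.contig}"
        )
    span = slice(t.start, t.end)
    span_depth = track.depth[span]
    exon_mask = _exon_mask(t.exons, t.start, t.end - t.start)

    span_mass = float(span_depth.sum())
    exon_mass = float(span_depth[exon_mask].sum())
    alignment = exon_mass / span_mass if span_mass > 0 else 0.0

    # flanking windows, clipped at contig ends, minus bases in any annotated exon
    all_exons = [e for tx in annotation.transcripts.values() for e in tx.exons
                 if e.contig == track.contig]
    lo = max(t.start - flank_bp, 0)
    hi = min(t.end + flank_bp, track.length)
    flank_idx = np.concatenate([np.arange(lo, t.start), np.arange(t.end, hi)])
    if flank_idx.size:
        genome_exon_mask = _exon_mask(all_exons, 0, track.length)
        flank_idx = flank_idx[~genome_exon_mask[flank_idx]]
    background = float(track.depth[flank_idx].mean()) if flank_idx.size else 0.0

    mean_exon_depth = exon_mass / max(int(exon_mask.sum()), 1)
    ratio = min(mean_exon_depth / max(background, EPSILON), RATIO_CAP)

    uniq_mask = _exon_mask(unique_exons.get(transcript_id, []), t.start, t.end - t.start)
    uniq_mass = float(span_depth[uniq_mask & exon_mask].sum())
    unique_fraction = uniq_mass / max(exon_mass, EPSILON) if exon_mass > 0 else 0.0

    return CandidacyReport(
        transcript_id=transcript_id,
        group=track.label,
        exon_alignment_fraction=alignment,
        background_ratio=ratio,
        unique_fraction=min(unique_fraction, 1.0),
    )


def apply_verdict(report: CandidacyReport,
                  thresholds: CandidacyThresholds = CandidacyThresholds()) -> CandidacyReport:
    """Accept iff all three metric thresholds are met; reasons list failures."""
    reasons = []
    if report.exon_alignment_fraction < thresholds.min_alignment:
        reasons.append("alignment")
    if report.background_ratio < thresholds.min_background_ratio:
        reasons.append("background")
    if report.unique_fraction < thresholds.min_unique_fraction:
        reasons.append("protein_overlap")
    report.accept = not reasons
    report.reasons = reasons
    return report


def assess_candidates(
    tracks_by_group: dict[str, dict[str, CoverageTrack]],
    annotation: GenomeAnnotation,
    unique_exons: dict[str, list[Exon]],
    transcript_ids: list[str],
    thresholds: CandidacyThresholds = CandidacyThresholds(),
) -> pd.DataFrame:
    """Per-transcript verdicts over group tracks; accept if any group passes."""
    rows = []
    for tid in sorted(transcript_ids):
        contig = annotation.transcripts[tid].contig
        per_group = []
        for group in sorted(tracks_by_group):
            track = tracks_by_group[group][contig]
            rep = apply_verdict(
                candidacy_metrics(track, annotation, unique_exons, tid,
                                  thresholds.flank_bp),
                thresholds,
            )
            per_group.append(rep)
        accept = any(r.accept for r in per_group)
        best = max(per_group,
                   key=lambda r: (r.accept, r.exon_alignment_fraction
                                  + r.unique_fraction + min(r.background_ratio, 10)))
        rows.append(
            {
                "transcript_id": tid,
                "accept": accept,
                "best_group": best.group,
                "exon_alignment_fraction": best.exon_alignment_fraction,
                "background_ratio": best.background_ratio,
                "unique_fraction": best.unique_fraction,
                "reasons": "" if accept else ";".join(sorted(set(
                    r for rep in per_group for r in rep.reasons))),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def plot_coverage(tracks_by_group, annotation, transcript_id, path,
                  flank_bp: int = 500) -> None:
    """Depth over the transcript locus, one line per group, exons shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = annotation.transcripts[transcript_id]
    lo = max(t.start - flank_bp, 0)
    fig, ax = plt.subplots(figsize=(8, 3))
    for group in sorted(tracks_by_group):
        track = tracks_by_group[group][t.contig]
        hi = min(t.end + flank_bp, track.length)
        x = np.arange(lo, hi)
        ax.plot(x, track.depth[lo:hi], label=group, lw=0.8)
    for e in t.exons:
        ax.axvspan(e.start, e.end, alpha=0.15, color="orange")
    ax.set_xlabel(f"{t.contig} position (bp)")
    ax.set_ylabel("depth")
    ax.set_title(transcript_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
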