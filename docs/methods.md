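# Methods

## The problem

Long non-coding RNAs (lncRNAs) are weakly expressed and frequently share
exonic sequence with protein-coding genes on the same strand, so read counts
over such exons cannot be attributed unambiguously to the lncRNA.  A
differential-expression call based on any single quantification is therefore
fragile.  `lncfunnel` implements a deliberately stringent discovery funnel
for two-group (case vs control) bulk RNA-seq designs: a lncRNA transcript is
a candidate only when several independent lines of evidence agree *and* its
signal demonstrably originates from exons that no protein-coding transcript
shares.

## Pipeline model

1. **Biotype classification.**  A transcript counts as lncRNA when either
   its transcript-level or its gene-level biotype attribute equals `lncRNA`
   (both Gencode `*_type` and Ensembl `*_biotype` keys are accepted); it
   counts as protein-coding by the same either-level rule, checked second.
   All other biotypes fall into `other` and never exclude exons.

2. **Unique-exon isolation.**  Internally all intervals are 0-based
   half-open (GTF I/O converts from 1-based closed at the boundary).  For
   every lncRNA transcript, an exon is retained iff it shares zero bases
   with the union of same-strand protein-coding exons.  Antisense overlap
   does not exclude.  A partial overlap excludes the whole exon — no
   trimming — because the downstream evidence layer counts reads per
   *annotated* exon, not per fragment.  Exons without a defined strand are
   rejected at parse time: the same-strand rule is undefined for them.
   Identical exons shared by two lncRNA transcripts are kept per transcript,
   since all evidence is per-transcript.

3. **Four evidence layers.**
   * *Gene-level NB Wald test* on the gene count matrix.
   * *Transcript-level NB Wald test* on the transcript count matrix.
   * *FPKM group test*: nested-model F-test of the group label on
     log2(FPKM + 1), with FPKM = counts·10⁹ / (library size · length) and
     library size the raw column sum.  BH-adjusted p-values are reported as
     q-values.  Transcripts with zero residual variance are flagged and get
     q = 1.
   * *Unique-exon layer*: the NB test applied to the retained-exon count
     matrix, aggregated per transcript as the count of exons with
     padj < 0.05 and the minimum exon padj.

   The NB test normalizes by median-of-ratios size factors, estimates a
   per-feature dispersion by method of moments from the pooled within-group
   variance, `alpha = max((s² − mu)/mu², 1e-8)`, and refers
   log2FC / SE(log2FC) (delta method, pseudocount 0.5 on group means) to the
   standard normal.  This is a transparent generic NB Wald test: no
   empirical-Bayes dispersion shrinkage, no outlier replacement, no t-type
   small-sample correction.  The simplifications are acceptable at the
   design scale this package targets (≈15 samples per group) and are
   checked by calibration tests (type-I error within [0.03, 0.07] at nominal
   0.05 under the generative null).  Features with all-zero counts carry no
   information; they are removed before testing and excluded from the BH
   family so they cannot distort FDR control.

4. **Consensus.**  A transcript passes iff gene padj < 0.05, transcript
   padj < 0.05, FPKM q < 0.05, at least one significant unique exon, and
   raw mean transcript count strictly greater than 16.  Gene evidence is
   inherited by every transcript of the gene.  Missing evidence in any layer
   fails — never imputed.  The count floor applies to the raw
   transcript-level mean over all samples; which matrix carries the floor is
   ambiguous in practice, so the choice is exposed in config.  Setting an
   alpha to 1.0 disables that layer and a floor of 0 disables the floor:
   this defines the no-filter limit used to audit the funnel.  A biotype
   recheck against a current-annotation map then demotes passing transcripts
   whose biotype is no longer lncRNA (reason `biotype_changed`) or that are
   absent from the map (`not_found`).

5. **Coverage candidacy.**  Visual inspection of read pileups is replaced
   by three scale-free metrics per transcript and group track:
   `exon_alignment_fraction` (signal mass inside the transcript's exons over
   the mass across its whole span), `background_ratio` (mean exonic depth
   over the mean depth in flanking windows of `flank_bp` = 500 bp that fall
   outside any annotated exon), and `unique_fraction` (exonic mass inside
   retained unique exons over total exonic mass).  Defaults 0.5 / 2.0 / 0.5
   are conservative, dimensionless, and fully configurable; their effect is
   auditable through a monotone threshold sweep.  ε = 10⁻⁶ guards divisions
   and the background ratio is capped at 10⁶ for zero-background loci.  A
   transcript is accepted if *either* group's track passes all three — a
   genuine candidate may be expressed in only one condition.

6. **Co-expression.**  Candidate lncRNAs are correlated (Pearson, p from the
   t transform with n − 2 df) against all protein-coding transcripts on
   log2(size-factor-normalized count + 1); the log scale stabilizes variance
   and is recorded in output metadata.  Targets are pairs with |r| > 0.85
   and p < 0.05; when fewer than 30 pass for a lncRNA, the top 30 by |r|
   (ties broken by transcript ID ascending, for determinism) are taken
   instead and flagged `fallback_topk`.  At n = 30 samples the p-criterion
   is mathematically redundant at the threshold (p < 10⁻⁸), which a test
   asserts.  The PCA summary centers features without scaling and reports
   variance fractions from squared singular values.

7. **Enrichment.**  Threshold-passing coding transcripts are collapsed to
   gene symbols (the fallback lists are a per-lncRNA exploration device, not
   the enrichment query) and tested per GMT set with the upper-tail
   hypergeometric p over the universe of all protein-coding genes in the
   working annotation — not all GMT members; the universe choice is
   configurable and surfaced in output.  Significance requires both
   BH padj < 0.05 and Storey q < 0.05 (π₀ estimated at λ = 0.5; with fewer
   than 20 sets the estimate is unstable and π₀ defaults to 1, making
   q equal the BH padj).

## Synthetic data generator

The generator emulates the study design this pipeline targets: 14 case vs
16 control samples, ~200 protein-coding genes and 80 lncRNAs (15 true
candidates, 15 decoys, 50 nulls) on two toy contigs.

* **Structure.**  Coding genes have three exons.  Decoy lncRNAs have every
  exon strictly inside a host coding exon on the same strand — the failure
  mode the unique-exon filter exists to catch.  True candidates are
  intergenic with three fully unique exons.  Every fifth null lncRNA sits
  antisense on a coding gene (retained by the strand rule); the rest are
  intergenic.
* **Counts.**  Only exon counts are drawn, NB(mean, dispersion α = 0.1 with
  variance μ + αμ²); transcript counts are exact exon sums and gene counts
  exact transcript sums, so layer consistency is structural.  Per-transcript
  base expression is log-uniform (coding 50–500, true/decoy lncRNA 40–400,
  null lncRNA 5–400 so some nulls sit below the count floor), split over
  exons by length.  Per-sample library factors are LogNormal(0, 0.15) times
  `depth_mean` (a relative depth multiplier, default 1).
* **Effects.**  True lncRNAs receive the planted log2FC (default 2,
  as ±log2FC/2 by group) on all exons; decoys receive it on their
  (all-overlapping) exons, mimicking signal of coding origin: decoys are
  genuinely DE at the gene/transcript/FPKM layers and must be caught by the
  exon condition.
* **Co-expression.**  Each true lncRNA shares a per-sample latent factor
  `f = corr_strength · (0.32·(log2FC/2)·g + 0.85·e)` (g the group sign, e
  standard normal, log2 scale) with 3 linked coding transcripts, which also
  carry the group effect with the link sign.  The amplitudes were fixed once
  so that at `corr_strength` 0.95 the population linked-pair correlation is
  ≈0.95 on the log scale while unlinked DE–DE pairs stay near 0.7, and the
  planted effect remains detectable at the study scale.  Scaling the group
  part by the effect makes `effect_log2fc = 0` a genuine two-group null.
* **Coverage.**  Idealized: group-mean exon count spread uniformly over the
  exon span (reads of one model-unit length) plus a uniform background floor
  (default 0.01); overlapping exons add, as ambiguous pileups do.  No
  read-level simulation — candidacy scoring needs depth profiles, not reads.
* **Gene sets.**  Two sets are packed with ~80% linked coding genes; eight
  background sets of the same size (15) are uniform draws from the coding
  universe.  Background sets can occasionally reach nominal significance by
  chance; the dual padj/q criterion and the seeded defaults keep this rare,
  and the planted/background distinction is recorded in the truth file.
* **Determinism.**  One global seed; sub-generators derive child seeds from
  a single SeedSequence, so partial re-runs reproduce and two runs with the
  same config are byte-identical.

### What the generator does not emulate

Sequencing reads and their biases (GC, length, positional), multi-isoform
genes (every gene has one transcript, making gene and transcript layers
strongly dependent), quantification uncertainty from read assignment (the
three count layers are exactly consistent rather than estimated by three
tools), batch structure, and outlier samples.  Passing tests therefore
demonstrate that the funnel logic, its statistics and its planted-truth
recovery behave correctly under a clean NB world — not that the pipeline is
robust to aligner disagreement or annotation error in real data.

## Numerical choices and degenerate inputs

* BH via the standard step-up procedure (statsmodels backend), validated
  against the direct formula; inputs outside [0, 1] are rejected.
* Size factors require a feature positive in all samples; otherwise an
  explicit error suggests the pseudo-reference fallback (geometric mean over
  counts + 0.5).
* Constant features: log2FC is exactly 0 and p ≈ 1 under trivial
  normalization; constant FPKM rows are flagged with q = 1; constant
  expression vectors are skipped in correlation with a log entry.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, N, K, n)`
  and match exact enumeration to < 10⁻¹⁰ relative error for all N ≤ 20.
* Ties in top-k target selection break by |r| descending then ID ascending;
  all outputs are sorted so runs are reproducible byte for byte.

## Problem sizes

Default simulations (≈280 transcripts, ≈790 exons, 30 samples) run the full
pipeline in well under a second; calibration simulations use 2000 features.
These sizes give stable FDR behaviour and tight Monte-Carlo error while
keeping every run interactive.

## Known limitations

The NB test's normal Wald reference is mildly anti-conservative at small n
(observed type-I ≈ 0.055–0.065 at nominal 0.05 — within the accepted
calibration band, but real analyses at this scale may prefer a t reference).
Method-of-moments dispersion is noisier than shrinkage estimators and the
package makes no attempt at outlier robustness.  The coverage metrics
formalize what was historically a visual judgement; their defaults are
package choices, not community standards, and should be swept (the funnel
report makes the sweep monotone and auditable) rather than trusted blindly.
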