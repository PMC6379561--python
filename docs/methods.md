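# Methods

`medipdmr` re-implements, as one tested pipeline, the statistical core of a
transgenerational epigenomics study design: windowed MeDIP-seq differential
DNA-methylation analysis with DMR construction, differential expression of
mRNA/lncRNA/sncRNA count tables, interval/id overlap analysis, and an
observer-consensus histopathology statistic. Every stage runs on synthetic
data with known ground truth so that sensitivity, precision and calibration
are measurable properties of the pipeline rather than assumptions.

## Windowed count model and exact test

The genome is tiled into fixed 100 bp windows (terminal remainders kept as
truncated windows so the tiling partitions each chromosome). Each mapped
MeDIP fragment is assigned to the single window containing its midpoint
`(start + end) // 2` under half-open arithmetic; a midpoint on a boundary
belongs to the right-hand window. This convention makes counting exactly
reversible (column sums equal fragment counts), which the test suite
exploits as a round-trip invariant. An `overlap` counting mode (every
touched window incremented) is available for comparison but does not
conserve totals.

A window count for sample *j* is modelled as negative binomial with mean
μ_j and dispersion φ, Var = μ + φμ²; φ = 0 degenerates to Poisson. The
two-group test is an exact conditional test in the family used by the
windowed-methylation and RNA-seq count tools:

1. **Normalization.** TMM scale factors: each sample is compared to the
   deepest library; log-ratios M are trimmed 30% from each tail and
   log-abundances A 5% from each tail, and the factor is 2 to the
   precision-weighted mean of the surviving M values, with factors rescaled
   to geometric mean 1. A `total` mode (library-size-only) is available.
2. **Dispersion.** A common φ is estimated by the method of moments on the
   pooled Pearson statistic: φ solves Σ SS_fg / (m_fg + φ m_fg²) = Σ df_g
   over all feature×group cells with ≥ 2 samples and normalized mean above a
   floor (default 1), solved by bisection on [0, 10]. The per-feature moment
   estimate (v − m)/m² has the same expectation but is so noisy at 2–3
   samples per group that its median is biased ~35% low, which makes the
   downstream exact test liberal; the pooled Pearson form is near-unbiased
   (simulations in the test suite recover φ = 0 to ≤ 0.01 and φ = 0.2 to
   0.19) and keeps the null fraction of p < 0.01 at ~0.010.
3. **Exact test.** Counts are rescaled to the geometric-mean effective
   library size and rounded. Under the null the group sums A (n₁ samples)
   and B (n₂) are NB with means n₁μ, n₂μ and dispersions φ/n₁, φ/n₂ (the
   sum of n iid NB(μ, φ) is NB(nμ, φ/n)). Conditional on T = A + B with
   μ̂ = T/(n₁+n₂), the two-sided p-value sums the probabilities of all
   splits no more probable than the observed one (probability-mass
   ordering, ties included; T = 0 gives p = 1). Because the conditional
   distribution depends only on (T, n₁, n₂, φ), p-values for a 50,000-window
   matrix reduce to a few hundred cached distributions.
4. **Fold change and FDR.** log2((mean_exposure + ½)/(mean_control + ½)) on
   normalized means (pseudo-count guards zeros; > 0 is an increase in the
   exposure group), and Benjamini–Hochberg step-up q-values.

Numerical choices: the float path resolves probability ties with a 1e-7
relative slack (the standard exact-test convention); the φ = 0 limit instead
uses exact integer conditional-binomial weights C(T,a)·n₁^a·n₂^(T−a), so
tie ordering is exact and the test agrees with independent binomial
enumeration to < 1e-9. Exact numeric agreement with any particular external
package is not claimed — the statistic's family and its calibration are.

## DMR construction

Windows with p below the seed threshold (default 1e-6) start DMRs. Edges
are extended until no window with p < 0.1 remains within 1,000 bp of the
DMR span, and DMRs whose extensions meet are merged. Because the span's
edges are always window edges, this fixed point equals single-linkage
clustering of the sub-0.1 windows at inter-window gap ≤ 1,000 bp (inclusive);
a cluster containing at least one seed becomes one DMR spanning its
members. The implementation is property-tested for exact agreement with a
brute-force absorb-until-stable oracle.

Per DMR: the significant-window count at the seed threshold; the
multiple-window flag (≥ 2 seed-level windows that are immediately adjacent
tiles — an `any_two` reading is exposed as config); direction from the sign
of the log2 fold change at the most significant window; length; and CpG
density as the mean over spanned windows of CpG count per 100 bp (a CpG is
a C immediately followed by G; one straddling a window boundary is credited
to the window holding the C). Threshold tables re-call DMRs over a grid of
seed thresholds (1e-2 … 1e-8) and report all-window and multiple-window
counts. DMR clusters are maximal same-chromosome runs of ≥ 3 DMRs with
consecutive start-to-start gaps ≤ 2 Mb; the cluster rule the original
analyses cite is not published in detail, so these two parameters are
explicit config, not an inference.

## Overlap and annotation conventions

Gene association uses the gene body as anchor, ignores strand and counts a
gene when the interval gap is ≤ 10,000 bp inclusive (overlap ⇒ gap 0), so
promoter/flank contacts count. Interval Venn overlap requires ≥ 1 bp and is
reported from both sides (an element of one set can overlap several of the
other, so the two "common" counts may differ; both are kept rather than
choosing a convention silently). Id-set Venns are exact set operations with
duplicate warnings. Features with unknown genomic location (permitted for a
fraction of sncRNA) are excluded from interval overlaps with a logged
count. Category/pathway tallies count distinct genes per label from a
static gene→label map (multi-label genes count once per label; unmapped
genes are tallied as `unknown`) — no live annotation-database queries.

## Pathology statistic

Per observer and category, the disease cutoff is the control mean plus 2
sample standard deviations (ddof = 1) of that observer's own control scores
(per-observer rather than pooled, since observers score independently
before consensus; both the multiplier and pooling are config). An observer
calls an animal diseased when any category count strictly exceeds the
cutoff; a count equal to the cutoff is not a call. The consensus rule needs
≥ 2 of 3 observers. Control animals are classified under the same rule,
which yields the control disease frequency. Lineage frequencies are
compared with a two-sided Fisher exact test computed by hypergeometric
probability-mass ordering in exact integer arithmetic (any zero margin
gives p = 1). At low discrete means the mean+2SD rule is lenient — with a
Poisson(0.5) control baseline the expected control frequency is ~5–10%, not
0 — which the synthetic-power analysis reflects rather than hides.

## The synthetic-data generator

The generator emulates the study structure: two lineages × three pooled
samples per cell type, a CpG-sparse genome, planted DMRs, planted DE
transcripts in three RNA classes, and observer-scored pathology for 26
control vs 27 exposed animals.

- **Genome.** Uniform random sequence scrubbed of accidental CG
  dinucleotides, then CpGs planted per window at a Poisson rate whose mean
  follows a two-state local-density process (2% of windows at 8× the
  background, rescaled to a genome-wide mean of 1.5 CpG per 100 bp). This
  reproduces the CpG-desert regime (modal window CpG count 1–2) with
  occasional denser patches; it is not a model of real CpG islands.
- **MeDIP counts.** NB(μ = 50, φ = 0.1) per window per sample; planted
  regions (default 100 regions of 300–500 bp, window-aligned,
  non-overlapping) multiply or divide the exposed mean by 8, with an exact
  50/50 split of increases and decreases. Window counts are materialized as
  300 bp BED fragments centred in their window; near chromosome ends both
  fragment ends are trimmed equally so the midpoint — hence the assigned
  window — is preserved and counting stays reversible.
- **Transcripts.** Per-class counts (default 1,500 mRNA / 900 lncRNA / 600
  sncRNA; sncRNA subclasses miRNA/piRNA/tRNA/other at 40/40/10/10%),
  per-transcript lognormal baseline means around 100 (σ = 0.5), 5% planted
  DE at 8-fold (50/50 up/down), NB noise at φ = 0.1, random genomic
  intervals, and 5% of sncRNA with unknown location.
- **Pathology.** Each animal has a latent Poisson rate of 0.5 per category;
  observers are independent Poisson draws around it (the study does not
  describe inter-observer variability, so this noise model is this
  package's invention). 40% of exposed animals receive a +2.0 excess rate
  in two randomly chosen categories; the number of affected categories is
  config (with one category the Fisher power at n = 26/27 drops to ~0.77,
  with two it is ~0.96, matching the designed power of the comparison).

What passing tests show: the pipeline recovers planted effects of the
stated sizes and is calibrated under its own null. What they do not show:
robustness to mappability/GC bias, CpG-coupled enrichment efficiency,
library-composition artifacts, read-level error, or biological replicate
structure beyond exchangeable NB noise — none of which the generator
simulates.

## Problem sizes and determinism

The standard synthetic experiment used by the tests and the acceptance
script is one 5 Mb chromosome (50,000 windows), 3 vs 3 samples; smaller
80–500 kb designs back the unit tests, chosen so the whole suite runs in
about a minute. All randomness flows from a single config seed through
salted, operation-local generators; identical config + seed yields
byte-identical output files, which the pipeline manifest (SHA-256 per
file) makes checkable.

## Known limitations

- The exact test conditions on T with a plug-in μ̂; like its family it is
  mildly conservative for small T and approximate for very unequal depths.
- The common dispersion is shared across windows (per class for RNA);
  no tagwise/trended shrinkage or covariate designs.
- Fragment counting takes BED intervals as mapped fragments; there is no
  BAM/CIGAR handling, read extension or duplicate marking.
- Histopathology severity is reduced to abnormality counts; litter effects
  are not modelled.
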