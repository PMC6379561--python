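# medipdmr

Windowed MeDIP-seq differential DNA-methylation analysis with DMR calling,
mRNA/ncRNA differential expression, multi-omic overlap analysis and an
observer-consensus histopathology statistic — plus a synthetic-data
generator with known ground truth that makes every stage's sensitivity,
precision and calibration measurable.

The package is aimed at epigenomics analysts who have window-level MeDIP
fragment coordinates (BED), transcript count tables with RNA-class labels,
and observer-scored pathology tables — the typical outputs of a
transgenerational exposure study comparing a control and an exposed
lineage — and who want a fully specified, testable re-implementation of the
windowed differential-methylation statistic rather than a black box.

## The model

Fragment counts in 100 bp genomic windows (or transcript counts) are
negative binomial: Var(Y) = μ + φμ², with φ = 0 the Poisson limit. For two
groups with n₁ and n₂ samples, after TMM normalization and rescaling to a
common effective library size, the group sums A and B are NB(n₁μ, φ/n₁)
and NB(n₂μ, φ/n₂) under H₀. Conditional on T = A + B, the two-sided exact
p-value is

    p = Σ { P(a, T−a) : P(a, T−a) ≤ P(A, B) }  /  Σ_a P(a, T−a)

(probability-mass ordering; in the φ = 0 limit this is the exact
conditional binomial test, computed in exact integer arithmetic). The
common dispersion φ is a pooled Pearson moment estimate, and discoveries
are controlled with Benjamini–Hochberg FDR.

DMRs are built from windows with p < 1e-6 by edge extension: the region
grows until no window with p < 0.1 remains within 1,000 bp of its span,
and regions whose extensions meet are merged. A DMR is *multiple-window*
when at least two seed-level windows are immediately adjacent. Genes
within 10 kb of a DMR (gene-body anchor, flanks included) are associated
for category/pathway tallies. Disease status per animal is the 2-of-3
observer consensus of "any abnormality count above that observer's control
mean + 2 SD", and lineage frequencies are compared with a two-sided Fisher
exact test.

## Worked example

`examples/01_simulate_and_call_dmrs.py` simulates a 500 kb CpG-desert
genome with 10 planted 8-fold methylation changes, counts fragments into
100 bp windows, tests each window and calls DMRs:

```text
windows tested: 5000, estimated dispersion phi = 0.097
DMRs called at seed p < 1e-6: 8 (8 multiple-window)
  dmr_id  start    end  n_windows_significant        min_p direction  length_bp
DMR00001  14600  17600                      5 1.664984e-15  increase       3000
DMR00002 219200 225500                      8 2.989307e-18  increase       6300
...
recovery vs planted truth: sensitivity=1.00, precision=1.00
```

Every planted region is recovered (sensitivity) and every call overlaps a
planted region (precision); the estimated dispersion matches the simulated
φ = 0.1. The other examples cover differential expression by RNA class
(`02`), pathology disease calls (`03`: prints the per-observer cutoffs, the
2×2 lineage table and Fisher p = 0.019 for a 0.08 vs 0.37 disease-frequency
difference), overlap annotation (`04`) and the full pipeline with its
report bundle (`05`). The same stages are scriptable via the thin CLI:

```bash
medipdmr run-all --seed 7 --out run_dir    # simulate -> ... -> summary.json
medipdmr pathology --records scores.tsv --out pathology.json
```

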