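"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by the most transparent route
available (exact rational arithmetic, exhaustive enumeration, fixed-point
iteration) and stays independent of the library code paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import pandas as pd


def _choose(n: int, k: int) -> int:
    if k < 0 or k > n:
        return 0
    return factorial(n) // (factorial(k) * factorial(n - k))


def binomial_exact_two_sided(A: int, T: int, n1: int, n2: int) -> Fraction:
    """Two-sided exact test of a split (A, T-A) of Poisson group sums.

    Conditional on T the split is Binomial(T, n1/(n1+n2)); the two-sided
    p-value sums, in exact rational arithmetic, the probabilities of all
    splits no more probable than the observed one.
    """
    if T == 0:
        return Fraction(1)
    weights = [_choose(T, a) * Fraction(n1) ** a * Fraction(n2) ** (T - a) for a in range(T + 1)]
    w_obs = weights[A]
    num = sum(w for w in weights if w <= w_obs)
    return min(Fraction(1), Fraction(num, Fraction(n1 + n2) ** T))


def fisher_two_sided(table) -> Fraction:
    """Two-sided Fisher exact p by full hypergeometric enumeration with
    exact rational probabilities (factorial formula)."""
    (a, b), (c, d) = table
    N = a + b + c + d
    K, n = a + b, a + c
    if K == 0 or n == 0 or K == N or n == N:
        return Fraction(1)

    def prob(x: int) -> Fraction:
        return Fraction(
            factorial(K) * factorial(N - K) * factorial(n) * factorial(N - n),
            factorial(x)
            * factorial(K - x)
            * factorial(n - x)
            * factorial(N - K - n + x)
            * factorial(N),
        )

    lo, hi = max(0, K + n - N), min(K, n)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return min(Fraction(1), total)


def cpg_count_scan(sequence: str) -> int:
    """Position-by-position brute-force CpG scan."""
    seq = sequence.upper()
    return sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")


def call_dmrs_fixed_point(
    window_results: pd.DataFrame,
    seed_p: float,
    extend_p: float,
    extend_dist_bp: int,
) -> list[tuple[str, int, int]]:
    """Brute-force DMR spans: absorb sub-threshold windows into each seed
    span until nothing changes, then merge touching/overlapping spans."""
    ext = [
        (r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in window_results.iterrows()
        if r["p_value"] < extend_p
    ]
    spans = [
        [r["chrom"], int(r["start"]), int(r["end"])]
        for _, r in window_results.iterrows()
        if r["p_value"] < seed_p
    ]
    changed = True
    while changed:
        changed = False
        for span in spans:
            for (c, ws, we) in ext:
                if c != span[0]:
                    continue
                gap = max(ws - span[2], span[1] - we, 0)
                if gap <= extend_dist_bp and not (ws >= span[1] and we <= span[2]):
                    span[1] = min(span[1], ws)
                    span[2] = max(span[2], we)
                    changed = True
        # merge spans that overlap or touch
        spans.sort()
        merged: list[list] = []
        for span in spans:
            if merged and merged[-1][0] == span[0] and span[1] <= merged[-1][2]:
                if span[2] > merged[-1][2]:
                    merged[-1][2] = span[2]
                    changed = True
                elif span[1] < merged[-1][1]:
                    changed = True
            else:
                merged.append(list(span))
        if len(merged) != len(spans):
            changed = True
        spans = merged
    return [tuple(s) for s in spans]


def venn_intervals_quadratic(set_a: pd.DataFrame, set_b: pd.DataFrame) -> tuple[int, int]:
    """All-pairs interval overlap: (count of A overlapping any B, vice versa)."""

    def rows(df):
        return [
            (r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()
            if pd.notna(r["chrom"]) and pd.notna(r["start"]) and pd.notna(r["end"])
        ]

    ra, rb = rows(set_a), rows(set_b)

    def overlaps(x, y):
        return x[0] == y[0] and x[1] < y[2] and y[1] < x[2]

    a_common = sum(1 for x in ra if any(overlaps(x, y) for y in rb))
    b_common = sum(1 for y in rb if any(overlaps(y, x) for x in ra))
    return a_common, b_common
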