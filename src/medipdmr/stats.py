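"""Two-group differential testing for count features (windows or transcripts).

The statistic is a from-scratch negative-binomial exact test in the style of
the count-based differential tools used for windowed MeDIP coverage and
RNA-seq: TMM scale factors, a method-of-moments common dispersion, rescaling
of counts to a common effective library size, an exact conditional test on
the two group sums, a pseudo-counted log2 fold change, and Benjamini-Hochberg
FDR.  Exact numeric agreement with any particular external implementation is
not claimed; the family of the statistic is.

Model: a feature's count in sample j is NB with mean mu_j and dispersion phi
(Var = mu + phi mu^2; phi = 0 is Poisson).  After rescaling all samples to a
common effective size, the group sums A (n1 samples) and B (n2 samples) are
treated as NB with means n1*mu, n2*mu and dispersions phi/n1, phi/n2 under
the null.  Conditional on T = A + B the two-sided p-value sums the
probabilities of all splits no more probable than the observed one.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

_LOG_TIE_SLACK = 1e-7  # relative tie tolerance for float probability ordering


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    library_sizes: pd.Series
    scale_factors: pd.Series

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.scale_factors


def normalization_factors(
    counts: pd.DataFrame,
    method: str = "tmm",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """TMM (trimmed mean of M-values) scale factors, geometric mean 1.

    Each sample is compared pairwise to the deepest library: log-ratios M are
    trimmed at ``trim_m`` from each tail and log-abundances A at ``trim_a``,
    and the factor is 2 to the precision-weighted mean of the surviving M
    values.  ``method='total'`` falls back to pure library-size scaling
    (all factors 1).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"sample with all-zero counts: {zero.index[0]}")
    if method == "total":
        factors = pd.Series(1.0, index=counts.columns)
        return NormalizationResult(lib, factors)
    if method != "tmm":
        raise ValueError("method must be 'tmm' or 'total'")

    ref = lib.idxmax()
    r = counts[ref].to_numpy(float)
    Nr = lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y = counts[s].to_numpy(float)
        Ny = lib[s]
        keep = (y > 0) & (r > 0)
        if not keep.any():
            factors[s] = 1.0
            continue
        yk, rk = y[keep], r[keep]
        m = np.log2((yk / Ny) / (rk / Nr))
        a = 0.5 * np.log2((yk / Ny) * (rk / Nr))
        m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not sel.any():
            factors[s] = 1.0
            continue
        # asymptotic inverse variance of M as weight
        w = 1.0 / ((Ny - yk) / (Ny * yk) + (Nr - rk) / (Nr * rk))
        factors[s] = float(2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))
    f = pd.Series(factors).reindex(counts.columns)
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationResult(lib, f)


def _common_scaled(counts: pd.DataFrame, norm: NormalizationResult) -> tuple[pd.DataFrame, float]:
    """Counts rescaled to the geometric-mean effective library size."""
    eff = norm.effective_sizes.reindex(counts.columns)
    S = float(np.exp(np.mean(np.log(eff))))
    return counts * (S / eff), S


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    norm: NormalizationResult,
    mean_floor: float = 1.0,
    max_phi: float = 10.0,
) -> float:
    """Method-of-moments common dispersion phi from Pearson residuals.

    On normalized counts, the within-group residual sum of squares of every
    feature with group mean >= ``mean_floor`` contributes to the Pearson
    dispersion statistic sum(SS_fg / (m_fg + phi m_fg^2)); phi solves for
    that statistic matching its degrees of freedom (sum of n_g - 1 over
    contributing feature-groups).  The per-feature moment estimate
    (v - m) / m^2 averages to the same quantity but is far noisier at two or
    three samples per group, so the pooled Pearson form is used.  Clamped to
    [0, ``max_phi``]; returns 0 (with a warning) when no feature qualifies.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    z, _ = _common_scaled(counts, norm)
    means = []
    ssqs = []
    dfs = []
    for g in pd.unique(groups.loc[list(counts.columns)]):
        cols = [c for c in counts.columns if groups[c] == g]
        if len(cols) < 2:
            continue
        sub = z[cols].to_numpy(float)
        m = sub.mean(axis=1)
        ss = ((sub - m[:, None]) ** 2).sum(axis=1)
        ok = m >= mean_floor
        if ok.any():
            means.append(m[ok])
            ssqs.append(ss[ok])
            dfs.append(np.full(ok.sum(), len(cols) - 1, dtype=float))
    if not means:
        logger.warning("no features eligible for dispersion estimation; using phi = 0")
        return 0.0
    m = np.concatenate(means)
    ss = np.concatenate(ssqs)
    df_total = float(np.concatenate(dfs).sum())

    def pearson_excess(phi: float) -> float:
        return float((ss / (m + phi * m**2)).sum() - df_total)

    if pearson_excess(0.0) <= 0.0:
        return 0.0
    if pearson_excess(max_phi) >= 0.0:
        return max_phi
    from scipy.optimize import brentq

    phi = brentq(pearson_excess, 0.0, max_phi, xtol=1e-8)
    return float(phi)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mu: float, size: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (
        gammaln(k + size)
        - gammaln(size)
        - gammaln(k + 1.0)
        + size * np.log(size / (size + mu))
        + k * np.log(mu / (size + mu))
    )


class _ExactTestCache:
    """Conditional split distributions keyed by the total T.

    After rescaling to a common library size the conditional null
    distribution of a split depends only on (T, n1, n2, phi), so p-values for
    a whole matrix reduce to a handful of distinct totals.
    """

    def __init__(self, n1: int, n2: int, phi: float):
        if phi < 0:
            raise ValueError("dispersion phi must be >= 0")
        if n1 < 1 or n2 < 1:
            raise ValueError("both groups need at least one sample")
        self.n1, self.n2, self.phi = n1, n2, float(phi)
        self._float: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._int: dict[int, tuple[list, list, list, int]] = {}

    # exact integer weights for the Poisson (phi = 0) limit: conditional on
    # T the split is Binomial(T, n1/(n1+n2)); weight(a) = C(T,a) n1^a n2^(T-a)
    def _int_entry(self, T: int):
        entry = self._int.get(T)
        if entry is None:
            n1, n2 = self.n1, self.n2
            weights = [comb(T, a) * n1**a * n2 ** (T - a) for a in range(T + 1)]
            swts = sorted(weights)
            prefix = [0]
            for w in swts:
                prefix.append(prefix[-1] + w)
            entry = (weights, swts, prefix, (n1 + n2) ** T)
            self._int[T] = entry
        return entry

    def _float_entry(self, T: int):
        entry = self._float.get(T)
        if entry is None:
            a = np.arange(T + 1)
            mu = T / (self.n1 + self.n2)
            lp = _nb_logpmf(a, self.n1 * mu, self.n1 / self.phi) + _nb_logpmf(
                T - a, self.n2 * mu, self.n2 / self.phi
            )
            order = np.argsort(lp, kind="stable")
            lp_sorted = lp[order]
            # cumulative log-sum-exp of the sorted probabilities
            with np.errstate(divide="ignore"):
                cum = np.logaddexp.accumulate(lp_sorted)
            entry = (lp, lp_sorted, cum)
            self._float[T] = entry
        return entry

    def p_value(self, A: int, T: int) -> float:
        if T == 0:
            return 1.0
        if not 0 <= A <= T:
            raise ValueError("observed group sum outside [0, T]")
        if self.phi == 0:
            weights, swts, prefix, total = self._int_entry(T)
            w_obs = weights[A]
            idx = bisect_right(swts, w_obs)
            return min(1.0, prefix[idx] / total)
        lp, lp_sorted, cum = self._float_entry(T)
        thr = lp[A] + _LOG_TIE_SLACK
        idx = int(np.searchsorted(lp_sorted, thr, side="right"))
        log_p = cum[idx - 1] - cum[-1]
        return float(min(1.0, np.exp(log_p)))


def nb_exact_test(
    feature_counts: Sequence[float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    norm: NormalizationResult,
    phi: float,
) -> float:
    """Exact conditional two-sided p-value for one feature.

    Counts are rescaled to the common effective library size and rounded;
    the split of the rounded group sums is then tested against the
    conditional null.  T = 0 gives p = 1 by convention.
    """
    feature_counts = pd.Series(feature_counts)
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    scaled, _ = _common_scaled(feature_counts.to_frame().T, norm)
    vals = np.rint(scaled.iloc[0].to_numpy(float)).astype(np.int64)
    labels = groups.loc[list(feature_counts.index)].to_numpy()
    glabels = pd.unique(labels)
    if len(glabels) != 2:
        raise ValueError("exactly two groups are required")
    mask = labels == glabels[0]
    A = int(vals[mask].sum())
    B = int(vals[~mask].sum())
    cache = _ExactTestCache(int(mask.sum()), int((~mask).sum()), phi)
    return cache.p_value(A, A + B)


def exact_test_pvalues(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    norm: NormalizationResult,
    phi: float,
) -> np.ndarray:
    """Vectorized exact test over a feature x sample count matrix."""
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    scaled, _ = _common_scaled(counts, norm)
    vals = np.rint(scaled.to_numpy(float)).astype(np.int64)
    labels = groups.loc[list(counts.columns)].to_numpy()
    glabels = pd.unique(labels)
    if len(glabels) != 2:
        raise ValueError("exactly two groups are required")
    mask = labels == glabels[0]
    A = vals[:, mask].sum(axis=1)
    T = A + vals[:, ~mask].sum(axis=1)
    cache = _ExactTestCache(int(mask.sum()), int((~mask).sum()), phi)
    return np.array([cache.p_value(int(a), int(t)) for a, t in zip(A, T)])


# ---------------------------------------------------------------------------
# fold change and FDR
# ---------------------------------------------------------------------------

def group_means(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    norm: NormalizationResult,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (common-scale) mean per group: (control, exposure)."""
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    scaled, _ = _common_scaled(counts, norm)
    labels = groups.loc[list(counts.columns)]
    ctrl_cols = labels.index[labels == "control"]
    exp_cols = labels.index[labels != "control"]
    return (
        scaled[ctrl_cols].to_numpy(float).mean(axis=1),
        scaled[exp_cols].to_numpy(float).mean(axis=1),
    )


def log2_fold_change(
    feature_counts: Sequence[float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    norm: NormalizationResult,
    pseudo: float = 0.5,
) -> float:
    """log2((mean_exposure + pseudo) / (mean_control + pseudo)); > 0 means
    an increase in the exposure group."""
    fc = pd.Series(feature_counts)
    mc, me = group_means(fc.to_frame().T, groups, norm)
    return float(np.log2((me[0] + pseudo) / (mc[0] + pseudo)))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# assembled per-feature results
# ---------------------------------------------------------------------------

def test_two_groups(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    feature_meta: pd.DataFrame | None = None,
    phi: float | None = None,
    norm: NormalizationResult | None = None,
    min_total_count: int = 0,
    pseudo: float = 0.5,
    normalization: str = "tmm",
) -> pd.DataFrame:
    """Full per-feature differential table: p, BH FDR, log2FC, group means.

    Features with raw total count below ``min_total_count`` are dropped
    before testing (and before the FDR correction).
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    keep = counts.sum(axis=1) >= min_total_count
    counts_k = counts.loc[keep]
    if norm is None:
        norm = normalization_factors(counts, method=normalization)
    if phi is None:
        phi = estimate_common_dispersion(counts_k, groups, norm)
    p = exact_test_pvalues(counts_k, groups, norm, phi)
    mc, me = group_means(counts_k, groups, norm)
    lfc = np.log2((me + pseudo) / (mc + pseudo))
    out = pd.DataFrame(
        {
            "p_value": p,
            "fdr": bh_fdr(p),
            "log2fc": lfc,
            "mean_control": mc,
            "mean_exposure": me,
            "dispersion_used": phi,
        },
        index=counts_k.index,
    )
    if feature_meta is not None:
        out = pd.concat([feature_meta.loc[keep].reset_index(drop=True),
                         out.reset_index(drop=True)], axis=1)
    return out


def differential_expression(
    transcripts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    p_threshold: float = 0.001,
    min_total_count: int = 10,
    normalization: str = "tmm",
) -> tuple[pd.DataFrame, dict]:
    """Per-transcript differential test with per-RNA-class dispersion.

    ``transcripts`` needs columns id, class, subclass plus one column per
    sample named in ``groups``.  Returns (results, tallies): results carries
    every tested transcript with a ``significant`` flag at ``p_threshold``;
    tallies counts significant transcripts per class and per sncRNA subclass.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    sample_cols = [c for c in transcripts.columns if c in groups.index]
    meta_cols = [c for c in transcripts.columns if c not in sample_cols]
    if "class" not in transcripts.columns:
        raise ValueError("transcripts must carry a 'class' column")
    if transcripts["class"].isna().any():
        raise ValueError("missing RNA class label")
    bad = set(transcripts["class"]) - {"mRNA", "lncRNA", "sncRNA"}
    if bad:
        raise ValueError(f"invalid RNA class label: {sorted(bad)[0]!r}")

    counts = transcripts[sample_cols]
    norm = normalization_factors(counts, method=normalization)
    pieces = []
    for cls, grp in transcripts.groupby("class", sort=False):
        sub_counts = grp[sample_cols]
        keep = sub_counts.sum(axis=1) >= min_total_count
        sub_counts = sub_counts.loc[keep]
        if sub_counts.empty:
            continue
        phi = estimate_common_dispersion(sub_counts, groups, norm)
        res = test_two_groups(
            sub_counts, groups, phi=phi, norm=norm, min_total_count=0
        )
        res = pd.concat(
            [grp.loc[keep, meta_cols].reset_index(drop=True), res.reset_index(drop=True)],
            axis=1,
        )
        pieces.append(res)
    results = pd.concat(pieces, ignore_index=True)
    # BH across all tested transcripts jointly
    results["fdr"] = bh_fdr(results["p_value"].to_numpy())
    results["significant"] = results["p_value"] < p_threshold
    de = results[results["significant"]]
    by_class = de["class"].value_counts().to_dict()
    snc = de[de["class"] == "sncRNA"]
    by_subclass = snc["subclass"].value_counts().to_dict()
    tallies = {
        "total": int(len(de)),
        "by_class": {c: int(by_class.get(c, 0)) for c in ("mRNA", "lncRNA", "sncRNA")},
        "by_sncrna_subclass": {str(k): int(v) for k, v in by_subclass.items()},
    }
    return results, tallies
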