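"""Histopathology disease classification and lineage comparison.

An animal's tissue section is scored by several observers, each counting
abnormalities in the categories atrophy, hyperplasia and vacuoles.  Each
observer's disease cutoff in a category is the control mean plus two sample
standard deviations of that observer's own control scores; an observer calls
an animal diseased when any category count strictly exceeds the cutoff, and
the final call needs agreement of at least two of the three observers.
Lineage disease frequencies are compared with a two-sided Fisher exact test
(hypergeometric probability-mass ordering, computed with exact integer
arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .config import PATHOLOGY_CATEGORIES

LINEAGES = ("control", "exposed")


@dataclass
class DiseaseCallResult:
    cutoffs: pd.DataFrame  # observer x category
    per_observer_calls: pd.DataFrame  # animal x observer booleans
    consensus: pd.Series  # animal -> bool
    table_2x2: np.ndarray  # rows lineages (control, exposed); cols (diseased, healthy)
    fisher_p: float
    frequencies: dict[str, float]


def _pivot(records: pd.DataFrame) -> pd.DataFrame:
    need = {"animal_id", "lineage", "observer"} | set(PATHOLOGY_CATEGORIES)
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"pathology records missing columns: {sorted(missing)}")
    return records


def compute_cutoffs(
    control_records: pd.DataFrame,
    sd_multiplier: float = 2.0,
    per_observer: bool = True,
) -> pd.DataFrame:
    """Disease cutoffs: control mean + ``sd_multiplier`` x sample SD (ddof=1).

    Computed separately per observer and category (each observer is compared
    against their own control scores); ``per_observer=False`` pools all
    observers' control scores into one cutoff per category.
    """
    recs = _pivot(control_records)
    if recs["animal_id"].nunique() < 2:
        raise ValueError("need at least two control animals to compute a cutoff")
    observers = sorted(recs["observer"].unique())
    rows = {}
    for obs in observers:
        sub = recs[recs["observer"] == obs] if per_observer else recs
        rows[obs] = {
            cat: float(sub[cat].mean() + sd_multiplier * sub[cat].std(ddof=1))
            for cat in PATHOLOGY_CATEGORIES
        }
    return pd.DataFrame(rows).T[list(PATHOLOGY_CATEGORIES)]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by hypergeometric probability-mass ordering.

    Ties are resolved exactly (integer weights); any zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer entries")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # column-1 margin
    if K == 0 or n == 0 or K == N or n == N:
        return 1.0
    lo, hi = max(0, K + n - N), min(K, n)
    # weight(x) = C(K, x) * C(N-K, n-x); common denominator C(N, n)
    weights = [comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return min(1.0, num / comb(N, n))


def call_disease(
    records: pd.DataFrame,
    cutoffs: pd.DataFrame,
    min_observers: int = 2,
) -> DiseaseCallResult:
    """Per-observer and consensus disease calls plus the lineage 2x2 table.

    An observer calls an animal diseased when any category count strictly
    exceeds that observer's cutoff (a count equal to the cutoff is not
    called).  Control animals are classified under the same rule.
    """
    recs = _pivot(records)
    observers = sorted(recs["observer"].unique())
    if sorted(cutoffs.index) != observers:
        raise ValueError("cutoff observers do not match record observers")
    animals = recs[["animal_id", "lineage"]].drop_duplicates().set_index("animal_id")

    calls = pd.DataFrame(False, index=animals.index, columns=observers)
    for obs in observers:
        sub = recs[recs["observer"] == obs].set_index("animal_id")
        over = pd.Series(False, index=sub.index)
        for cat in PATHOLOGY_CATEGORIES:
            over |= sub[cat] > cutoffs.at[obs, cat]
        calls.loc[over.index, obs] = over
    consensus = calls.sum(axis=1) >= min_observers

    table = np.zeros((2, 2), dtype=np.int64)
    freqs = {}
    for i, lin in enumerate(LINEAGES):
        ids = animals.index[animals["lineage"] == lin]
        diseased = int(consensus.loc[ids].sum())
        table[i] = (diseased, len(ids) - diseased)
        freqs[lin] = diseased / len(ids) if len(ids) else float("nan")
    return DiseaseCallResult(
        cutoffs=cutoffs,
        per_observer_calls=calls,
        consensus=consensus,
        table_2x2=table,
        fisher_p=fisher_exact_2x2(table),
        frequencies=freqs,
    )


def compare_lineages(
    records: pd.DataFrame,
    sd_multiplier: float = 2.0,
    min_observers: int = 2,
    per_observer_cutoffs: bool = True,
) -> DiseaseCallResult:
    """Full comparison: control cutoffs, calls on all animals, Fisher test."""
    recs = _pivot(records)
    present = set(recs["lineage"].unique())
    if not set(LINEAGES) <= present:
        raise ValueError(f"both lineages required, found: {sorted(present)}")
    cutoffs = compute_cutoffs(
        recs[recs["lineage"] == "control"], sd_multiplier, per_observer_cutoffs
    )
    return call_disease(recs, cutoffs, min_observers)
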