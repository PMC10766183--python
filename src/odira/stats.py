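"""Statistical layer: usage enrichment, rank and contingency tests, and
per-population junction balance accounting.

`usage_ratio` compares the inverted repeats *used* at junctions with the
*potential* inventory from the scanner, stratified by arm length or spacer
bin. `mann_whitney` is a Mann-Whitney rank-sum test with midrank ties and
exact enumeration for small samples; `chi_squared` is the Pearson test on a
2 x k table. `cj_tj_balance` tabulates centromere- vs telomere-proximal
junction counts per population — unbalanced counts are the signature of
junctions formed in different cell cycles via linear hairpin intermediates.

No multiple-testing correction is applied: each comparison is reported as a
single test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caller import InvertedJunction, Orientation


# ---------------------------------------------------------------------------
# Usage enrichment


def usage_ratio(used: Sequence, potential: Sequence,
                stratify_by: str = "arm_len",
                spacer_bin: int = 20) -> pd.DataFrame:
    """Used-vs-potential counts and ratio per stratum.

    *used* are junctions (anything with arm_len / spacer_len attributes);
    junctions flagged as secondary deletions (spacer > 1 kb) are excluded.
    *potential* are scanned IIRs from the same reference region. Strata with
    zero potential get a missing (NaN) ratio. *stratify_by* is 'arm_len' or
    'spacer_bin' (bins of *spacer_bin* bp).
    """
    potential = list(potential)
    if not potential:
        raise ValueError("empty potential table")
    used = [u for u in used if not getattr(u, "secondary_deletion", False)]
    if stratify_by == "arm_len":
        key = lambda r: r.arm_len
    elif stratify_by == "spacer_bin":
        key = lambda r: (r.spacer_len // spacer_bin) * spacer_bin
    else:
        raise ValueError("stratify_by must be 'arm_len' or 'spacer_bin'")
    pot = pd.Series([key(r) for r in potential]).value_counts().sort_index()
    use = pd.Series([key(r) for r in used]).value_counts().sort_index()
    table = pd.DataFrame({"potential": pot, "used": use}).fillna(0).astype(int)
    table.index.name = stratify_by
    table["ratio"] = np.where(table["potential"] > 0,
                              table["used"] / table["potential"].clip(lower=1),
                              np.nan)
    table.loc[table["potential"] == 0, "ratio"] = np.nan
    return table


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney(sample_a, sample_b, exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U for *sample_a* with a two-sided p-value.

    Ties are handled with midranks. When n_a + n_b <= *exact_max_n* the
    p-value is computed exactly by enumerating all assignments of the pooled
    observations to the two groups; otherwise the normal approximation with
    tie correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mean_u = n_a * n_b / 2
    if n_a + n_b <= exact_max_n:
        dev = abs(u_obs - mean_u)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            total += 1
            if abs(u - mean_u) >= dev - 1e-9:
                count += 1
        return u_obs, count / total
    # normal approximation with tie correction
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sd = math.sqrt(n_a * n_b / 12 * ((n + 1) - tie_term))
    if sd == 0:
        return u_obs, 1.0
    # continuity correction toward the mean
    z = (abs(u_obs - mean_u) - 0.5) / sd
    p = 2 * sps.norm.sf(max(z, 0.0))
    return u_obs, min(1.0, p)


# ---------------------------------------------------------------------------
# Chi-squared test


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared on a 2 x k contingency table.

    Returns (statistic, df = k - 1, upper-tail p). Raises when a row or
    column sums to zero (expected counts must be positive).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be >= 0")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row or column sum: expected counts must be > 0")
    expected = np.outer(row, col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = t.shape[1] - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


# ---------------------------------------------------------------------------
# CJ/TJ balance


class Balance(str, Enum):
    MATCHED = "MATCHED"
    UNBALANCED = "UNBALANCED"
    NO_INVERTED = "NO_INVERTED"


@dataclass(frozen=True)
class PopulationSummary:
    population: str
    cj_count: int
    tj_count: int
    balance: Balance


def cj_tj_balance(junctions: Iterable[InvertedJunction]) -> tuple[list[PopulationSummary], dict]:
    """Per-population CJ/TJ counts and balance classification.

    MATCHED: equal, non-zero counts; NO_INVERTED: no productive junctions;
    UNBALANCED otherwise. Aggregate counts of each class are returned
    alongside the per-population summaries.
    """
    per_pop: dict[str, list[InvertedJunction]] = {}
    for j in junctions:
        per_pop.setdefault(j.population, []).append(j)
    summaries = []
    for pop in sorted(per_pop):
        cj = sum(1 for j in per_pop[pop] if j.orientation is Orientation.CJ)
        tj = sum(1 for j in per_pop[pop] if j.orientation is Orientation.TJ)
        if cj == tj == 0:
            balance = Balance.NO_INVERTED
        elif cj == tj:
            balance = Balance.MATCHED
        else:
            balance = Balance.UNBALANCED
        summaries.append(PopulationSummary(pop, cj, tj, balance))
    aggregate = {b.value: sum(1 for s in summaries if s.balance is b) for b in Balance}
    aggregate["n_populations"] = len(summaries)
    return summaries, aggregate
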