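"""Group summaries, two-group tests and bundle morphometry comparisons.

Experimental groups are compared as mean +/- SD with either Welch's
two-sample t test or the Mann-Whitney U test (two-sided).  For small
samples (combined n <= 20) the Mann-Whitney p-value is computed by exact
enumeration of all group assignments of the midranks, which handles ties
correctly; larger samples use the normal approximation with tie
correction.  Tip-link counts are summarized as the percentage of links
present among the scored pairs of adjacent stereocilia (by convention 10
pairs per bundle).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "BundleObservation",
    "ComparisonResult",
    "tip_link_percentage",
    "summarize_tip_links",
    "compare_groups",
    "mann_whitney_u",
    "EXACT_MAX_N",
]

#: exact Mann-Whitney enumeration is used up to this combined sample size
EXACT_MAX_N = 20


@dataclass
class BundleObservation:
    """Morphometry of one hair bundle.

    ``links_present`` of ``pairs_scored`` adjacent-stereocilia pairs carry
    a tip link; ``row_pair`` labels which rows were scored ("1st-2nd" or
    "2nd-3rd").  ``heights_um`` optionally stores per-row stereocilia
    heights.
    """

    cell_id: str
    genotype: str
    age: str
    links_present: int
    pairs_scored: int = 10
    row_pair: str = "2nd-3rd"
    heights_um: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.pairs_scored < 1:
            raise ValueError("pairs_scored must be >= 1")
        if not 0 <= self.links_present <= self.pairs_scored:
            raise ValueError("links_present must lie in [0, pairs_scored]")


@dataclass
class ComparisonResult:
    label_a: str
    label_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str
    statistic: float
    p_value: float
    note: str = ""


def tip_link_percentage(obs: BundleObservation) -> float:
    """Percentage of scored stereocilia pairs carrying a tip link."""
    return 100.0 * obs.links_present / obs.pairs_scored


def summarize_tip_links(
    observations: "list[BundleObservation]",
) -> tuple[float, float, int]:
    """(mean, SD, n) of the per-bundle tip-link percentages."""
    pct = np.array([tip_link_percentage(o) for o in observations])
    if pct.size == 0:
        raise ValueError("no observations")
    return float(pct.mean()), float(pct.std(ddof=0)), int(pct.size)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample, from midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all group assignments.

    Midranks of the pooled sample are fixed; every C(n, n1) assignment of
    positions to the first group is equally likely under the null, and the
    U distribution is symmetric about n1*n2/2 (groups are exchangeable), so
    the two-sided p-value is P(|U - n1*n2/2| >= |u_obs - n1*n2/2|).
    """
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu) - 1e-9
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(a, b) -> tuple[float, float, str]:
    """(U, two-sided p, method) for the Mann-Whitney U test.

    Exact enumeration (tie-safe, via midranks) for combined n <=
    :data:`EXACT_MAX_N`; otherwise the normal approximation with tie
    correction and continuity correction as implemented in scipy.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    u = _u_statistic(x, y)
    if x.size + y.size <= EXACT_MAX_N:
        return u, _exact_mw_p(x, y), "exact_enumeration"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue), "normal_approximation"


def compare_groups(
    a,
    b,
    test: str = "mann_whitney",
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-group comparison with summary statistics.

    ``test`` is "mann_whitney" or "welch_t" (two-sided).  Degenerate inputs
    (zero variance in both groups for Welch) are reported with a note and a
    NaN p-value rather than raising.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    note = ""
    if test == "welch_t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            stat, p = float("nan"), float("nan")
            note = "degenerate: both groups have zero variance"
            if float(x[0]) == float(y[0]):
                note += " and identical values"
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "mann_whitney":
        stat, p, method = mann_whitney_u(x, y)
        note = method
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        label_a, label_b,
        float(x.mean()), float(x.std(ddof=0)), int(x.size),
        float(y.mean()), float(y.std(ddof=0)), int(y.size),
        test, stat, p, note,
    )
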