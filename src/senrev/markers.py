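"""Per-cell marker gating, quadrant analysis and nuclear-focus comparison.

Covers the BrdU-positive fraction, the p16/p21 quadrant table (with the
double-negative "reversed" fraction as headline statistic) and the comparison
of EGR2 nuclear-focus count distributions between populations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class GateResult:
    channel: str
    method: str
    threshold: float
    calls: np.ndarray  # boolean, True = positive
    positive_fraction: float


def gate_marker(
    intensities,
    method: str = "reference",
    reference=None,
    k: float = 2.0,
    threshold: float | None = None,
    channel: str = "marker",
) -> GateResult:
    """Threshold per-cell intensities into positive/negative calls.

    Methods: ``reference`` — negative-control mean + k*SD (needs
    *reference*); ``otsu`` — bimodal Otsu threshold; ``absolute`` — a
    supplied *threshold*. Cells strictly above the threshold are positive,
    so raising the threshold can never raise the positive fraction.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 20:
        raise ValueError("need >= 20 cells to gate")
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    if method == "absolute":
        if threshold is None:
            raise ValueError("absolute gating needs a threshold")
        thr = float(threshold)
    elif np.ptp(x) == 0 and method != "reference":
        raise ValueError("all intensities identical; no gate definable")
    elif method == "reference":
        if reference is None:
            raise ValueError("reference gating needs negative-control intensities")
        ref = np.asarray(reference, dtype=float)
        thr = float(ref.mean() + k * ref.std(ddof=1))
    elif method == "otsu":
        thr = float(threshold_otsu(x))
    else:
        raise ValueError(f"unknown gating method {method!r}")
    calls = x > thr
    return GateResult(channel, method, thr, calls, float(calls.mean()))


@dataclass(frozen=True)
class QuadrantTable:
    """Counts/fractions of the four p16 x p21 quadrants."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n: int

    @property
    def double_negative_fraction(self) -> float:
        return self.fractions["p16-/p21-"]


def quadrant_fractions(p16_calls, p21_calls) -> QuadrantTable:
    """Cross-tabulate aligned per-cell p16/p21 positivity calls."""
    p16 = np.asarray(p16_calls, dtype=bool)
    p21 = np.asarray(p21_calls, dtype=bool)
    if p16.shape != p21.shape:
        raise ValueError("call lists must be aligned per cell")
    n = p16.size
    if n == 0:
        raise ValueError("no cells")
    counts = {
        "p16+/p21+": int(np.sum(p16 & p21)),
        "p16+/p21-": int(np.sum(p16 & ~p21)),
        "p16-/p21+": int(np.sum(~p16 & p21)),
        "p16-/p21-": int(np.sum(~p16 & ~p21)),
    }
    fractions = {kk: c / n for kk, c in counts.items()}
    return QuadrantTable(counts, fractions, n)


def _ranksum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive two-sided permutation p for the rank-sum statistic.

    Uses midranks (tie-safe) and enumerates every assignment of the pooled
    observations to group A; two-sidedness via |R - E[R]| with E[R] fixed by
    the pooled ranks, which makes the p symmetric in A/B.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    e_r = n_a * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n_a].sum() - e_r)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        r = ranks[list(comb)].sum()
        total += 1
        if abs(r - e_r) >= obs - 1e-12:
            count += 1
    return count / total


def compare_foci(counts_a, counts_b, max_exact_n: int = 10):
    """Compare two per-nucleus focus-count distributions.

    Returns ``(median difference B-A, two-sided rank-test p, frequency
    table)``. The test is an exhaustive rank-sum permutation when both groups
    have <= *max_exact_n* nuclei, else the asymptotic Mann-Whitney U test
    with tie correction.
    """
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if a.size < 5 or b.size < 5:
        raise ValueError("need >= 5 nuclei per group")
    if np.any(a < 0) or np.any(b < 0) or np.any(a != np.floor(a)) or np.any(b != np.floor(b)):
        raise ValueError("focus counts must be non-negative integers")
    median_diff = float(np.median(b) - np.median(a))
    if a.size <= max_exact_n and b.size <= max_exact_n:
        p = _ranksum_exact_p(a.astype(float), b.astype(float))
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    hi = int(max(a.max(), b.max()))
    freq = pd.DataFrame(
        {
            "foci": np.arange(hi + 1),
            "A": [int(np.sum(a == i)) for i in range(hi + 1)],
            "B": [int(np.sum(b == i)) for i in range(hi + 1)],
        }
    )
    return median_diff, p, freq
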