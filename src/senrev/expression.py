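"""Candidate-gene selection from a three-condition expression matrix.

Genes significantly up-regulated in deep senescence (DS) versus early
proliferating (EP) cells and down-regulated again on reversal (R) are
candidate senescence drivers. Per-gene contrasts use Welch's two-sample
t-test on log-scale values; false-discovery control is Benjamini-Hochberg
per contrast; the conjunction of both directional contrasts at q < 0.05 is
ranked and truncated to the top N (default 190).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample log-intensity matrix with a sample -> condition map."""

    values: pd.DataFrame
    conditions: pd.Series  # index: sample id; value: EP | DS | R

    def __post_init__(self):
        if not set(self.values.columns) <= set(self.conditions.index):
            raise ValueError("every sample column needs a condition label")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def samples(self, condition: str) -> list[str]:
        mask = self.conditions.loc[list(self.values.columns)] == condition
        return list(self.values.columns[mask.to_numpy()])


def differential_stats(
    expr: ExpressionMatrix, cond_a: str, cond_b: str
) -> pd.DataFrame:
    """Welch t-test per gene between two conditions.

    Returns a DataFrame indexed by gene with columns ``effect`` (mean B minus
    mean A, log units), ``p`` and ``q`` (BH-adjusted). A gene with zero
    variance in both groups and zero effect is assigned p = 1 (no evidence,
    not an error); zero variance with a nonzero effect gives p = 0.
    """
    a = expr.values[expr.samples(cond_a)].to_numpy()
    b = expr.values[expr.samples(cond_b)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both conditions need >= 2 replicates")
    effect = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (effect == 0)] = 1.0
    p[degenerate & (effect != 0)] = 0.0
    out = pd.DataFrame(
        {"effect": effect, "p": p, "q": adjust_bh(p)}, index=expr.values.index
    )
    out.index.name = "gene"
    return out


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_candidates(
    up_stats: pd.DataFrame,
    down_stats: pd.DataFrame,
    q_threshold: float = 0.05,
    top_n: int = 190,
) -> list[str]:
    """Rank genes up in DS-vs-EP and down in R-vs-DS, both at q < threshold.

    Ranking: ascending q in the up (DS-vs-EP) contrast, ties broken by
    descending |effect|, then gene id; truncated to ``top_n``.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    if set(up_stats.index) != set(down_stats.index):
        raise ValueError("the two contrasts must cover the same gene universe")
    down = down_stats.loc[up_stats.index]
    keep = (
        (up_stats["effect"] > 0)
        & (down["effect"] < 0)
        & (up_stats["q"] < q_threshold)
        & (down["q"] < q_threshold)
    )
    sel = up_stats.loc[keep].copy()
    sel["abs_effect"] = sel["effect"].abs()
    sel = sel.rename_axis("gene").reset_index().sort_values(
        ["q", "abs_effect", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return sel["gene"].head(top_n).tolist()
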