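"""Consensus-motif promoter scanning and resampled-background enrichment.

Scans promoter sequences on both strands for a consensus site (default the
EGR2 motif ACGCCCACGCA) within a mismatch budget, tabulates hits per gene,
and tests whether a foreground gene set carries motif-bearing promoters more
often than size-matched gene sets sampled at random from the rest of the
universe. The enrichment p-value is empirical with the add-one correction,
so it is never zero: p = (1 + #{background >= observed}) / (1 + N_bg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """Consensus sequence with a mismatch budget, scanned on both strands."""

    consensus: str = "ACGCCCACGCA"
    max_mismatches: int = 0

    def __post_init__(self):
        c = self.consensus.upper()
        if len(c) < 4 or set(c) - set("ACGT"):
            raise ValueError("consensus must be >= 4 bases over ACGT")
        if not (0 <= self.max_mismatches < len(c)):
            raise ValueError("max_mismatches must be in [0, len(consensus))")
        object.__setattr__(self, "consensus", c)


def _mismatch_counts(arr: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatches of *pattern* against every window of *arr* (bytes). N never
    matches any pattern base."""
    L = len(pattern)
    n_win = arr.size - L + 1
    mism = np.zeros(n_win, dtype=np.int32)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    for j in range(L):
        mism += arr[j : j + n_win] != pat[j]
    return mism


def scan_sequence(seq: str, motif: MotifModel) -> list[tuple[int, str, int]]:
    """All motif windows within the mismatch budget, on both strands.

    Returns ``(position, strand, mismatches)`` tuples, 0-based window starts
    on the given sequence; a minus-strand hit at position i means the window
    ``seq[i:i+L]`` matches the reverse complement of the consensus. Sequences
    shorter than the motif yield an empty list.
    """
    s = seq.upper()
    if set(s) - set("ACGTN"):
        raise ValueError("sequence must be over ACGTN")
    L = len(motif.consensus)
    if len(s) < L:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    hits = []
    for strand, pattern in (("+", motif.consensus), ("-", reverse_complement(motif.consensus))):
        mism = _mismatch_counts(arr, pattern)
        for pos in np.nonzero(mism <= motif.max_mismatches)[0]:
            hits.append((int(pos), strand, int(mism[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def gene_motif_table(
    promoters: list[tuple[str, str]], motif: MotifModel
) -> pd.DataFrame:
    """Per-gene motif hit counts over a promoter FASTA.

    Returns a DataFrame indexed by gene with ``hit_count`` and ``has_hit``.
    Duplicate gene ids are an error; callers asking about genes not present
    should use the index, which lists exactly the scanned genes.
    """
    genes = [g for g, _ in promoters]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene ids in FASTA: {dupes}")
    counts = {g: len(scan_sequence(s, motif)) for g, s in promoters}
    df = pd.DataFrame(
        {"hit_count": pd.Series(counts, dtype=int)}
    ).rename_axis("gene")
    df["has_hit"] = df["hit_count"] > 0
    return df


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float  # foreground statistic
    background: np.ndarray  # one statistic per background draw
    n_background: int
    p_value: float
    seed: int
    statistic: str = "presence"

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("empirical p must lie in (0, 1]")


def enrichment_test(
    foreground,
    universe,
    promoters: list[tuple[str, str]],
    motif: MotifModel,
    n_background: int = 1000,
    seed: int = 0,
    statistic: str = "presence",
) -> EnrichmentResult:
    """Motif enrichment of a foreground gene set against resampled backgrounds.

    The statistic is the fraction of genes with >= 1 promoter hit
    (``presence``, default) or the mean hit count (``counts``). Each of the
    ``n_background`` draws is a size-matched sample without replacement from
    universe minus foreground.
    """
    fg = sorted(set(foreground))
    uni = sorted(set(universe))
    if not fg:
        raise ValueError("foreground is empty")
    if not set(fg) <= set(uni):
        raise ValueError("foreground must be a subset of the universe")
    pool = sorted(set(uni) - set(fg))
    if len(pool) < len(fg):
        raise ValueError(
            "universe too small for disjoint size-matched background sampling"
        )
    if n_background < 100:
        raise ValueError("n_background must be >= 100")
    table = gene_motif_table(promoters, motif)
    missing = sorted(set(uni) - set(table.index))
    if missing:
        raise ValueError(f"universe genes missing from the promoter FASTA: {missing}")
    col = {"presence": "has_hit", "counts": "hit_count"}[statistic]
    values = table[col].astype(float)
    observed = float(values.loc[fg].mean())
    rng = np.random.default_rng(seed % (2**31))
    pool_vals = values.loc[pool].to_numpy()
    bg = np.empty(n_background)
    for i in range(n_background):
        draw = rng.choice(len(pool_vals), size=len(fg), replace=False)
        bg[i] = pool_vals[draw].mean()
    p = (1 + int(np.sum(bg >= observed - 1e-12))) / (1 + n_background)
    return EnrichmentResult(
        observed=observed,
        background=bg,
        n_background=n_background,
        p_value=p,
        seed=seed,
        statistic=statistic,
    )
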