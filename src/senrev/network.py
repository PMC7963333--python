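"""Seed expansion over a protein-interaction edge list and categorisation.

Screen-hit seed genes are expanded by their first-degree interactors
(depth 1 only; no transitive expansion) and every gene in the merged set is
assigned one of six functional categories or "unassigned".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .synthdata import SIX_CATEGORIES

VALID_CATEGORIES = SIX_CATEGORIES + ("unassigned",)


@dataclass(frozen=True)
class ExpansionResult:
    seeds: frozenset
    interactors: frozenset

    @property
    def merged(self) -> frozenset:
        return self.seeds | self.interactors

    def __post_init__(self):
        if self.seeds & self.interactors:
            raise ValueError("seeds and interactors must be disjoint")


def expand_seeds(seeds, edges, max_interactors: int | None = None) -> ExpansionResult:
    """All non-seed genes adjacent to at least one seed.

    With *max_interactors*, interactors are capped by descending number of
    seed neighbours, ties broken lexicographically. Seeds absent from the
    edge list simply contribute no neighbours.
    """
    seed_set = frozenset(seeds)
    if not seed_set:
        raise ValueError("seed set is empty")
    seed_degree: Counter = Counter()
    for edge in edges:
        pair = tuple(edge)
        if len(pair) != 2:
            continue  # self-loop survived upstream; ignore
        a, b = pair
        if a in seed_set and b not in seed_set:
            seed_degree[b] += 1
        elif b in seed_set and a not in seed_set:
            seed_degree[a] += 1
    interactors = sorted(seed_degree, key=lambda g: (-seed_degree[g], g))
    if max_interactors is not None:
        interactors = interactors[:max_interactors]
    return ExpansionResult(seeds=seed_set, interactors=frozenset(interactors))


def categorize(genes, annotation: dict[str, str]):
    """Map each gene to its functional category; absent genes -> "unassigned".

    Returns ``(category map, summary counts per category)``. An annotation
    value outside the six categories (plus "unassigned") is an error.
    """
    bad = sorted(set(annotation.values()) - set(VALID_CATEGORIES))
    if bad:
        raise ValueError(f"unknown category labels: {bad}")
    mapping = {g: annotation.get(g, "unassigned") for g in sorted(set(genes))}
    summary = Counter(mapping.values())
    return mapping, dict(summary)
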