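"""Over-representation analysis of gene sets against annotated categories.

A deliberately plain, open stand-in for proprietary functional-enrichment
engines: for each category the overlap with the query is tested with the
one-sided upper-tail hypergeometric distribution (Fisher's exact test,
greater alternative) against a user-supplied gene universe. Each category is
intersected with the universe before testing, so genes outside the measured
universe never inflate category sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .disease_comparison import CategoryAnnotation

DEFAULT_TOP = 5


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    overlap: int
    query_size: int
    category_size: int
    universe_size: int
    p_value: float
    neg_log10_p: float

    def __post_init__(self):
        if self.overlap > min(self.query_size, self.category_size):
            raise ValueError("overlap cannot exceed query or category size")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def overrepresentation(
    query: set[str],
    annotation: CategoryAnnotation,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail P per category, sorted by ascending P.

    ``P(overlap >= k)`` for drawing ``|query|`` genes from a universe of
    ``N`` containing ``K`` category members. Ties are ordered by category
    name. Categories with no universe member are skipped.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("universe must not be empty")
    query = {g.upper() for g in query}
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe: {', '.join(extra)}")
    results = []
    for name, genes in annotation.categories.items():
        members = genes & universe
        if not members:
            continue
        overlap = len(query & members)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query))
        )
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                category=name,
                overlap=overlap,
                query_size=len(query),
                category_size=len(members),
                universe_size=len(universe),
                p_value=p,
                neg_log10_p=-math.log10(p) if p > 0 else math.inf,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


def top_categories(
    results: Sequence[EnrichmentResult], k: int = DEFAULT_TOP
) -> list[EnrichmentResult]:
    """First ``min(k, n)`` categories by ascending P; ties by category name."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return sorted(results, key=lambda r: (r.p_value, r.category))[:k]
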