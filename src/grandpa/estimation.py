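"""Empirical estimation of the joint label distributions P_L and P_C.

P_L(c) is the fraction of vertices whose full label vector equals category
``c``; P_C({c, c'}) is the fraction of edges whose endpoint categories form
the unordered pair {c, c'}.  Both are plain empirical frequencies — no
smoothing — so categories unseen in the source graph carry zero mass and are
omitted from the sparse support.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .core import (
    CategoryDistribution,
    PairDistribution,
    PropertyGraph,
    canonical_pair,
)

__all__ = [
    "estimate_vertex_distribution",
    "estimate_edge_distribution",
    "vertex_distribution_frame",
    "edge_distribution_frame",
]


def estimate_vertex_distribution(graph: PropertyGraph) -> CategoryDistribution:
    """Empirical distribution of joint label categories over vertices."""
    if graph.n_vertices == 0:
        raise ValueError("cannot estimate from empty graph")
    counts = Counter(graph.category(v) for v in graph.vertices)
    return CategoryDistribution(counts)


def estimate_edge_distribution(graph: PropertyGraph) -> PairDistribution:
    """Empirical distribution of unordered endpoint-category pairs over edges."""
    if graph.n_edges == 0:
        raise ValueError("cannot estimate edge distribution from edgeless graph")
    counts = Counter(
        canonical_pair(graph.category(u), graph.category(v)) for u, v in graph.edges
    )
    return PairDistribution(counts)


def vertex_distribution_frame(dist: CategoryDistribution) -> pd.DataFrame:
    """Tabular view of P_L: one row per category, with count and probability."""
    rows = [
        {"category": "|".join(cat), "count": dist.support_counts[cat], "probability": p}
        for cat, p in sorted(dist.mass.items())
    ]
    return pd.DataFrame(rows, columns=["category", "count", "probability"])


def edge_distribution_frame(dist: PairDistribution) -> pd.DataFrame:
    """Tabular view of P_C: one row per unordered category pair."""
    rows = [
        {
            "category_a": "|".join(a),
            "category_b": "|".join(b),
            "count": dist.support_counts[(a, b)],
            "probability": p,
        }
        for (a, b), p in sorted(dist.mass.items())
    ]
    return pd.DataFrame(
        rows, columns=["category_a", "category_b", "count", "probability"]
    )
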