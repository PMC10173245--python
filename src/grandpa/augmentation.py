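"""Structural label augmentation.

Generation preserves only what the label vectors encode, so structure that
matters — degree, community membership, bridging position — is folded into
the label space before estimation.  Each operation here returns a copy of
the graph whose schema gains one dimension; vertices and edges are never
touched.

Degree bins follow empirical quantiles (right-closed, ties to the lower
bin) or fixed integer widths.  Communities come from either Girvan–Newman
edge-betweenness splitting (cut at the modularity-maximal level) or greedy
modularity maximisation; both are deterministic given the vertex order, and
the resulting membership is thereafter an ordinary categorical label — the
generator never re-runs detection while sampling.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from bisect import bisect_left
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np

from .core import LabelDimension, PropertyGraph

__all__ = [
    "BinningScheme",
    "degree_bin_labels",
    "community_labels",
    "detect_communities",
    "linchpin_labels",
    "linchpin_scores",
    "add_structural_label",
]

log = logging.getLogger(__name__)

COMMUNITY_METHODS = ("edge_betweenness", "fast_greedy")


@dataclasses.dataclass(frozen=True)
class BinningScheme:
    """How to discretise a degree distribution into labels.

    ``quantile`` mode cuts at the empirical k/n_b quantiles; ``fixed_width``
    mode uses contiguous integer intervals [0,w), [w,2w), ...
    """

    mode: str = "quantile"
    n_b: int | None = None
    width: int | None = None

    def __post_init__(self) -> None:
        if self.mode == "quantile":
            if not self.n_b or self.n_b < 1 or self.width is not None:
                raise ValueError("quantile mode requires n_b >= 1 and no width")
        elif self.mode == "fixed_width":
            if not self.width or self.width < 1 or self.n_b is not None:
                raise ValueError("fixed_width mode requires width >= 1 and no n_b")
        else:
            raise ValueError(f"unknown binning mode {self.mode!r}")


def _quantile_boundaries(degrees: Sequence[int], n_b: int) -> list[int]:
    """Right-closed bin upper boundaries at the k/n_b empirical quantiles."""
    arr = np.sort(np.asarray(degrees))
    cuts = [
        int(np.quantile(arr, k / n_b, method="inverted_cdf")) for k in range(1, n_b)
    ]
    # collapse duplicate boundaries produced by degree ties
    uniq: list[int] = []
    for c in cuts:
        if not uniq or c > uniq[-1]:
            uniq.append(c)
    return uniq


def degree_bin_labels(
    graph: PropertyGraph,
    scheme: BinningScheme = BinningScheme("quantile", n_b=10),
    name: str = "degree_bin",
) -> PropertyGraph:
    """Append a label dimension encoding each vertex's degree bin.

    Quantile mode: bin k is the right-closed interval up to the k/n_b
    empirical quantile; a degree equal to a boundary goes to the lower bin.
    When ``n_b`` exceeds the number of distinct degrees the scheme collapses
    to one bin per distinct degree, with a warning.  Fixed-width mode: the
    bin index is ``floor(degree / width)``.
    """
    degrees = graph.degrees()
    values = list(degrees.values())
    if scheme.mode == "quantile":
        n_distinct = len(set(values))
        n_b = scheme.n_b
        if n_b > n_distinct:
            warnings.warn(
                f"n_b={n_b} exceeds {n_distinct} distinct degrees; "
                "collapsing to distinct-degree bins",
                stacklevel=2,
            )
        boundaries = _quantile_boundaries(values, min(n_b, n_distinct))
        assignment = {
            v: f"b{bisect_left(boundaries, d) + 1}" for v, d in degrees.items()
        }
        meta = {"mode": "quantile", "n_b": n_b, "boundaries": tuple(boundaries)}
    else:
        assignment = {v: f"b{d // scheme.width}" for v, d in degrees.items()}
        meta = {"mode": "fixed_width", "width": scheme.width}
    dim = LabelDimension(
        name, tuple(set(assignment.values())), origin="degree_bin", metadata=meta
    )
    return graph.with_dimension(dim, assignment)


def _modularity_best_girvan_newman(g: nx.Graph) -> list[set[str]]:
    """Girvan–Newman dendrogram cut at the modularity-maximal level.

    The initial partition into connected components is a candidate level, so
    disconnected inputs are handled and an edgeless graph short-circuits.
    """
    components = [set(c) for c in nx.connected_components(g)]
    if g.number_of_edges() == 0:
        return components
    best, best_q = components, nx.community.modularity(g, components)
    for level in nx.community.girvan_newman(g):
        parts = [set(c) for c in level]
        q = nx.community.modularity(g, parts)
        if q > best_q:
            best, best_q = parts, q
    return best


def detect_communities(graph: PropertyGraph, method: str) -> dict[str, str]:
    """Partition vertices into communities; return vertex -> 'c1'..'cK'.

    Community ids are ordered by descending size, ties broken by the
    smallest member id, so the labelling is deterministic.
    """
    if method not in COMMUNITY_METHODS:
        raise ValueError(f"unknown community method {method!r}; use {COMMUNITY_METHODS}")
    g = graph.to_networkx()
    if method == "fast_greedy":
        parts = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    else:
        parts = _modularity_best_girvan_newman(g)
    parts.sort(key=lambda c: (-len(c), min(c)))
    membership: dict[str, str] = {}
    for i, part in enumerate(parts, start=1):
        for v in part:
            membership[v] = f"c{i}"
    return membership


def community_labels(
    graph: PropertyGraph, method: str = "fast_greedy", name: str = "community"
) -> PropertyGraph:
    """Append detected community membership as a label dimension."""
    membership = detect_communities(graph, method)
    dim = LabelDimension(
        name,
        tuple(set(membership.values())),
        origin="community",
        metadata={"method": method},
    )
    return graph.with_dimension(dim, membership)


def linchpin_scores(graph: PropertyGraph, attribute_dimension: str) -> dict[str, float]:
    """Linchpin score in [0, 1] per vertex.

    score(v) = fraction of v's neighbours u for whom v is their only contact
    with v's value on ``attribute_dimension`` — i.e. no other neighbour of u
    shares v's value.  A vertex whose kind is redundant everywhere scores 0;
    a hub that is its neighbours' sole link to its kind scores 1.  Isolated
    vertices score 0.
    """
    idx = graph.schema.index(attribute_dimension)
    value = {v: graph.labels[v][idx] for v in graph.vertices}
    scores: dict[str, float] = {}
    for v in graph.vertices:
        nbrs = graph.neighbors(v)
        if not nbrs:
            scores[v] = 0.0
            continue
        sole = sum(
            1
            for u in nbrs
            if not any(w != v and value[w] == value[v] for w in graph.neighbors(u))
        )
        scores[v] = sole / len(nbrs)
    return scores


def linchpin_labels(
    graph: PropertyGraph,
    attribute_dimension: str,
    cuts: tuple[float, float] = (0.0, 0.2),
    name: str = "linchpin",
) -> PropertyGraph:
    """Append a 3-level linchpin-centrality label.

    "none" for a score of exactly ``cuts[0]`` (default 0), "low" strictly
    between the cuts, "high" at or above ``cuts[1]`` (default 0.2).
    """
    lo, hi = cuts
    scores = linchpin_scores(graph, attribute_dimension)

    def level(s: float) -> str:
        if s <= lo:
            return "none"
        return "high" if s >= hi else "low"

    assignment = {v: level(s) for v, s in scores.items()}
    dim = LabelDimension(
        name,
        ("none", "low", "high"),
        origin="linchpin",
        metadata={"cuts": cuts, "attribute_dimension": attribute_dimension},
    )
    return graph.with_dimension(dim, assignment)


def add_structural_label(
    graph: PropertyGraph, name: str, values: Mapping[str, str]
) -> PropertyGraph:
    """Append an arbitrary user-supplied categorical dimension.

    ``values`` must cover every vertex; any other vertex metric (closeness
    quartiles, k-core shells, ...) can be folded into generation this way.
    """
    missing = [v for v in graph.vertices if v not in values]
    if missing:
        raise ValueError(f"structural label {name!r} missing vertices: {missing[:5]}")
    dim = LabelDimension(
        name, tuple(set(str(x) for x in values.values())), origin="custom_structural"
    )
    return graph.with_dimension(dim, values)
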