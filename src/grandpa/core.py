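"""Property-graph data model shared by every other module.

A *property graph* is an undirected simple graph whose vertices carry an
ordered vector of categorical labels.  The vector of one vertex, taken as a
whole, is its *joint label category*; the empirical distribution of those
categories over vertices (and over the endpoint pairs of edges) is what the
generator preserves.

Only categorical labels participate in generation.  Numeric vertex metrics
(degree, centralities, ...) must first be discretised into labels by one of
the augmentation operations.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping
from typing import Callable, Optional

__all__ = [
    "LabelDimension",
    "LabelSchema",
    "PropertyGraph",
    "CategoryDistribution",
    "PairDistribution",
    "GenerationSpec",
    "validate",
    "canonical_edge",
    "canonical_pair",
]

#: origins a label dimension may declare; used by evaluation to tell
#: attribute labels apart from structural augmentation labels.
VALID_ORIGINS = (
    "attribute",
    "degree_bin",
    "community",
    "linchpin",
    "custom_structural",
)


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


def canonical_pair(a: tuple, b: tuple) -> tuple[tuple, tuple]:
    """Canonical form of an unordered pair of joint label categories."""
    return (a, b) if a <= b else (b, a)


@dataclasses.dataclass(frozen=True)
class LabelDimension:
    """One label dimension: a name, its finite value set, and its origin.

    ``metadata`` may carry provenance such as bin boundaries; it does not
    take part in equality.
    """

    name: str
    values: tuple[str, ...]
    origin: str = "attribute"
    metadata: Mapping = dataclasses.field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("dimension name must be non-empty")
        if not self.values:
            raise ValueError(f"dimension {self.name!r}: value set must be non-empty")
        ordered = tuple(sorted(set(str(v) for v in self.values)))
        object.__setattr__(self, "values", ordered)
        if self.origin not in VALID_ORIGINS:
            raise ValueError(
                f"dimension {self.name!r}: unknown origin {self.origin!r}; "
                f"expected one of {VALID_ORIGINS}"
            )

    @property
    def cardinality(self) -> int:
        return len(self.values)


@dataclasses.dataclass(frozen=True)
class LabelSchema:
    """Ordered collection of label dimensions.

    ``n_dimensions`` is the number M of label sets and ``n_joint_categories``
    the product of their cardinalities, i.e. the number N of possible joint
    label categories.
    """

    dimensions: tuple[LabelDimension, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        names = [d.name for d in self.dimensions]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate dimension names in schema: {names}")

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)

    @property
    def n_joint_categories(self) -> int:
        return math.prod(d.cardinality for d in self.dimensions)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no dimension named {name!r} in schema {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def with_dimension(self, dimension: LabelDimension) -> "LabelSchema":
        if dimension.name in self:
            raise ValueError(f"dimension {dimension.name!r} already present in schema")
        return LabelSchema(self.dimensions + (dimension,))


class PropertyGraph:
    """Undirected simple graph with per-vertex categorical label vectors.

    Parameters
    ----------
    vertices : iterable of str
        Vertex identifiers (opaque text tokens).
    edges : iterable of (str, str)
        Undirected edges; stored in canonical sorted-pair form, duplicates
        collapse silently.  Self-loops are kept as given and flagged by
        :func:`validate`.
    labels : mapping vertex -> tuple of str
        One label vector per vertex, aligned with ``schema.dimensions``.
    schema : LabelSchema
    """

    def __init__(
        self,
        vertices: Iterable[str],
        edges: Iterable[tuple[str, str]],
        labels: Optional[Mapping[str, tuple]] = None,
        schema: LabelSchema = LabelSchema(),
    ) -> None:
        self.vertices: tuple[str, ...] = tuple(str(v) for v in vertices)
        self.edges: frozenset[tuple[str, str]] = frozenset(
            canonical_edge(str(u), str(v)) for u, v in edges
        )
        labels = labels or {}
        self.labels: dict[str, tuple[str, ...]] = {
            str(v): tuple(str(x) for x in vec) for v, vec in labels.items()
        }
        if schema.n_dimensions == 0 and not self.labels:
            self.labels = {v: () for v in self.vertices}
        self.schema = schema
        self._adjacency: Optional[dict[str, set[str]]] = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adjacency is None:
            adj: dict[str, set[str]] = {v: set() for v in self.vertices}
            for u, v in self.edges:
                if u in adj and v in adj:
                    adj[u].add(v)
                    adj[v].add(u)
        # a vertex referenced only by an edge is invalid; validate() reports it
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, v: str) -> set[str]:
        return self.adjacency[v]

    def degree(self, v: str) -> int:
        return len(self.adjacency[v])

    def degrees(self) -> dict[str, int]:
        return {v: len(nbrs) for v, nbrs in self.adjacency.items()}

    def category(self, v: str) -> tuple[str, ...]:
        """The joint label category of vertex ``v`` (its full label vector)."""
        return self.labels[v]

    # -- construction helpers --------------------------------------------

    def with_dimension(
        self, dimension: LabelDimension, values: Mapping[str, str]
    ) -> "PropertyGraph":
        """Return a copy whose schema gains ``dimension``; topology unchanged."""
        missing = [v for v in self.vertices if v not in values]
        if missing:
            raise ValueError(
                f"values for dimension {dimension.name!r} missing vertices: {missing[:5]}"
            )
        new_labels = {
            v: self.labels.get(v, ()) + (str(values[v]),) for v in self.vertices
        }
        return PropertyGraph(
            self.vertices, self.edges, new_labels, self.schema.with_dimension(dimension)
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for v in self.vertices:
            attrs = dict(zip(self.schema.names, self.labels.get(v, ())))
            g.add_node(v, **attrs)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PropertyGraph):
            return NotImplemented
        return (
            set(self.vertices) == set(other.vertices)
            and self.edges == other.edges
            and self.labels == other.labels
            and self.schema == other.schema
        )

    def __repr__(self) -> str:
        return (
            f"PropertyGraph(|V|={self.n_vertices}, |E|={self.n_edges}, "
            f"dims={list(self.schema.names)})"
        )


class _EmpiricalDistribution:
    """Shared bookkeeping for sparse count-backed probability masses."""

    def __init__(self, support_counts: Mapping) -> None:
        counts = {k: int(c) for k, c in support_counts.items() if c != 0}
        if any(c < 0 for c in counts.values()):
            raise ValueError("support counts must be non-negative")
        if not counts:
            raise ValueError("distribution needs at least one positive count")
        self.support_counts: dict = dict(counts)
        self.total: int = sum(counts.values())
        self.mass: dict = {k: c / self.total for k, c in counts.items()}

    def __len__(self) -> int:
        return len(self.support_counts)

    def __getitem__(self, key) -> float:
        return self.mass.get(key, 0.0)


class CategoryDistribution(_EmpiricalDistribution):
    """Probability mass over joint label categories, P_L.

    Keys are label-vector tuples; only categories with positive support are
    stored (the joint space can be combinatorially large after augmentation).
    """


class PairDistribution(_EmpiricalDistribution):
    """Probability mass over unordered pairs of joint label categories, P_C.

    Keys are canonical (sorted) pairs of label-vector tuples, so
    ``mass[{a,b}] == mass[{b,a}]`` by construction.
    """

    def __init__(self, support_counts: Mapping) -> None:
        canon: dict = {}
        for (a, b), c in support_counts.items():
            key = canonical_pair(tuple(a), tuple(b))
            canon[key] = canon.get(key, 0) + c
        super().__init__(canon)

    def __getitem__(self, key) -> float:
        a, b = key
        return self.mass.get(canonical_pair(tuple(a), tuple(b)), 0.0)


@dataclasses.dataclass(frozen=True)
class GenerationSpec:
    """Target size and control parameters for one generation run.

    ``tolerance`` is the error threshold of the resample-until-good-enough
    loop: generation repeats with fresh sub-seeds while the error metric
    (degree-CCDF NRMSE by default) stays above it.  ``tolerance=0`` asks for
    exact degree-curve recovery and simply exhausts ``max_iterations`` when
    that is unattainable, returning the best attempt.
    """

    n_t: int
    m_t: int
    seed: int = 0
    tolerance: float = 0.0
    max_iterations: int = 20
    error_metric: Optional[Callable] = None  # (source, generated) -> float

    def __post_init__(self) -> None:
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")
        if self.m_t < 0:
            raise ValueError("m_t must be >= 0")
        if self.m_t > self.n_t * (self.n_t - 1) // 2:
            raise ValueError(
                f"m_t={self.m_t} exceeds the simple-graph maximum for n_t={self.n_t}"
            )
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


def validate(graph: PropertyGraph) -> list[str]:
    """Check every PropertyGraph invariant; return a list of violations.

    The empty list means the graph is well formed.  Violations name the
    offending vertex, edge or dimension; nothing is raised.
    """
    problems: list[str] = []
    vset = set(graph.vertices)
    if len(vset) != len(graph.vertices):
        problems.append("duplicate vertex ids")
    for u, v in sorted(graph.edges):
        if u == v:
            problems.append(f"self-loop at {u}")
        if u not in vset:
            problems.append(f"edge ({u},{v}) references unknown vertex {u}")
        if v not in vset:
            problems.append(f"edge ({u},{v}) references unknown vertex {v}")
    dims = graph.schema.dimensions
    for v in graph.vertices:
        vec = graph.labels.get(v)
        if vec is None:
            problems.append(f"vertex {v} has no label vector")
            continue
        if len(vec) != len(dims):
            problems.append(
                f"vertex {v}: label vector length {len(vec)} != {len(dims)} dimensions"
            )
            continue
        for dim, value in zip(dims, vec):
            if value not in dim.values:
                problems.append(
                    f"vertex {v}: value {value!r} not in dimension {dim.name!r}"
                )
    return problems
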