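"""In-repo data sources: the Zachary karate club graph, stochastic
attribute labellers, a synthetic patient-sharing network, and a purpose-
built homophily-regression test-bed.

Everything here is generated programmatically and seeded, so the full
pipeline is exercisable without any download or confidential data.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np

from .core import LabelDimension, LabelSchema, PropertyGraph

__all__ = [
    "load_karate",
    "CorrelatedLabelSpec",
    "assign_correlated_labels",
    "default_karate_label_specs",
    "labeled_karate",
    "SyntheticHealthcareSpec",
    "synthetic_healthcare_graph",
    "homophily_testbed",
]


def load_karate() -> PropertyGraph:
    """The canonical Zachary karate club graph (34 vertices, 78 edges).

    Vertex ids are zero-padded ("v00".."v33") so lexical order matches the
    conventional numbering; the label schema starts empty.
    """
    g = nx.karate_club_graph()
    rename = {i: f"v{i:02d}" for i in g.nodes}
    vertices = [rename[i] for i in sorted(g.nodes)]
    edges = [(rename[u], rename[v]) for u, v in g.edges]
    return PropertyGraph(vertices, edges, {v: () for v in vertices}, LabelSchema())


@dataclasses.dataclass(frozen=True)
class CorrelatedLabelSpec:
    """Stochastic label construction correlated with a structural driver.

    Vertices are stratified by the empirical quantiles of ``driver``
    (degree or closeness centrality); the vertex's stratum selects a row of
    ``level_weights``, and its label level is drawn from that row.  The
    expected label-driver association is thus fixed by the weight matrix
    while individual assignments stay noisy.
    """

    dimension_name: str
    level_weights: tuple[tuple[float, ...], ...]
    driver: str = "degree"
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.level_weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("level_weights must be a matrix (strata x levels)")
        if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0):
            raise ValueError("each level_weights row must be a probability vector")
        if self.driver not in ("degree", "closeness"):
            raise ValueError(f"unknown driver {self.driver!r}")

    @property
    def n_strata(self) -> int:
        return len(self.level_weights)

    @property
    def n_levels(self) -> int:
        return len(self.level_weights[0])


def _driver_values(graph: PropertyGraph, driver: str) -> dict[str, float]:
    if driver == "degree":
        return {v: float(d) for v, d in graph.degrees().items()}
    closeness = nx.closeness_centrality(graph.to_networkx())
    return {v: float(c) for v, c in closeness.items()}


def _strata(values: dict[str, float], n_strata: int) -> dict[str, int]:
    """Quantile stratum per vertex: right-closed cuts at k/n_strata."""
    arr = np.sort(np.array(list(values.values())))
    cuts = [np.quantile(arr, k / n_strata, method="inverted_cdf")
            for k in range(1, n_strata)]
    out = {}
    for v, x in values.items():
        s = 0
        for c in cuts:
            if x > c:
                s += 1
        out[v] = s
    return out


def assign_correlated_labels(
    graph: PropertyGraph, spec: CorrelatedLabelSpec
) -> PropertyGraph:
    """Append one stochastic label dimension drawn per the spec.

    Deterministic given ``spec.seed``; topology untouched.
    """
    rng = np.random.default_rng(spec.seed)
    driver = _driver_values(graph, spec.driver)
    strata = _strata(driver, spec.n_strata)
    weights = np.asarray(spec.level_weights, dtype=float)
    levels = [f"l{i + 1}" for i in range(spec.n_levels)]
    assignment = {}
    for v in sorted(graph.vertices):
        assignment[v] = levels[rng.choice(spec.n_levels, p=weights[strata[v]])]
    dim = LabelDimension(
        spec.dimension_name,
        tuple(levels),
        origin="attribute",
        metadata={"driver": spec.driver, "n_strata": spec.n_strata},
    )
    return graph.with_dimension(dim, assignment)


def default_karate_label_specs(seed: int = 0) -> tuple[CorrelatedLabelSpec, ...]:
    """Default two-attribute construction for the karate study.

    A 3-level label whose sampling weights track degree terciles, and a
    4-level label tracking closeness-centrality quartiles.  Each stratum
    concentrates ~70-80% of its mass on its "own" level, leaving genuine
    noise in individual assignments.
    """
    degree_weights = (
        (0.80, 0.15, 0.05),
        (0.15, 0.70, 0.15),
        (0.05, 0.15, 0.80),
    )
    closeness_weights = tuple(
        tuple(0.7 if j == i else 0.1 for j in range(4)) for i in range(4)
    )
    return (
        CorrelatedLabelSpec("activity", degree_weights, driver="degree", seed=seed),
        CorrelatedLabelSpec(
            "reach", closeness_weights, driver="closeness", seed=seed + 1
        ),
    )


def labeled_karate(seed: int = 0) -> PropertyGraph:
    """Karate graph with the two default correlated attribute labels."""
    g = load_karate()
    for spec in default_karate_label_specs(seed):
        g = assign_correlated_labels(g, spec)
    return g


@dataclasses.dataclass(frozen=True)
class SyntheticHealthcareSpec:
    """Planted-partition stand-in for a physician patient-sharing subgraph.

    Synthetic: emulates the qualitative features of a claims-derived
    unipartite network — around ten communities of heterogeneous size
    (hospitals / regions / working groups), a specialty attribute
    concentrated within communities, and a few sparse bridge vertices with
    a distinct specialty — at a reduced scale.  It does not reproduce any
    real claims data.
    """

    community_sizes: tuple[int, ...] = (45, 40, 35, 32, 28, 25, 22, 20, 19, 18)
    within_density: float = 0.60
    between_density: float = 0.0005
    n_specialties: int = 6
    specialty_community_concentration: float = 0.8
    n_bridge_vertices: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_density <= 1 or not 0 <= self.between_density <= 1:
            raise ValueError("densities must lie in [0, 1]")
        if not 0 <= self.specialty_community_concentration <= 1:
            raise ValueError("concentration must lie in [0, 1]")
        if min(self.community_sizes) < 1 or self.n_specialties < 1:
            raise ValueError("community sizes and specialty count must be positive")

    @property
    def n_vertices(self) -> int:
        return sum(self.community_sizes)


def synthetic_healthcare_graph(
    spec: SyntheticHealthcareSpec = SyntheticHealthcareSpec(),
) -> PropertyGraph:
    """Sample the synthetic patient-sharing network.

    Planted partition: each within-community vertex pair is an edge with
    probability ``within_density``, each between-community pair with
    ``between_density``.  Specialties are drawn per vertex from a
    community-specific mixture putting ``specialty_community_concentration``
    on the community's home specialty.  Bridge vertices are appended after
    partition sampling (community sizes stay as specified); each receives a
    distinct "bridge" specialty and a handful of edges into two random
    communities, to exercise linchpin augmentation.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.community_sizes
    n = spec.n_vertices
    community_of = np.repeat(np.arange(len(sizes)), sizes)
    ids = [f"p{i:03d}" for i in range(n)]

    edges: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            p = (
                spec.within_density
                if community_of[i] == community_of[j]
                else spec.between_density
            )
            if rng.random() < p:
                edges.append((ids[i], ids[j]))

    specialties = [f"s{k + 1}" for k in range(spec.n_specialties)]
    conc = spec.specialty_community_concentration
    assignment: dict[str, str] = {}
    for i in range(n):
        home = community_of[i] % spec.n_specialties
        if spec.n_specialties == 1 or rng.random() < conc:
            assignment[ids[i]] = specialties[home]
        else:
            others = [s for k, s in enumerate(specialties) if k != home]
            assignment[ids[i]] = others[rng.integers(len(others))]

    vertices = list(ids)
    # bridges link pairs of the largest communities (linchpin physicians
    # connecting major systems); attaching them to small communities makes
    # greedy modularity glue the pair together, which would confound the
    # community-preservation comparison.
    hub_pool = np.argsort(sizes)[::-1][: min(4, len(sizes))]
    for b in range(spec.n_bridge_vertices):
        bid = f"b{b:02d}"
        vertices.append(bid)
        assignment[bid] = "bridge"
        comms = rng.choice(hub_pool, size=min(2, len(hub_pool)), replace=False)
        for c in comms:
            members = [ids[i] for i in np.flatnonzero(community_of == c)]
            targets = rng.choice(len(members), size=min(3, len(members)), replace=False)
            edges.extend((bid, members[t]) for t in targets)

    dim = LabelDimension(
        "specialty", tuple(specialties) + ("bridge",), origin="attribute"
    )
    labels = {v: (assignment[v],) for v in vertices}
    return PropertyGraph(vertices, edges, labels, LabelSchema((dim,)))


def homophily_testbed(
    n_stars: int = 300,
    intercept: float = math.log(0.25),
    slope: float = (math.log(4.0) - math.log(0.25)) / 100.0,
    seed: int = 0,
) -> tuple[PropertyGraph, float]:
    """Graph whose specialty labels realise a known homophily model.

    Builds disjoint three-vertex stars (an anchor with two leaves) whose
    value assignments are mixed so that, marginally, a vertex's probability
    of carrying the target specialty "T" given x = percentage of
    same-value neighbours is exactly ``logistic(intercept + slope * x)``
    at the design points x in {0, 50, 100}.  Non-target vertices carry
    fresh one-off specialty values so no unintended sharing arises.

    Returns the graph and the true odds ratio ``exp(slope)``; fitting
    :func:`grandpa.evaluation.homophily_odds_ratio` on dimension
    "specialty" with target {"T"} recovers the slope.

    Star mix (shares of the anchor's two leaves that copy its value):
    2-share, 1-share and 0-share stars in proportions 0.2/0.4/0.4, with
    target rates per star type solved from the three cell probabilities.
    Raises if the requested (intercept, slope) make that mix infeasible.
    """

    def logistic(z: float) -> float:
        return 1.0 / (1.0 + math.exp(-z))

    p0 = logistic(intercept)
    p50 = logistic(intercept + 50 * slope)
    p100 = logistic(intercept + 100 * slope)
    s2, s1, s0 = 0.2, 0.4, 0.4
    t1 = p50  # anchor-of-1-share target rate (it sits at x=50)
    t2 = (p100 * (3 * s2 + s1) - s1 * t1) / (3 * s2)
    h = p0  # P(target) for the 1-share star's lone non-sharing leaf
    t0 = p0  # 0-share anchor target rate (x=0)
    h0 = p0 * (s1 * t1 + 2 * s0) / (2 * s0 * (1 - p0))
    for name, val in (("t2", t2), ("h0", h0)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(
                f"infeasible homophily design: {name}={val:.3f} outside [0,1] "
                f"for intercept={intercept:.3f}, slope={slope:.4f}"
            )

    rng = np.random.default_rng(seed)
    vertices: list[str] = []
    edges: list[tuple[str, str]] = []
    labels: dict[str, tuple[str, ...]] = {}
    fresh = iter(range(10 ** 9))

    def off_value() -> str:
        return f"o{next(fresh)}"

    for k in range(n_stars):
        a, u1, u2 = f"a{k}", f"u{k}x", f"u{k}y"
        vertices += [a, u1, u2]
        edges += [(a, u1), (a, u2)]
        r = rng.random()
        if r < s2:  # both leaves share the anchor's value
            val = "T" if rng.random() < t2 else off_value()
            labels[a] = labels[u1] = labels[u2] = (val,)
        elif r < s2 + s1:  # one sharing leaf, one fresh leaf
            val = "T" if rng.random() < t1 else off_value()
            labels[a] = labels[u1] = (val,)
            if val == "T":
                labels[u2] = (off_value(),)
            else:
                labels[u2] = ("T",) if rng.random() < h else (off_value(),)
        else:  # no sharing: anchor and leaves all distinct values
            if rng.random() < t0:
                labels[a] = ("T",)
                labels[u1] = (off_value(),)
                labels[u2] = (off_value(),)
            else:
                labels[a] = (off_value(),)
                labels[u1] = ("T",) if rng.random() < h0 else (off_value(),)
                labels[u2] = ("T",) if rng.random() < h0 else (off_value(),)

    values = tuple({vec[0] for vec in labels.values()})
    dim = LabelDimension("specialty", values, origin="attribute")
    graph = PropertyGraph(vertices, edges, labels, LabelSchema((dim,)))
    return graph, math.exp(slope)
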