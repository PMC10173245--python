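import pytest

from grandpa.core import LabelDimension, LabelSchema, PropertyGraph
from grandpa.fixtures import (
    SyntheticHealthcareSpec,
    labeled_karate,
    load_karate,
    synthetic_healthcare_graph,
)


def graph_from(edges, labels, origins=None):
    """Small-graph helper: labels is a map vertex -> tuple of values."""
    n_dims = len(next(iter(labels.values())))
    origins = origins or ["attribute"] * n_dims
    dims = []
    for k in range(n_dims):
        values = tuple({vec[k] for vec in labels.values()})
        dims.append(LabelDimension(f"d{k}", values, origins[k]))
    return PropertyGraph(labels.keys(), edges, labels, LabelSchema(tuple(dims)))


@pytest.fixture(scope="session")
def karate():
    return load_karate()


@pytest.fixture(scope="session")
def karate_labeled():
    return labeled_karate(seed=1)


@pytest.fixture(scope="session")
def healthcare():
    return synthetic_healthcare_graph(SyntheticHealthcareSpec(seed=0))


@pytest.fixture
def triangle_ab():
    """Triangle with labels A, A, B."""
    return graph_from(
        [("x", "y"), ("y", "z"), ("x", "z")],
        {"x": ("A",), "y": ("A",), "z": ("B",)},
    )


@pytest.fixture
def two_triangles():
    edges = [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
    labels = {v: ("X",) for v in "abcdef"}
    return graph_from(edges, labels)
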