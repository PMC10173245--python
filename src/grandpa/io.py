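"""Reading and writing property graphs.

Two interchange formats:

- ``graphml``: lossless single file.  Label dimensions ride along as vertex
  attributes, and the full schema (names, value sets, origins) is stored in
  a JSON graph attribute so that round trips preserve unused label values.
- ``csv_pair``: an edge-list CSV (``source,target``) next to a node table
  CSV (``id`` plus one column per attribute).  Columns whose name contains
  the word "label" become schema dimensions — the convention claims-derived
  node tables tend to follow — unless an explicit column list is given.

Vertex ids and label values are always read and written as text; no numeric
coercion happens anywhere.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import LabelDimension, LabelSchema, PropertyGraph, canonical_edge

__all__ = ["read_graph", "write_graph", "read_csv_pair", "write_csv_pair"]

log = logging.getLogger(__name__)

_SCHEMA_ATTR = "label_schema_json"


def _schema_to_json(schema: LabelSchema) -> str:
    return json.dumps(
        [
            {"name": d.name, "values": list(d.values), "origin": d.origin}
            for d in schema.dimensions
        ]
    )


def _schema_from_json(payload: str) -> LabelSchema:
    dims = [
        LabelDimension(d["name"], tuple(d["values"]), d.get("origin", "attribute"))
        for d in json.loads(payload)
    ]
    return LabelSchema(tuple(dims))


def _collapse_edges(raw_edges: list[tuple[str, str]]) -> set[tuple[str, str]]:
    edges: set[tuple[str, str]] = set()
    dupes = 0
    for u, v in raw_edges:
        if u == v:
            raise ValueError(f"self-loop at {u}: directed/self edges are rejected")
        e = canonical_edge(u, v)
        if e in edges:
            dupes += 1
        edges.add(e)
    if dupes:
        log.info("collapsed %d duplicate undirected edges", dupes)
    return edges


def read_graph(path: str | Path, format: str = "graphml") -> PropertyGraph:
    """Read a PropertyGraph; ``format`` is "graphml" or "csv_pair".

    For ``csv_pair`` the path is a prefix: ``<prefix>_edges.csv`` and
    ``<prefix>_nodes.csv`` are read.
    """
    if format == "csv_pair":
        p = Path(path)
        return read_csv_pair(p.parent / f"{p.name}_edges.csv",
                             p.parent / f"{p.name}_nodes.csv")
    if format != "graphml":
        raise ValueError(f"unknown format {format!r}")
    g = nx.read_graphml(path)
    if g.is_directed():
        raise ValueError("directed graphs are not supported")
    vertices = sorted(str(v) for v in g.nodes)
    edges = _collapse_edges([(str(u), str(v)) for u, v in g.edges])
    if _SCHEMA_ATTR in g.graph:
        schema = _schema_from_json(g.graph[_SCHEMA_ATTR])
    else:
        cols = sorted(
            {k for _, data in g.nodes(data=True) for k in data if "label" in k.lower()}
        )
        dims = [
            LabelDimension(
                c, tuple({str(g.nodes[v].get(c, "")) for v in g.nodes}), "attribute"
            )
            for c in cols
        ]
        schema = LabelSchema(tuple(dims))
    labels = {
        str(v): tuple(str(g.nodes[v][d.name]) for d in schema.dimensions)
        for v in g.nodes
    }
    graph = PropertyGraph(vertices, edges, labels, schema)
    from .core import validate

    problems = validate(graph)
    if problems:
        raise ValueError(f"invalid graph in {path}: {problems[:5]}")
    return graph


def write_graph(graph: PropertyGraph, path: str | Path, format: str = "graphml") -> None:
    """Write a PropertyGraph with stable (sorted) ordering."""
    if format == "csv_pair":
        p = Path(path)
        write_csv_pair(graph, p.parent / f"{p.name}_edges.csv",
                       p.parent / f"{p.name}_nodes.csv")
        return
    if format != "graphml":
        raise ValueError(f"unknown format {format!r}")
    g = nx.Graph()
    g.graph[_SCHEMA_ATTR] = _schema_to_json(graph.schema)
    for v in sorted(graph.vertices):
        g.add_node(v, **dict(zip(graph.schema.names, graph.labels[v])))
    for u, v in sorted(graph.edges):
        g.add_edge(u, v)
    nx.write_graphml(g, path)


def read_csv_pair(
    edge_path: str | Path,
    node_path: str | Path,
    label_columns: list[str] | None = None,
) -> PropertyGraph:
    """Read the edge-list + node-table CSV pair.

    ``label_columns`` overrides the contains-"label" column convention.
    """
    edge_df = pd.read_csv(edge_path, dtype=str)
    node_df = pd.read_csv(node_path, dtype=str)
    if edge_df.empty and node_df.empty:
        raise ValueError(f"empty input: {edge_path} / {node_path}")
    for col in ("source", "target"):
        if col not in edge_df.columns:
            raise ValueError(f"malformed edge header in {edge_path}: need {col!r}")
    if "id" not in node_df.columns:
        raise ValueError(f"malformed node header in {node_path}: need 'id'")
    vertices = [str(v) for v in node_df["id"]]
    vset = set(vertices)
    raw = []
    for u, v in zip(edge_df["source"], edge_df["target"]):
        if u not in vset:
            raise ValueError(f"edge references unknown vertex {u!r}")
        if v not in vset:
            raise ValueError(f"edge references unknown vertex {v!r}")
        raw.append((str(u), str(v)))
    edges = _collapse_edges(raw)
    if label_columns is None:
        label_columns = [c for c in node_df.columns if c != "id" and "label" in c.lower()]
    dims = tuple(
        LabelDimension(_strip_label_suffix(c), tuple(set(node_df[c].astype(str))),
                       "attribute")
        for c in label_columns
    )
    labels = {
        str(row["id"]): tuple(str(row[c]) for c in label_columns)
        for _, row in node_df.iterrows()
    }
    return PropertyGraph(vertices, edges, labels, LabelSchema(dims))


def _strip_label_suffix(column: str) -> str:
    """Drop the ``__label`` marker the writer adds to non-conforming names."""
    return column[: -len("__label")] if column.endswith("__label") else column


def _label_column(name: str) -> str:
    """Column name for a dimension, guaranteed to contain the word "label"
    so that a re-read picks it up under the node-table convention."""
    return name if "label" in name.lower() else f"{name}__label"


def write_csv_pair(
    graph: PropertyGraph, edge_path: str | Path, node_path: str | Path
) -> None:
    edges = sorted(graph.edges)
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(edge_path, index=False)
    columns = [_label_column(n) for n in graph.schema.names]
    rows = [
        {"id": v, **dict(zip(columns, graph.labels[v]))}
        for v in sorted(graph.vertices)
    ]
    pd.DataFrame(rows, columns=["id", *columns]).to_csv(node_path, index=False)
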