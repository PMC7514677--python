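"""Chromosome proximity graph and force-directed embedding.

Each chromosome becomes a node; each anchored cis-vs-trans Hellinger
record becomes a directed edge k -> l weighted by the distance between
the cis density of k and the trans density of (k, l). Edge affinity is
the inverse distance (distances are floored at 1e-6 so affinities stay
finite). The embedding is a seeded weighted Fruchterman–Reingold
(spring) layout on the symmetrized affinities: chromosome pairs whose
cis and trans programs are similar are pulled together. The layout is a
visualization device, not an estimate of nuclear geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .distances import DistanceRecord
from .errors import ContractError

logger = logging.getLogger(__name__)

#: Floor on Hellinger edge weights so affinities stay finite.
EPSILON_WEIGHT = 1e-6


@dataclass
class ChromosomeGraph:
    """Directed chromosome graph weighted by Hellinger distances."""

    graph: nx.DiGraph
    condition: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class LayoutResult:
    """2-D node coordinates of a seeded force-directed embedding."""

    coordinates: dict[str, tuple[float, float]]
    seed: int
    n_iterations: int


def build_chromosome_graph(
    records: list[DistanceRecord], condition: str = ""
) -> ChromosomeGraph:
    """Directed graph from anchored Hellinger distance records.

    One edge per record (anchor -> other); zero distances are floored
    at ``EPSILON_WEIGHT``. Missing pairs simply leave the graph sparse;
    duplicate records for the same directed pair are a contract error.
    """
    if not records:
        raise ContractError("no distance records to build a graph from")
    g = nx.DiGraph()
    for r in records:
        (k, _), _ = r.program_a
        (_, l), _ = r.program_b
        if k == l:
            raise ContractError(f"self-edge record for chromosome {k}")
        if g.has_edge(k, l):
            raise ContractError(f"duplicate record for directed pair ({k}, {l})")
        weight = max(float(r.value), EPSILON_WEIGHT)
        g.add_edge(k, l, weight=weight, affinity=1.0 / weight)
    return ChromosomeGraph(graph=g, condition=condition)


def force_directed_layout(
    g: ChromosomeGraph, seed: int = 0, n_iterations: int = 500
) -> LayoutResult:
    """Seeded weighted spring (Fruchterman–Reingold) layout.

    Directed edge pairs are symmetrized by averaging their affinities;
    affinities act as spring strengths, so high-affinity (small
    Hellinger distance) pairs land close together. Coordinates are
    centered at the origin and deterministic given (graph, seed).
    """
    if g.graph.number_of_nodes() < 2:
        raise ContractError("layout requires at least 2 nodes")
    sym = nx.Graph()
    sym.add_nodes_from(g.graph.nodes)
    for k, l, data in g.graph.edges(data=True):
        if sym.has_edge(k, l):
            sym[k][l]["affinity"] = (sym[k][l]["affinity"] + data["affinity"]) / 2.0
        else:
            sym.add_edge(k, l, affinity=data["affinity"])
    pos = nx.spring_layout(
        sym, weight="affinity", iterations=n_iterations, seed=seed
    )
    coords = np.array([pos[n] for n in sym.nodes])
    coords = coords - coords.mean(axis=0)
    coordinates = {
        n: (float(x), float(y)) for n, (x, y) in zip(sym.nodes, coords)
    }
    return LayoutResult(coordinates=coordinates, seed=seed, n_iterations=n_iterations)


def export_graph(
    g: ChromosomeGraph,
    layout: LayoutResult | None,
    path: str | Path,
    format: str = "graphml",
) -> None:
    """Write the graph as GraphML (with x/y attributes) or edge-list TSV."""
    path = Path(path)
    if layout is not None and set(layout.coordinates) != set(g.graph.nodes):
        raise ContractError("layout nodes do not match graph nodes")
    if format == "graphml":
        out = g.graph.copy()
        if layout is not None:
            for node, (x, y) in layout.coordinates.items():
                out.nodes[node]["x"] = x
                out.nodes[node]["y"] = y
        nx.write_graphml(out, path)
    elif format == "tsv":
        rows = [
            {"source": k, "target": l, "weight": d["weight"], "affinity": d["affinity"]}
            for k, l, d in g.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ContractError(f"unknown export format: {format!r}")


def read_graphml(path: str | Path) -> tuple[ChromosomeGraph, LayoutResult | None]:
    """Read a GraphML file written by :func:`export_graph`."""
    g = nx.read_graphml(Path(path))
    directed = nx.DiGraph()
    for n, data in g.nodes(data=True):
        directed.add_node(n)
    for k, l, data in g.edges(data=True):
        directed.add_edge(k, l, weight=data["weight"], affinity=data["affinity"])
    layout = None
    if all("x" in g.nodes[n] for n in g.nodes):
        layout = LayoutResult(
            coordinates={n: (g.nodes[n]["x"], g.nodes[n]["y"]) for n in g.nodes},
            seed=-1,
            n_iterations=-1,
        )
    return ChromosomeGraph(graph=directed), layout
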