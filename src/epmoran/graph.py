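"""Population graphs: Barabási–Albert generation and plain-text edge lists.

Individuals live on the nodes of an undirected, connected graph; edges define
who can reproduce into whom under the death–birth rule and who can inherit an
abandoned extended phenotype.  Graphs are grown by preferential attachment
(scale-free degree distribution), which mimics the clustered contact structure
of many natural populations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Union

import networkx as nx
import numpy as np


class EdgeListError(ValueError):
    """Raised for malformed edge-list input or an unwritable graph."""


@dataclass
class PopulationGraph:
    """An undirected population graph with 0-based contiguous node ids.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`.  Nodes must be the integers
        ``0 .. N-1``; no self-loops, no parallel edges, connected.
    m
        The preferential-attachment parameter used to grow the graph, kept as
        metadata (``None`` for hand-built graphs such as paths or triangles).
    """

    graph: nx.Graph
    m: Union[int, None] = None
    _csr: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = self.graph
        n = g.number_of_nodes()
        if n == 0:
            raise EdgeListError("population graph must have at least one node")
        if set(g.nodes) != set(range(n)):
            raise EdgeListError("node ids must be the contiguous integers 0..N-1")
        if any(u == v for u, v in g.edges):
            raise EdgeListError("self-loops are not allowed")
        if n > 1 and not nx.is_connected(g):
            raise EdgeListError("population graph must be connected")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> set:
        """Edge set in canonical (u < v) order."""
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    def csr(self) -> tuple:
        """Adjacency in CSR form ``(indptr, indices)`` for the simulation kernels."""
        if self._csr is None:
            a = nx.to_scipy_sparse_array(self.graph, nodelist=range(self.n), format="csr")
            object.__setattr__(
                self,
                "_csr",
                (a.indptr.astype(np.int64), a.indices.astype(np.int64)),
            )
        return self._csr

    def degrees(self) -> np.ndarray:
        indptr, _ = self.csr()
        return np.diff(indptr)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PopulationGraph):
            return NotImplemented
        return self.n == other.n and self.m == other.m and self.edges == other.edges


def generate_ba_graph(n: int, m: int, seed: int) -> PopulationGraph:
    """Grow a Barabási–Albert graph of ``n`` nodes with attachment parameter ``m``.

    Growth starts from a star on ``m + 1`` nodes; each subsequently added node
    attaches to ``m`` distinct existing nodes with probability proportional to
    their current degree.  The edge count is therefore exactly ``m * (n - m)``.

    Raises
    ------
    ValueError
        If ``m < 1`` or ``n <= m``.
    """
    if m < 1:
        raise ValueError(f"attachment parameter m must be >= 1, got {m}")
    if n <= m:
        raise ValueError(f"need n > m to grow the graph, got n={n}, m={m}")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    return PopulationGraph(g, m=m)


def write_edge_list(graph: PopulationGraph, destination: Union[str, IO[str]]) -> None:
    """Write ``graph`` as a plain-text edge list.

    Format: '#'-prefixed header lines carrying ``n`` and ``m`` metadata, then
    one edge per line as ``"u v"`` with ``u < v``, ASCII decimal, sorted.
    """
    if graph.n == 0:
        raise EdgeListError("refusing to write an empty graph")
    lines = [f"# epmoran edge list", f"# n={graph.n}"]
    if graph.m is not None:
        lines.append(f"# m={graph.m}")
    for u, v in sorted(graph.edges):
        lines.append(f"{u} {v}")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str,)):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)


def read_edge_list(source: Union[str, IO[str]]) -> PopulationGraph:
    """Read an edge list written by :func:`write_edge_list` (or compatible).

    Raises :class:`EdgeListError` naming the offending line for self-loops,
    duplicate edges or unparsable lines.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_edge_list(fh)
    n_meta = None
    m_meta = None
    edges = set()
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("n="):
                n_meta = int(body[2:])
            elif body.startswith("m="):
                m_meta = int(body[2:])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise EdgeListError(f"line {lineno}: expected 'u v', got {line!r}")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise EdgeListError(f"line {lineno}: non-integer node id in {line!r}") from None
        if u == v:
            raise EdgeListError(f"line {lineno}: self-loop {u}-{v}")
        e = (min(u, v), max(u, v))
        if e in edges:
            raise EdgeListError(f"line {lineno}: duplicate edge {u}-{v}")
        if u < 0 or v < 0:
            raise EdgeListError(f"line {lineno}: negative node id in {line!r}")
        edges.add(e)
    if not edges:
        raise EdgeListError("edge list contains no edges")
    g = nx.Graph()
    n = n_meta if n_meta is not None else max(max(e) for e in edges) + 1
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return PopulationGraph(g, m=m_meta)
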