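"""Gene-regulatory network model.

A :class:`Network` is an undirected, optionally weighted graph whose nodes
are gene/miRNA symbols.  The same network is reused against several omics
levels; an optional ``level_map`` resolves a node to its measured feature
identifier on each level (by default the node symbol itself is the feature
id on every level).

Matrix representations follow the usual spectral conventions: adjacency A,
degree D, symmetrically normalized adjacency S = D^{-1/2} A D^{-1/2} and
normalized Laplacian L = I - S.  Isolated nodes get D^{-1/2} entries of 0
(not inf), so S rows/columns of isolated nodes are identically zero and the
random-walk kernel stays well defined on arbitrary subnetworks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "NetworkMatrices",
    "read_edge_list",
    "read_level_map",
    "build_matrices",
    "random_network_null",
    "filter_low_variance",
    "load_synthetic_core_network",
]


class EdgeListParseError(ValueError):
    """Malformed edge-list line; carries the 1-based line number."""


@dataclass
class Network:
    """Undirected weighted network over named nodes.

    Parameters
    ----------
    graph:
        ``networkx.Graph`` with nodes in first-appearance order; every edge
        carries a positive ``weight`` attribute (default 1.0).
    level_map:
        Optional mapping ``node -> {level: feature_id}``.  Nodes absent from
        the mapping (or the mapping itself being ``None``) resolve to their
        own symbol on every level.
    n_selfloop_warnings:
        Count of self-loop edges dropped while reading (bookkeeping only).
    """

    graph: nx.Graph
    level_map: dict[str, dict[str, str]] | None = None
    n_selfloop_warnings: int = 0

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            if not w > 0:
                raise ValueError(f"edge ({u},{v}) has non-positive weight {w}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def feature_for(self, node: str, level: str) -> str | None:
        """Feature id measuring ``node`` on ``level`` (None if unmeasured)."""
        if self.level_map is None or node not in self.level_map:
            return node
        return self.level_map[node].get(level)

    def features_for_level(self, level: str) -> dict[str, str]:
        """Mapping node -> feature id for all nodes measured on ``level``."""
        out = {}
        for node in self.graph.nodes:
            feat = self.feature_for(node, level)
            if feat is not None:
                out[node] = feat
        return out

    def subgraph(self, keep: Iterable[str]) -> "Network":
        """Induced subgraph on ``keep`` (node order preserved)."""
        keep = set(keep)
        g = nx.Graph()
        g.add_nodes_from(n for n in self.graph.nodes if n in keep)
        g.add_weighted_edges_from(
            (u, v, w)
            for u, v, w in self.graph.edges(data="weight", default=1.0)
            if u in keep and v in keep
        )
        lm = None
        if self.level_map is not None:
            lm = {n: dict(m) for n, m in self.level_map.items() if n in keep}
        return Network(g, lm)

    def relabel(self, mapping: Mapping[str, str]) -> "Network":
        """Edge-isomorphic copy with node labels replaced via ``mapping``."""
        g = nx.Graph()
        g.add_nodes_from(mapping[n] for n in self.graph.nodes)
        g.add_weighted_edges_from(
            (mapping[u], mapping[v], w)
            for u, v, w in self.graph.edges(data="weight", default=1.0)
        )
        return Network(g, None)


@dataclass
class NetworkMatrices:
    """Dense matrix views of a network in a fixed node order."""

    nodes: list[str]
    adjacency: np.ndarray
    degree: np.ndarray
    normalized_adjacency: np.ndarray
    normalized_laplacian: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}


def read_edge_list(path: str | Path, weighted: bool = False) -> Network:
    """Parse a 2-3 column whitespace-separated edge list.

    Lines starting with '#' (and blank lines) are skipped.  Duplicate
    undirected edges are collapsed (first weight wins); self-loops are
    dropped and counted in ``Network.n_selfloop_warnings``.
    """
    g = nx.Graph()
    n_selfloops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            if weighted and len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if w <= 0:
                raise EdgeListParseError(f"{path}:{lineno}: non-positive weight {w}")
            if u == v:
                n_selfloops += 1
                warnings.warn(f"{path}:{lineno}: self-loop {u!r} dropped")
                continue
            g.add_node(u)
            g.add_node(v)
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=w)
    return Network(g, n_selfloop_warnings=n_selfloops)


def read_level_map(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a node->feature mapping: TSV columns node_id, level, feature_id."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 columns (node, level, feature)"
                )
            node, level, feat = parts
            out.setdefault(node, {})[level] = feat
    return out


def build_matrices(net: Network) -> NetworkMatrices:
    """Adjacency, degree, D^{-1/2} A D^{-1/2} and normalized Laplacian."""
    nodes = net.nodes
    a = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    s = dinv_sqrt[:, None] * a * dinv_sqrt[None, :]
    lap = np.eye(len(nodes)) - s
    return NetworkMatrices(
        nodes=nodes,
        adjacency=a,
        degree=deg,
        normalized_adjacency=s,
        normalized_laplacian=lap,
    )


def random_network_null(
    reference: Network, feature_pool: Sequence[str], seed: int
) -> Network:
    """Edge-isomorphic null network with node labels resampled from a pool.

    The returned network has exactly the reference's edge structure; labels
    are drawn uniformly without replacement from ``feature_pool``, so its
    degree sequence is identical while its biological content is destroyed.
    """
    n = reference.n_nodes
    pool = list(feature_pool)
    if len(pool) < n:
        raise ValueError(
            f"feature pool has {len(pool)} entries but the reference network "
            f"has {n} nodes"
        )
    rng = np.random.default_rng(seed)
    labels = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    mapping = dict(zip(reference.nodes, labels))
    return reference.relabel(mapping)


def filter_low_variance(net: Network, data, min_variance: float) -> Network:
    """Drop nodes whose best per-level feature variance falls below a floor.

    For every node the variance of its feature column is computed on each
    omics level where it is measured; the node survives if the maximum of
    those variances is >= ``min_variance``.  Returns the induced subgraph on
    survivors.
    """
    keep = []
    for node in net.nodes:
        best = None
        for level, frame in data.levels.items():
            feat = net.feature_for(node, level)
            if feat is not None and feat in frame.columns:
                v = float(frame[feat].var(ddof=1))
                best = v if best is None else max(best, v)
        if best is None:
            raise ValueError(f"node {node!r} resolves to no measured feature")
        if best >= min_variance:
            keep.append(node)
    if not keep:
        raise ValueError(
            "variance filter removed every node; lower min_variance"
        )
    return net.subgraph(keep)


def load_synthetic_core_network() -> Network:
    """Bundled 74-node synthetic scale-free fixture network.

    A stand-in, generated by :func:`prnfs.simulate.generate_grn`, mirroring
    the size of a literature-curated core EMT regulatory network; it carries
    no biological meaning.
    """
    path = Path(__file__).parent / "data" / "synthetic_core_grn_74.edges"
    return read_edge_list(path)
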