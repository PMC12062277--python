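"""Prior-knowledge graphs for omics modalities.

A :class:`ModalityGraphSpec` couples a simple undirected topology with the
ordered feature symbols it covers (typically one graph per modality per
functional gene-set / biodomain).  Includes shortest-path subnetwork
reconstruction from a background protein-protein-interaction graph: the
union, over all seed pairs, of every node and edge lying on at least one
shortest path between the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ModalityGraphSpec", "shortest_path_subnetwork", "restrict_to_measured",
    "load_graph", "save_graph", "EmptyGraphError",
]


class EmptyGraphError(ValueError):
    pass


@dataclass
class ModalityGraphSpec:
    """A prior topology plus the ordered feature identifiers it covers.

    ``edges`` hold node *indices* into ``feature_ids``; each unordered pair is
    stored once, lower index first, with no self-loops.
    """

    name: str
    feature_ids: list[str]
    edges: list[tuple[int, int]]
    edge_weights: list[float] | None = None
    _norm_adj: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.feature_ids)
        if len(set(self.feature_ids)) != n:
            raise ValueError("feature_ids must be unique")
        canon = []
        seen = set()
        weights = self.edge_weights
        new_w = [] if weights is not None else None
        for k, (u, v) in enumerate(self.edges):
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) references an invalid node index")
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            canon.append(key)
            if new_w is not None:
                new_w.append(float(weights[k]))
        self.edges = canon
        self.edge_weights = new_w
        if self.edge_weights is not None and len(self.edge_weights) != len(self.edges):
            raise ValueError("edge_weights length must match edges")

    @property
    def n_nodes(self) -> int:
        return len(self.feature_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        w = self.edge_weights or [1.0] * len(self.edges)
        for (u, v), wt in zip(self.edges, w):
            if wt < 0:
                raise ValueError("negative edge weight: normalization undefined")
            A[u, v] = wt
            A[v, u] = wt
        return A

    def normalized_adjacency(self) -> np.ndarray:
        """Symmetric-normalized adjacency with unit self-loops, D^-1/2 (A+I) D^-1/2."""
        if self._norm_adj is None:
            A = self.adjacency() + np.eye(self.n_nodes)
            d = A.sum(axis=1)
            dinv = 1.0 / np.sqrt(d)
            self._norm_adj = A * dinv[:, None] * dinv[None, :]
        return self._norm_adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.feature_ids)
        w = self.edge_weights or [1.0] * len(self.edges)
        for (u, v), wt in zip(self.edges, w):
            g.add_edge(self.feature_ids[u], self.feature_ids[v], weight=wt)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "graph",
                      node_order: list[str] | None = None) -> "ModalityGraphSpec":
        order = [str(n) for n in (node_order if node_order is not None else g.nodes())]
        idx = {n: i for i, n in enumerate(order)}
        edges, weights = [], []
        has_w = False
        for u, v, data in g.edges(data=True):
            u, v = str(u), str(v)
            if u == v:
                continue
            edges.append((idx[u], idx[v]))
            wt = data.get("weight", 1.0)
            has_w = has_w or ("weight" in data)
            weights.append(float(wt))
        return cls(name=name, feature_ids=order, edges=edges,
                   edge_weights=weights if has_w else None)


def shortest_path_subnetwork(background: nx.Graph, seeds) -> nx.Graph:
    """Union of all shortest paths between every seed pair (unweighted hops).

    Seed pairs in different connected components are skipped with a warning;
    isolated seeds are retained as singleton nodes.  A node v lies on a
    shortest s-t path iff d(s,v) + d(v,t) = d(s,t); an edge (u,v) lies on one
    iff d(s,u) + 1 + d(v,t) = d(s,t) in one of its orientations.
    """
    seeds = [s for s in seeds]
    if not seeds:
        raise ValueError("empty seed set")
    present = [s for s in seeds if background.has_node(s)]
    missing = sorted(set(seeds) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} seed(s) not in background graph: {missing[:5]}")
    dist = {s: nx.single_source_shortest_path_length(background, s) for s in present}
    sub = nx.Graph()
    sub.add_nodes_from(present)
    skipped = 0
    for i, s in enumerate(present):
        for t in present[i + 1:]:
            if t not in dist[s]:
                skipped += 1
                continue
            dst = dist[s][t]
            on_path = {v for v, dv in dist[s].items()
                       if v in dist[t] and dv + dist[t][v] == dst}
            sub.add_nodes_from(on_path)
            for u in on_path:
                du = dist[s][u]
                for v in background.neighbors(u):
                    if v in on_path and dist[s][v] == du + 1 \
                            and du + 1 + dist[t][v] == dst:
                        sub.add_edge(u, v)
    if skipped:
        warnings.warn(f"skipped {skipped} seed pair(s) in different components")
    return sub


def restrict_to_measured(spec: ModalityGraphSpec, measured) -> ModalityGraphSpec:
    """Induced subgraph on the measured symbols, preserving relative node order."""
    measured = set(measured)
    keep = [i for i, f in enumerate(spec.feature_ids) if f in measured]
    if not keep:
        raise EmptyGraphError(
            f"no overlap between graph '{spec.name}' nodes and measured features")
    remap = {old: new for new, old in enumerate(keep)}
    edges, weights = [], []
    w = spec.edge_weights or [1.0] * len(spec.edges)
    for (u, v), wt in zip(spec.edges, w):
        if u in remap and v in remap:
            edges.append((remap[u], remap[v]))
            weights.append(wt)
    return ModalityGraphSpec(
        name=spec.name,
        feature_ids=[spec.feature_ids[i] for i in keep],
        edges=edges,
        edge_weights=weights if spec.edge_weights is not None else None,
    )


class GraphFormatError(ValueError):
    pass


def _read_node_order(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_graph(path, fmt: str, name: str | None = None,
               node_order_path=None) -> ModalityGraphSpec:
    """Load an undirected simple graph from edge-list TSV, SIF, or GraphML.

    Node order is first-appearance order unless a node-order sidecar file
    (one symbol per line) is given.
    """
    path = str(path)
    name = name or path
    order: list[str] = []
    seen: set[str] = set()

    def note(node):
        if node not in seen:
            seen.add(node)
            order.append(node)

    pairs: dict[tuple[str, str], float | None] = {}

    def add_edge(u, v, w=None, lineno=None):
        if u == v:
            return
        key = (u, v) if u <= v else (v, u)
        if key in pairs:
            old = pairs[key]
            if old is not None and w is not None and old != w:
                raise GraphFormatError(
                    f"{path}:{lineno}: conflicting weights for edge {key}: {old} vs {w}")
            if w is not None:
                pairs[key] = w
        else:
            pairs[key] = w
        note(u)
        note(v)

    if fmt == "edge_list_tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split("\t")
                parts = [p.strip() for p in parts if p.strip()]
                if len(parts) < 2 or len(parts) > 3:
                    raise GraphFormatError(f"{path}:{lineno}: expected 2-3 columns")
                w = None
                if len(parts) == 3:
                    try:
                        w = float(parts[2])
                    except ValueError as e:
                        raise GraphFormatError(
                            f"{path}:{lineno}: bad weight {parts[2]!r}") from e
                add_edge(parts[0], parts[1], w, lineno)
    elif fmt == "sif":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) == 1:
                    note(parts[0])  # isolated node
                    continue
                if len(parts) < 3:
                    raise GraphFormatError(
                        f"{path}:{lineno}: SIF line needs source, relation, target(s)")
                src = parts[0]
                for tgt in parts[2:]:
                    add_edge(src, tgt, None, lineno)
    elif fmt == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as e:
            raise GraphFormatError(f"{path}: GraphML parse failure: {e}") from e
        for n in g.nodes():
            note(str(n))
        for u, v, data in g.edges(data=True):
            add_edge(str(u), str(v), data.get("weight"))
    else:
        raise GraphFormatError(f"unknown graph format: {fmt!r}")

    if node_order_path is not None:
        sidecar = _read_node_order(node_order_path)
        if set(order) - set(sidecar):
            raise GraphFormatError("node-order sidecar is missing graph nodes")
        order = sidecar

    idx = {n: i for i, n in enumerate(order)}
    edges = [(idx[u], idx[v]) for (u, v) in pairs]
    has_w = any(w is not None for w in pairs.values())
    weights = [1.0 if w is None else w for w in pairs.values()] if has_w else None
    return ModalityGraphSpec(name=name, feature_ids=order, edges=edges,
                             edge_weights=weights)


def save_graph(spec: ModalityGraphSpec, path, fmt: str = "edge_list_tsv",
               node_order_path=None):
    path = str(path)
    if fmt == "edge_list_tsv":
        w = spec.edge_weights
        with open(path, "w") as fh:
            for k, (u, v) in enumerate(spec.edges):
                row = [spec.feature_ids[u], spec.feature_ids[v]]
                if w is not None:
                    row.append(repr(w[k]))
                fh.write("\t".join(row) + "\n")
    elif fmt == "graphml":
        nx.write_graphml(spec.to_networkx(), path)
    else:
        raise GraphFormatError(f"unsupported save format: {fmt!r}")
    if node_order_path is not None:
        with open(node_order_path, "w") as fh:
            fh.write("\n".join(spec.feature_ids) + "\n")
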