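"""DI-weighted Chow-Liu tree construction, response ranking, and export.

The Chow-Liu procedure selects the spanning tree over the cohort variables
that maximizes summed pairwise dependence.  Classically the weights are
mutual information; here they are direct information, which discounts
indirect (transitive) correlation.  Edges stay undirected — no orientation
or conditional-probability-table estimation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dca import DIMatrix

__all__ = [
    "ChowLiuTree",
    "ResponseRanking",
    "chow_liu_tree",
    "rank_response_couplings",
    "export_network",
    "read_edge_list",
]


@dataclass
class ChowLiuTree:
    """Undirected maximum-weight spanning tree over the cohort variables."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (a, b, weight), a < b lexicographically
    total_weight: float
    node_kinds: dict[str, str] | None = None

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, kind=(self.node_kinds or {}).get(n, ""))
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def chow_liu_tree(
    di: DIMatrix, node_kinds: dict[str, str] | None = None
) -> ChowLiuTree:
    """Maximum-weight spanning tree of the complete DI graph (Kruskal).

    Ties are broken deterministically: candidate edges are processed in
    (-weight, name_a, name_b) order with names sorted lexicographically
    within each pair.
    """
    names = di.names
    L = len(names)
    if L < 2:
        raise ValueError("a tree needs at least two variables")
    if not np.all(np.isfinite(di.values)):
        raise ValueError("DI matrix contains non-finite weights")
    candidates = []
    for i in range(L):
        for j in range(i + 1, L):
            a, b = sorted((names[i], names[j]))
            candidates.append((a, b, float(di.values[i, j])))
    candidates.sort(key=lambda e: (-e[2], e[0], e[1]))
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, float]] = []
    for a, b, w in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, w))
            if len(edges) == L - 1:
                break
    edges.sort(key=lambda e: (e[0], e[1]))
    return ChowLiuTree(
        nodes=list(names), edges=edges,
        total_weight=float(sum(w for _, _, w in edges)),
        node_kinds=node_kinds,
    )


@dataclass
class ResponseRanking:
    """Each factor's DI with the response, ranked within all pairwise DI.

    Rank 1 is the strongest pair in the whole pool of L(L-1)/2 values;
    smaller rank means stronger direct connectivity to the response.
    """

    table: pd.DataFrame  # columns: factor, di, rank
    pool_size: int


def rank_response_couplings(di: DIMatrix, response: str) -> ResponseRanking:
    """Rank every factor-response DI within the full pairwise pool.

    Ties are broken deterministically by the lexicographic name pair, so
    ranks are unique.  The ranking is invariant under any monotone rescaling
    of the DI values.
    """
    if response not in di.names:
        raise KeyError(f"unknown response variable {response!r}")
    names = di.names
    L = len(names)
    pool = []
    for i in range(L):
        for j in range(i + 1, L):
            a, b = sorted((names[i], names[j]))
            pool.append(((a, b), float(di.values[i, j])))
    pool.sort(key=lambda t: (-t[1], t[0]))
    rank_of = {pair: r + 1 for r, (pair, _) in enumerate(pool)}
    rows = []
    for f in names:
        if f == response:
            continue
        pair = tuple(sorted((f, response)))
        rows.append({"factor": f, "di": di.di(f, response), "rank": rank_of[pair]})
    rows.sort(key=lambda r: r["rank"])
    return ResponseRanking(table=pd.DataFrame(rows), pool_size=len(pool))


# -- serialization ---------------------------------------------------------

_FORMATS = ("tsv", "graphml", "dot")


def export_network(tree: ChowLiuTree, path, fmt: str = "tsv") -> None:
    """Write the tree as an edge-list TSV, GraphML, or DOT file.

    Nodes carry a ``kind`` annotation (drug vs clinical vs polymorphism ...)
    when the tree was built with ``node_kinds``.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; choose from {_FORMATS}")
    if fmt == "tsv":
        pd.DataFrame(tree.edges, columns=["var_a", "var_b", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "graphml":
        nx.write_graphml(tree.to_graph(), path)
    else:  # dot
        kinds = tree.node_kinds or {}
        lines = ["graph chow_liu {"]
        for n in tree.nodes:
            shape = "hexagon" if kinds.get(n) == "drug" else "ellipse"
            lines.append(f'  "{n}" [shape={shape}, kind="{kinds.get(n, "")}"];')
        for a, b, w in tree.edges:
            lines.append(f'  "{a}" -- "{b}" [weight={w:.6g}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def read_edge_list(path) -> ChowLiuTree:
    """Read back an edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    edges = [
        (str(r.var_a), str(r.var_b), float(r.weight)) for r in df.itertuples()
    ]
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    return ChowLiuTree(
        nodes=nodes, edges=edges,
        total_weight=float(sum(w for _, _, w in edges)),
    )
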