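"""Bipartite network construction, degree topology and graph export.

Compound-target (C-T), target-disease (T-D) and target-pathway (T-P)
networks are all typed bipartite graphs; degree (number of incident edges) is
the sole topological statistic, matching NetworkAnalyzer-style reporting.
Graphs are held as :class:`networkx.Graph` with node ``kind`` attributes;
node identity is the (kind, id) pair so that, e.g., a UniProt accession used
in two different networks is only the same logical node after an explicit
join.

The hub rule is parameterized (threshold plus strict/inclusive comparison)
and the resulting report always names the rule that was applied, because
"degree > 10" and "degree >= 10" select different hub sets on realistic
degree distributions with ties at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import NetworkBuildError

__all__ = [
    "BipartiteNetwork",
    "DegreeReport",
    "MergedNetwork",
    "build_network",
    "degree_report",
    "merge_module_network",
    "export_graph",
    "read_graphml",
]

EXPORT_FORMATS = ("sif", "graphml", "tsv")

#: SIF interaction labels by (left_kind, right_kind).
INTERACTION_LABELS = {
    ("compound", "target"): "ct",
    ("target", "disease"): "td",
    ("target", "pathway"): "tp",
    ("target", "function_module"): "tm",
}


def _node_key(kind: str, ident: str) -> str:
    return f"{kind}:{ident}"


@dataclass
class BipartiteNetwork:
    """A typed two-sided network with set-semantics edges.

    ``left``/``right`` are the node id sets of each side; ``edges`` holds
    (left_id, right_id) pairs with duplicates collapsed at construction
    (``n_duplicates`` counts how many were dropped).
    """

    left_kind: str
    right_kind: str
    left: tuple[str, ...]
    right: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    n_duplicates: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, side: str) -> dict[str, int]:
        """Degree of every node on ``side`` ("left" or "right"), zeros included."""
        nodes = self.left if side == "left" else self.right
        idx = 0 if side == "left" else 1
        deg = {n: 0 for n in nodes}
        for e in self.edges:
            deg[e[idx]] += 1
        return deg

    def check_handshake(self) -> None:
        ld, rd = self.degree("left"), self.degree("right")
        if not (sum(ld.values()) == sum(rd.values()) == self.n_edges):
            raise NetworkBuildError("handshake identity violated")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.left:
            g.add_node(_node_key(self.left_kind, n), kind=self.left_kind, label=n)
        for n in self.right:
            g.add_node(_node_key(self.right_kind, n), kind=self.right_kind, label=n)
        for a, b in self.edges:
            g.add_edge(_node_key(self.left_kind, a),
                       _node_key(self.right_kind, b),
                       interaction=INTERACTION_LABELS.get(
                           (self.left_kind, self.right_kind), "pp"))
        return g


def build_network(edges: Iterable[tuple[str, str]],
                  left_kind: str, right_kind: str,
                  left_nodes: Sequence[str] | None = None,
                  right_nodes: Sequence[str] | None = None) -> BipartiteNetwork:
    """Assemble a typed bipartite network from an edge list.

    Node sets are inferred from the edges unless declared explicitly;
    declared nodes that carry no edge are retained as isolates.  Duplicate
    edges are collapsed (set semantics) and counted.  The two sides must be
    of different kinds — a same-kind edge is a modelling error, not a warning.
    """
    if left_kind == right_kind:
        raise NetworkBuildError(
            f"left and right kinds must differ, both are {left_kind!r}")
    left: list[str] = list(left_nodes) if left_nodes is not None else []
    right: list[str] = list(right_nodes) if right_nodes is not None else []
    lset, rset = set(left), set(right)
    seen: set[tuple[str, str]] = set()
    uniq: list[tuple[str, str]] = []
    dups = 0
    for a, b in edges:
        if left_nodes is not None and a not in lset:
            raise NetworkBuildError(f"edge endpoint {a!r} not in declared left nodes")
        if right_nodes is not None and b not in rset:
            raise NetworkBuildError(f"edge endpoint {b!r} not in declared right nodes")
        if (a, b) in seen:
            dups += 1
            continue
        seen.add((a, b))
        uniq.append((a, b))
        if a not in lset:
            lset.add(a)
            left.append(a)
        if b not in rset:
            rset.add(b)
            right.append(b)
    net = BipartiteNetwork(left_kind=left_kind, right_kind=right_kind,
                           left=tuple(left), right=tuple(right),
                           edges=tuple(uniq), n_duplicates=dups)
    net.check_handshake()
    return net


@dataclass(frozen=True)
class DegreeReport:
    """Degree topology of one bipartite network.

    ``hub_rule`` records whether hubs were selected with a strict (``>``)
    or inclusive (``>=``) comparison at ``hub_threshold``.  Mean degrees are
    exact (unrounded); use :meth:`mean_degree_2dp` for presentation.
    """

    left_degree: Mapping[str, int]
    right_degree: Mapping[str, int]
    hub_threshold: int
    hub_rule: str                      # "strict (>)" or "inclusive (>=)"
    left_hubs: tuple[str, ...]
    right_hubs: tuple[str, ...]

    def max_degree(self, side: str) -> tuple[str | None, int]:
        deg = self.left_degree if side == "left" else self.right_degree
        if not deg:
            return None, 0
        node = max(sorted(deg), key=lambda n: deg[n])
        return node, deg[node]

    def top(self, side: str, k: int) -> list[tuple[str, int]]:
        deg = self.left_degree if side == "left" else self.right_degree
        return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def mean_degree(self, side: str) -> float:
        deg = self.left_degree if side == "left" else self.right_degree
        return sum(deg.values()) / len(deg) if deg else 0.0

    def mean_degree_2dp(self, side: str) -> float:
        return round(self.mean_degree(side), 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [("left", n, d) for n, d in self.left_degree.items()]
        rows += [("right", n, d) for n, d in self.right_degree.items()]
        return pd.DataFrame(rows, columns=["side", "node", "degree"])


def degree_report(net: BipartiteNetwork, hub_threshold: int = 10,
                  strict: bool = True) -> DegreeReport:
    """Exact degrees, per-side maxima and hub lists under a stated rule."""
    ld, rd = net.degree("left"), net.degree("right")

    def hubs(deg: Mapping[str, int]) -> tuple[str, ...]:
        if strict:
            sel = [n for n, d in deg.items() if d > hub_threshold]
        else:
            sel = [n for n, d in deg.items() if d >= hub_threshold]
        return tuple(sorted(sel, key=lambda n: (-deg[n], n)))

    return DegreeReport(
        left_degree=ld, right_degree=rd,
        hub_threshold=hub_threshold,
        hub_rule="strict (>)" if strict else "inclusive (>=)",
        left_hubs=hubs(ld), right_hubs=hubs(rd))


@dataclass(frozen=True)
class MergedNetwork:
    """Union of a C-T network with target->function-module edges."""

    graph: nx.Graph
    node_counts: Mapping[str, int]      # kind -> count
    edge_counts: Mapping[str, int]      # interaction label -> count
    n_skipped: int                      # module edges to unknown targets

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def merge_module_network(ct_net: BipartiteNetwork,
                         target_to_module: pd.DataFrame) -> MergedNetwork:
    """Overlay function-module membership on a compound-target network.

    ``target_to_module`` is an annotation frame with ``subject_id`` (target)
    and ``term_id`` (module) columns; a target may belong to several modules.
    Module edges referencing targets absent from the C-T network are skipped
    and counted, not fatal: annotation universes routinely outrun any one
    network's target set.
    """
    if ct_net.right_kind != "target":
        raise NetworkBuildError("merge requires a compound-target network")
    g = ct_net.to_networkx()
    known = set(ct_net.right)
    skipped = 0
    seen: set[tuple[str, str]] = set()
    n_modules: set[str] = set()
    module_edges = 0
    for row in target_to_module.itertuples(index=False):
        tgt, module = str(row.subject_id), str(row.term_id)
        if tgt not in known:
            skipped += 1
            continue
        if (tgt, module) in seen:
            continue
        seen.add((tgt, module))
        mkey = _node_key("function_module", module)
        if mkey not in g:
            g.add_node(mkey, kind="function_module", label=module)
            n_modules.add(module)
        g.add_edge(_node_key("target", tgt), mkey, interaction="tm")
        module_edges += 1
    node_counts = {"compound": len(ct_net.left), "target": len(ct_net.right),
                   "function_module": len(n_modules)}
    edge_counts = {"ct": ct_net.n_edges, "tm": module_edges}
    merged = MergedNetwork(graph=g, node_counts=node_counts,
                           edge_counts=edge_counts, n_skipped=skipped)
    assert merged.n_edges == sum(edge_counts.values())
    return merged


def export_graph(net: BipartiteNetwork | MergedNetwork, path: str | Path,
                 format: str = "sif") -> None:
    """Export a network as SIF, GraphML or a two-column TSV edge list.

    SIF rows carry the interaction label of the edge (ct/td/tp/tm); GraphML
    carries node ``kind`` attributes and round-trips node and edge counts.
    """
    if format not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported: {', '.join(EXPORT_FORMATS)}")
    path = Path(path)
    g = net.to_networkx() if isinstance(net, BipartiteNetwork) else net.graph
    if format == "graphml":
        nx.write_graphml(g, path)
        return
    with path.open("w", encoding="utf-8", newline="") as fh:
        if format == "tsv":
            fh.write("source\ttarget\n")
        for a, b, data in g.edges(data=True):
            la, lb = g.nodes[a]["label"], g.nodes[b]["label"]
            if format == "sif":
                fh.write(f"{la}\t{data.get('interaction', 'pp')}\t{lb}\n")
            else:
                fh.write(f"{la}\t{lb}\n")


def read_graphml(path: str | Path) -> nx.Graph:
    """Re-import a GraphML export (node ``kind`` attributes preserved)."""
    return nx.read_graphml(Path(path))
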