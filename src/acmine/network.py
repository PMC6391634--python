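"""Activity-cliff networks: construction, cluster identification and the
sd-vs-combined comparison.

Nodes are cliff compounds, edges are cliffs (one edge per compound pair).
A connected component with exactly two nodes is an isolated pair; components
with more than two nodes are clusters of coordinated cliffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .chem_io import Compound, Status
from .cliff_calling import CLIFF_SD, Cliff
from .errors import ConsistencyError

KIND_ISOLATED_PAIR = "isolated_pair"
KIND_CLUSTER = "cluster"


@dataclass(frozen=True)
class Cluster:
    member_node_ids: frozenset[str]
    n_edges: int
    kind: str
    n_sd_edges: int
    n_isd_edges: int
    n_original_edges: int

    @property
    def size(self) -> int:
        return len(self.member_node_ids)


@dataclass
class NetworkComparison:
    """Effect of adding isd cliffs to an sd-cliff network.

    A *new* cluster is a combined component of >2 nodes with no sd edge; an
    *extended* cluster strictly contains at least one sd component plus an
    inactive node.  A component merging two or more sd components through
    inactive bridges counts once as extended and is flagged merged.
    2-node isd-only components are reported separately as isolated pairs.
    """

    n_new_clusters: int = 0
    n_extended_clusters: int = 0
    n_merged_clusters: int = 0
    n_unchanged_components: int = 0
    n_new_isolated_pairs: int = 0
    new_clusters: list[frozenset[str]] = field(default_factory=list)
    extended_clusters: list[frozenset[str]] = field(default_factory=list)
    cluster_details: list[Cluster] = field(default_factory=list)


def build_network(
    cliffs: Iterable[Cliff],
    compounds: Mapping[str, Compound],
    acrp_ids: frozenset[str] | set[str] = frozenset(),
) -> nx.Graph:
    """Graph with one node per cliff compound and one edge per cliff.

    Node attributes: status, pki (actives), acrp flag.  Edge attributes:
    cliff_type, family, delta_pki when present.  Parallel cliffs on the same
    compound pair collapse to the first edge seen.
    """
    g = nx.Graph()
    for cliff in cliffs:
        a, b = cliff.ids
        for cid in (a, b):
            if g.has_node(cid):
                continue
            c = compounds[cid]
            attrs = {"status": c.status.value, "acrp": cid in acrp_ids}
            if c.pki is not None:
                attrs["pki"] = c.pki
            g.add_node(cid, **attrs)
        if g.has_edge(a, b):
            continue
        attrs = {"cliff_type": cliff.cliff_type, "family": cliff.family}
        if cliff.delta_pki is not None:
            attrs["delta_pki"] = cliff.delta_pki
        g.add_edge(a, b, **attrs)
    return g


def find_clusters(net: nx.Graph) -> list[Cluster]:
    """Connected components as clusters / isolated pairs, sorted by size."""
    clusters = []
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        types = [d["cliff_type"] for _, _, d in sub.edges(data=True)]
        clusters.append(
            Cluster(
                member_node_ids=frozenset(comp),
                n_edges=sub.number_of_edges(),
                kind=KIND_CLUSTER if len(comp) > 2 else KIND_ISOLATED_PAIR,
                n_sd_edges=sum(t == "sd" for t in types),
                n_isd_edges=sum(t == "isd" for t in types),
                n_original_edges=sum(t == "original" for t in types),
            )
        )
    clusters.sort(key=lambda c: (-c.size, sorted(c.member_node_ids)))
    return clusters


def compare_networks(sd_net: nx.Graph, combined_net: nx.Graph) -> NetworkComparison:
    """Compare an sd-only network with the sd+isd combined network."""
    for a, b in sd_net.edges:
        if not combined_net.has_edge(a, b):
            raise ConsistencyError(
                f"combined network misses sd edge {a!r}-{b!r}"
            )
    sd_components = [frozenset(c) for c in nx.connected_components(sd_net)]
    report = NetworkComparison()
    for comp in nx.connected_components(combined_net):
        comp = frozenset(comp)
        sub = combined_net.subgraph(comp)
        has_sd_edge = any(
            d["cliff_type"] == CLIFF_SD for _, _, d in sub.edges(data=True)
        )
        contained_sd = [c for c in sd_components if c <= comp]
        if any(c == comp for c in contained_sd):
            report.n_unchanged_components += 1
            continue
        has_inactive = any(
            sub.nodes[n].get("status") == Status.INACTIVE.value for n in comp
        )
        if len(comp) == 2:
            if not has_sd_edge:
                report.n_new_isolated_pairs += 1
            continue
        if not has_sd_edge:
            report.n_new_clusters += 1
            report.new_clusters.append(comp)
        elif contained_sd and has_inactive:
            report.n_extended_clusters += 1
            report.extended_clusters.append(comp)
            if len(contained_sd) >= 2:
                report.n_merged_clusters += 1
    report.cluster_details = find_clusters(combined_net)
    report.new_clusters.sort(key=sorted)
    report.extended_clusters.sort(key=sorted)
    return report


# ---------------------------------------------------------------------------
# Export: node/edge TSV tables plus GraphML for external viewers.
# ---------------------------------------------------------------------------

_NODE_COLUMNS = ("node_id", "status", "pki", "acrp")
_EDGE_COLUMNS = ("source", "target", "cliff_type", "family", "delta_pki")


def export_graph(net: nx.Graph, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>_nodes.tsv``, ``<prefix>_edges.tsv`` and
    ``<prefix>.graphml``; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nodes_path = prefix.with_name(prefix.name + "_nodes.tsv")
    edges_path = prefix.with_name(prefix.name + "_edges.tsv")
    graphml_path = prefix.with_name(prefix.name + ".graphml")

    lines = ["\t".join(_NODE_COLUMNS)]
    for n in sorted(net.nodes):
        d = net.nodes[n]
        pki = d.get("pki")
        lines.append(
            "\t".join(
                [
                    str(n),
                    d.get("status", ""),
                    "" if pki is None else repr(float(pki)),
                    str(int(bool(d.get("acrp", False)))),
                ]
            )
        )
    nodes_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["\t".join(_EDGE_COLUMNS)]
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        d = net.edges[a, b]
        delta = d.get("delta_pki")
        lines.append(
            "\t".join(
                [
                    str(a),
                    str(b),
                    d.get("cliff_type", ""),
                    d.get("family", ""),
                    "" if delta is None else repr(float(delta)),
                ]
            )
        )
    edges_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    nx.write_graphml(net, graphml_path)
    return {"nodes": nodes_path, "edges": edges_path, "graphml": graphml_path}


def read_graph_tables(prefix: str | Path) -> nx.Graph:
    """Rebuild a network from the node/edge tables written by export_graph."""
    prefix = Path(prefix)
    g = nx.Graph()
    node_lines = (
        prefix.with_name(prefix.name + "_nodes.tsv").read_text().splitlines()
    )
    for line in node_lines[1:]:
        node_id, status, pki, acrp = line.split("\t")
        attrs = {"status": status, "acrp": bool(int(acrp))}
        if pki:
            attrs["pki"] = float(pki)
        g.add_node(node_id, **attrs)
    edge_lines = (
        prefix.with_name(prefix.name + "_edges.tsv").read_text().splitlines()
    )
    for line in edge_lines[1:]:
        a, b, cliff_type, family, delta = line.split("\t")
        attrs = {"cliff_type": cliff_type, "family": family}
        if delta:
            attrs["delta_pki"] = float(delta)
        g.add_edge(a, b, **attrs)
    return g
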