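"""Assembly of the TF -> miRNA -> target-TF-family regulatory network.

Nodes are miRNA genes and TF families; edges are directed TF_to_miRNA
(a family's binding site found in a miRNA promoter) or miRNA_to_target
(a negatively correlated target rolled up to its TF family).  Family-level
feedback loops are directed 2-cycles between a TF family and a miRNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd

TF_TO_MIRNA = "TF_to_miRNA"
MIRNA_TO_TARGET = "miRNA_to_target"

_FAMILY_RE = re.compile(r"(miR[a-z]*\d+)", re.IGNORECASE)


class NetworkValidationError(ValueError):
    pass


def mirna_family(name: str) -> str:
    """Maximal ``miR<number>`` prefix of a miRNA gene name.

    ``miR159h -> miR159``; ``miRn6 -> miRn6``; a species prefix such as
    ``zma-`` is stripped first.  Names without the pattern are returned
    unchanged.
    """
    stripped = name.split("-", 1)[-1] if "-" in name and "miR" in name else name
    m = _FAMILY_RE.search(stripped)
    return m.group(1) if m else name


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_mirna_nodes: int
    n_mirna_families: int
    n_tf_families: int
    n_tf_upstream_only: int
    n_tf_target_only: int
    n_tf_both: int
    n_feedback_loops: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def build_network(
    tf_mirna_table: pd.DataFrame,
    mirna_target_table: pd.DataFrame,
    mirna_regulation_table: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Assemble the directed regulatory graph from the two edge tables.

    ``tf_mirna_table`` needs columns ``mirna_id`` and ``tf_family`` (a TF
    family with a binding site in that miRNA's promoter);
    ``mirna_target_table`` needs ``mirna_id`` and ``tf_family`` (the family
    of a negatively correlated target).  ``mirna_regulation_table``
    (``mirna_id``, ``regulation`` in up/down) annotates miRNA nodes and must
    cover every miRNA appearing in an edge.
    """
    regulation: dict[str, str] = {}
    if mirna_regulation_table is not None:
        regulation = dict(
            zip(mirna_regulation_table["mirna_id"], mirna_regulation_table["regulation"])
        )
    graph = nx.DiGraph()
    mirnas = set(tf_mirna_table["mirna_id"]) | set(mirna_target_table["mirna_id"])
    if mirna_regulation_table is not None:
        missing = mirnas - set(regulation)
        if missing:
            raise NetworkValidationError(
                f"miRNAs missing from the regulation table: {sorted(missing)}"
            )
    for row in tf_mirna_table.itertuples():
        graph.add_node(row.tf_family, kind="TF_family")
        graph.add_node(row.mirna_id, kind="miRNA")
        graph.add_edge(row.tf_family, row.mirna_id, kind=TF_TO_MIRNA)
    for row in mirna_target_table.itertuples():
        graph.add_node(row.mirna_id, kind="miRNA")
        graph.add_node(row.tf_family, kind="TF_family")
        graph.add_edge(row.mirna_id, row.tf_family, kind=MIRNA_TO_TARGET)
    for node, data in graph.nodes(data=True):
        if data["kind"] == "miRNA":
            data["regulation"] = regulation.get(node, "")
            data["family"] = mirna_family(node)
    _assert_bipartite_kinds(graph)
    _annotate_tf_roles(graph)
    return graph


def _assert_bipartite_kinds(graph: nx.DiGraph) -> None:
    for u, v, data in graph.edges(data=True):
        ku = graph.nodes[u]["kind"]
        kv = graph.nodes[v]["kind"]
        if data["kind"] == TF_TO_MIRNA and (ku, kv) != ("TF_family", "miRNA"):
            raise NetworkValidationError(f"edge {u}->{v} breaks TF->miRNA typing")
        if data["kind"] == MIRNA_TO_TARGET and (ku, kv) != ("miRNA", "TF_family"):
            raise NetworkValidationError(f"edge {u}->{v} breaks miRNA->target typing")


def _annotate_tf_roles(graph: nx.DiGraph) -> None:
    for node, data in graph.nodes(data=True):
        if data["kind"] != "TF_family":
            continue
        upstream = graph.out_degree(node) > 0
        target = graph.in_degree(node) > 0
        data["tf_role"] = (
            "both" if upstream and target else "upstream_only" if upstream else "target_only"
        )


def find_feedback_loops(graph: nx.DiGraph) -> list[tuple[str, str]]:
    """All (TF family, miRNA) pairs joined by edges in both directions."""
    loops = []
    for u, v in graph.edges:
        if graph.nodes[u]["kind"] == "TF_family" and graph.has_edge(v, u):
            loops.append((u, v))
    return sorted(loops)


def summarize_network(graph: nx.DiGraph) -> NetworkSummary:
    mirnas = [n for n, d in graph.nodes(data=True) if d.get("kind") == "miRNA"]
    tfs = [n for n, d in graph.nodes(data=True) if d.get("kind") == "TF_family"]
    roles = [graph.nodes[t].get("tf_role", "") for t in tfs]
    return NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_mirna_nodes=len(mirnas),
        n_mirna_families=len({mirna_family(m) for m in mirnas}),
        n_tf_families=len(tfs),
        n_tf_upstream_only=roles.count("upstream_only"),
        n_tf_target_only=roles.count("target_only"),
        n_tf_both=roles.count("both"),
        n_feedback_loops=len(find_feedback_loops(graph)),
    )
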