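"""Bipartite lncRNA-CEG co-expression networks and their export formats.

Graphs are :class:`networkx.MultiGraph` objects whose nodes carry a
``node_class`` attribute (``LNCRNA`` or ``PCG``) and whose edges carry
``coefficient``, ``r``, ``p_value`` and ``dataset_id``; the multi-edge
key is the dataset id, so cross-dataset support for a pair stays visible.
Exports target desktop Cytoscape: GraphML, SIF (with a companion
edge-attribute TSV), and a two-file node/edge TSV convention.
"""

from __future__ import annotations

import logging
from enum import Enum
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .coexpression import CEGSet
from .errors import ValidationError

logger = logging.getLogger(__name__)


class GraphFormat(str, Enum):
    GRAPHML = "graphml"
    SIF = "sif"
    NODE_EDGE_TSV = "node_edge_tsv"


EDGE_ATTRS = ["coefficient", "r", "p_value", "dataset_id"]


def check_bipartite(graph: nx.MultiGraph) -> None:
    """Assert the LNCRNA/PCG partition: every edge crosses it."""
    for node, data in graph.nodes(data=True):
        if data.get("node_class") not in ("LNCRNA", "PCG"):
            raise ValidationError(f"node {node} lacks a valid node_class")
    for u, v in graph.edges():
        cu = graph.nodes[u]["node_class"]
        cv = graph.nodes[v]["node_class"]
        if {cu, cv} != {"LNCRNA", "PCG"}:
            raise ValidationError(f"edge {u}--{v} does not join LNCRNA to PCG")


def build_network(ceg_sets: Sequence[CEGSet]) -> nx.MultiGraph:
    """Assemble the bipartite graph from CEG sets with provenance.

    One edge per association record that passed the thresholds, keyed by
    dataset id; nodes are the lncRNAs plus the union of their CEGs.
    """
    if not ceg_sets:
        raise ValidationError("no CEG sets to build a network from")
    graph = nx.MultiGraph()
    for ceg in ceg_sets:
        graph.add_node(ceg.lnc_id, node_class="LNCRNA")
        for pcg in sorted(ceg.members):
            graph.add_node(pcg, node_class="PCG")
        for row in ceg.provenance.itertuples(index=False):
            key = ceg.dataset_id
            if graph.has_edge(ceg.lnc_id, row.pcg_id, key=key):
                raise ValidationError(
                    f"duplicate edge ({ceg.lnc_id}, {row.pcg_id}, {key})"
                )
            graph.add_edge(
                ceg.lnc_id,
                row.pcg_id,
                key=key,
                coefficient=float(row.coefficient),
                r=float(row.r),
                p_value=float(row.p_value),
                dataset_id=key,
            )
    check_bipartite(graph)
    logger.info(
        "network: %d nodes, %d edges", graph.number_of_nodes(), graph.number_of_edges()
    )
    return graph


def collapse_parallel_edges(graph: nx.MultiGraph) -> nx.MultiGraph:
    """Merge parallel cross-dataset edges, keeping the smallest p-value."""
    out = nx.MultiGraph()
    out.add_nodes_from(graph.nodes(data=True))
    best: dict[tuple[str, str], dict] = {}
    for u, v, data in graph.edges(data=True):
        pair = tuple(sorted((u, v)))
        if pair not in best or data["p_value"] < best[pair]["p_value"]:
            best[pair] = data
    for (u, v), data in best.items():
        out.add_edge(u, v, key=data["dataset_id"], **data)
    return out


# ---------------------------------------------------------------------------
# serialisation


def _edge_frame(graph: nx.MultiGraph) -> pd.DataFrame:
    rows = []
    for u, v, data in graph.edges(data=True):
        lnc, pcg = (u, v) if graph.nodes[u]["node_class"] == "LNCRNA" else (v, u)
        rows.append({"lnc_id": lnc, "pcg_id": pcg, **{a: data[a] for a in EDGE_ATTRS}})
    df = pd.DataFrame(rows, columns=["lnc_id", "pcg_id", *EDGE_ATTRS])
    return df.sort_values(["lnc_id", "pcg_id", "dataset_id"]).reset_index(drop=True)


def write_graph(graph: nx.MultiGraph, fmt: GraphFormat | str, out_path) -> list[Path]:
    """Serialise the graph; returns the paths written.

    GRAPHML writes a single attribute-complete file. SIF writes
    ``<stem>.sif`` with relation ``coexp`` plus ``<stem>.edges.tsv``
    attributes. NODE_EDGE_TSV writes ``<stem>.nodes.tsv`` and
    ``<stem>.edges.tsv``.
    """
    fmt = GraphFormat(fmt)
    check_bipartite(graph)
    out_path = Path(out_path)
    if fmt is GraphFormat.GRAPHML:
        nx.write_graphml(graph, out_path)
        return [out_path]
    stem = out_path.with_suffix("") if out_path.suffix else out_path
    edges = _edge_frame(graph)
    if fmt is GraphFormat.SIF:
        sif = stem.with_suffix(".sif")
        with sif.open("w") as fh:
            for row in edges.itertuples(index=False):
                fh.write(f"{row.lnc_id}\tcoexp\t{row.pcg_id}\n")
            # isolated nodes (lncRNAs with empty CEG sets) as lone-name lines
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
        attr = stem.with_suffix(".edges.tsv")
        edges.to_csv(attr, sep="\t", index=False, float_format="%.8g", lineterminator="\n")
        return [sif, attr]
    if fmt is GraphFormat.NODE_EDGE_TSV:
        nodes = pd.DataFrame(
            [{"id": n, "node_class": d["node_class"]} for n, d in graph.nodes(data=True)]
        ).sort_values("id")
        npath = stem.with_suffix(".nodes.tsv")
        epath = stem.with_suffix(".edges.tsv")
        nodes.to_csv(npath, sep="\t", index=False, lineterminator="\n")
        edges.to_csv(epath, sep="\t", index=False, float_format="%.8g", lineterminator="\n")
        return [npath, epath]
    raise ValidationError(f"unknown graph format {fmt}")


def read_graph(fmt: GraphFormat | str, *paths) -> nx.MultiGraph:
    """Read back a graph written by :func:`write_graph` (round-trip capable)."""
    fmt = GraphFormat(fmt)
    if fmt is GraphFormat.GRAPHML:
        (path,) = paths
        graph = nx.read_graphml(path, force_multigraph=True)
        graph = nx.MultiGraph(graph)
    elif fmt in (GraphFormat.SIF, GraphFormat.NODE_EDGE_TSV):
        # both variants reconstruct from the edge-attribute table
        edge_path = paths[-1]
        edges = pd.read_csv(edge_path, sep="\t")
        graph = nx.MultiGraph()
        if fmt is GraphFormat.NODE_EDGE_TSV:
            nodes = pd.read_csv(paths[0], sep="\t")
            for row in nodes.itertuples(index=False):
                graph.add_node(row.id, node_class=row.node_class)
        elif fmt is GraphFormat.SIF:
            with Path(paths[0]).open() as fh:
                for line in fh:
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) == 1 and fields[0]:
                        # lone-name SIF line: only lncRNAs can be isolated here
                        graph.add_node(fields[0], node_class="LNCRNA")
        for row in edges.itertuples(index=False):
            graph.add_node(row.lnc_id, node_class="LNCRNA")
            graph.add_node(row.pcg_id, node_class="PCG")
            graph.add_edge(
                row.lnc_id,
                row.pcg_id,
                key=str(row.dataset_id),
                coefficient=float(row.coefficient),
                r=float(row.r),
                p_value=float(row.p_value),
                dataset_id=str(row.dataset_id),
            )
    else:  # pragma: no cover
        raise ValidationError(f"unknown graph format {fmt}")
    check_bipartite(graph)
    return graph
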