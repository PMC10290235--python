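"""Thresholded gene/drug linkage networks.

From the three correlation classes (gene-gene, drug-drug, gene-drug) a
tri-partite network is built by keeping edges whose correlation passes a
per-class cutoff and dropping isolated nodes.  By default the threshold is
applied to the signed coefficient (rho >= cutoff): a drug that mimics a
knockout inhibits the same cell lines, so a similar-effect network keeps the
positive tail.  An absolute-value mode (|rho| >= cutoff) is available for
exploratory use.

Cutoff selection implements the stated objective — the largest average node
degree subject to a visualizable node count — as a constrained grid search;
``average_degree`` is 2*|E|/|V|.

Hub-query networks are star-like: a query entity, its top-k correlated
partners (selected from the full correlation tables, not from the thresholded
global network), and each partner's own top correlates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .correlate import (
    CorrelationTable,
    DEFAULT_MIN_PAIRS,
    DRUG_DRUG,
    GENE_DRUG,
    GENE_GENE,
    top_k_neighbors,
)
from .errors import DataError
from .io import DependencyMatrix, _comment_header

logger = logging.getLogger(__name__)

EDGE_CLASSES = (GENE_GENE, DRUG_DRUG, GENE_DRUG)

#: node classes implied by an edge class for (entity_a, entity_b)
_NODE_CLASSES = {
    GENE_GENE: ("gene", "gene"),
    DRUG_DRUG: ("drug", "drug"),
    GENE_DRUG: ("gene", "drug"),
}


@dataclass
class LinkageNetwork:
    """Thresholded correlation network of gene and drug nodes."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("node_class") == node_class
        )

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "edge_class": d["edge_class"], "rho": d["rho"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["a", "b", "edge_class", "rho"])
        return df.sort_values(["edge_class", "a", "b"]).reset_index(drop=True)

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(_comment_header({"table": "network_edges", **self.provenance}))
            self.edge_list().to_csv(fh, sep="\t", index=False)

    @staticmethod
    def from_edge_tsv(path: str | Path) -> "LinkageNetwork":
        df = pd.read_csv(path, sep="\t", comment="#")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            ca, cb = _NODE_CLASSES[row.edge_class]
            g.add_node(row.a, node_class=ca)
            g.add_node(row.b, node_class=cb)
            g.add_edge(row.a, row.b, edge_class=row.edge_class, rho=float(row.rho))
        return LinkageNetwork(graph=g)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def _passes(rho: pd.Series, cutoff: float, signed_mode: str) -> pd.Series:
    if signed_mode == "signed":
        return rho >= cutoff
    return rho.abs() >= cutoff


def build_global_network(
    corr: CorrelationTable,
    cutoffs: dict[str, float],
    signed_mode: str = "signed",
) -> LinkageNetwork:
    """Keep edges with rho >= per-class cutoff; drop degree-0 nodes.

    ``cutoffs`` maps each edge class (gene_gene, drug_drug, gene_drug) to its
    threshold.  Negative cutoffs are rejected; use ``signed_mode="absolute"``
    to threshold |rho| instead.
    """
    if signed_mode not in ("signed", "absolute"):
        raise DataError(f"unknown signed_mode {signed_mode!r}")
    for cls in EDGE_CLASSES:
        if cls not in cutoffs:
            raise DataError(f"missing cutoff for edge class {cls!r}")
        if cutoffs[cls] < 0:
            raise DataError(
                f"negative cutoff {cutoffs[cls]} for {cls}; use signed_mode='absolute' "
                "to threshold on |rho|"
            )
    g = nx.Graph()
    for cls in EDGE_CLASSES:
        df = corr.of_class(cls)
        if df.empty:
            continue
        kept = df[_passes(df["rho"], cutoffs[cls], signed_mode)]
        ca, cb = _NODE_CLASSES[cls]
        for row in kept.itertuples(index=False):
            g.add_node(row.entity_a, node_class=ca)
            g.add_node(row.entity_b, node_class=cb)
            g.add_edge(row.entity_a, row.entity_b, edge_class=cls, rho=float(row.rho))
    prov = {f"cutoff_{c}": cutoffs[c] for c in EDGE_CLASSES}
    prov["signed_mode"] = signed_mode
    prov["scope"] = corr.scope
    return LinkageNetwork(graph=g, provenance=prov)


def average_degree(net: LinkageNetwork) -> float:
    """Mean node degree, 2*|edges|/|nodes|."""
    if net.n_nodes == 0:
        raise DataError("empty network has no average degree")
    return 2.0 * net.n_edges / net.n_nodes


def select_cutoffs(
    corr: CorrelationTable,
    max_nodes: int | float = 600,
    grid: dict[str, list[float]] | None = None,
    signed_mode: str = "signed",
) -> tuple[dict[str, float], dict]:
    """Grid-search per-class cutoffs maximizing average node degree subject
    to a node-count bound.

    Evaluates every cutoff triple in the grid; ties break by fewer nodes,
    then by larger gene-drug cutoff.  Default grid: 0.1..0.9 step 0.1 for
    each class.  Raises when no grid point satisfies the bound.
    """
    if grid is None:
        default = [round(0.1 * i, 1) for i in range(1, 10)]
        grid = {c: default for c in EDGE_CLASSES}
    for cls in EDGE_CLASSES:
        vals = grid.get(cls, [])
        if len(vals) < 2:
            raise DataError(f"grid for {cls!r} needs >= 2 candidates")
        if any(v < 0 or v > 1 for v in vals):
            raise DataError(f"grid values for {cls!r} must be in [0, 1]")

    best: tuple | None = None
    best_cut: dict[str, float] | None = None
    best_summary: dict | None = None
    for gg, dd, gd in itertools.product(grid[GENE_GENE], grid[DRUG_DRUG], grid[GENE_DRUG]):
        cut = {GENE_GENE: gg, DRUG_DRUG: dd, GENE_DRUG: gd}
        net = build_global_network(corr, cut, signed_mode=signed_mode)
        if net.n_nodes == 0 or net.n_nodes > max_nodes:
            continue
        deg = average_degree(net)
        key = (deg, -net.n_nodes, gd)  # maximize degree, then fewer nodes, then larger gd
        if best is None or key > best:
            best = key
            best_cut = cut
            best_summary = {
                "n_nodes": net.n_nodes,
                "n_edges": net.n_edges,
                "average_degree": deg,
                "n_genes": len(net.nodes_of_class("gene")),
                "n_drugs": len(net.nodes_of_class("drug")),
            }
    if best_cut is None:
        raise DataError(
            f"no grid point yields a non-empty network with <= {max_nodes} nodes; "
            "try a larger max_nodes"
        )
    return best_cut, best_summary


def hub_query_network(
    hub: str,
    gene_m: DependencyMatrix,
    drug_m: DependencyMatrix,
    k_drugs: int = 10,
    k_genes: int = 10,
    *,
    cutoffs: dict[str, float] | None = None,
    signed_mode: str = "signed",
    ranking: str = "signed_desc",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> LinkageNetwork:
    """Star network around a hub gene (or drug, with roles mirrored).

    Nodes: the hub, its top-``k_drugs`` correlated drugs, and each such
    drug's top-``k_genes`` correlated genes.  Edges: the selection edges
    plus, when global ``cutoffs`` are given, any edge among included nodes
    passing those cutoffs.  Top-k selections use the full correlation
    tables, not a pre-thresholded network.
    """
    if hub in gene_m.entity_ids:
        hub_m, partner_m = gene_m, drug_m
        hub_class, partner_class = "gene", "drug"
        hub_edge = GENE_DRUG
    elif hub in drug_m.entity_ids:
        hub_m, partner_m = drug_m, gene_m
        hub_class, partner_class = "drug", "gene"
        hub_edge = GENE_DRUG
    else:
        raise DataError(f"unknown hub {hub!r}")

    g = nx.Graph()
    g.add_node(hub, node_class=hub_class)
    partners = top_k_neighbors(
        hub, hub_m, partner_m, k_drugs, ranking=ranking, min_pairs=min_pairs
    )
    for row in partners.itertuples(index=False):
        g.add_node(row.entity_b, node_class=partner_class)
        g.add_edge(hub, row.entity_b, edge_class=hub_edge, rho=float(row.rho))
        if k_genes > 0:
            second = top_k_neighbors(
                row.entity_b, partner_m, hub_m, k_genes,
                ranking=ranking, min_pairs=min_pairs,
            )
            for srow in second.itertuples(index=False):
                if srow.entity_b == hub:
                    continue
                g.add_node(srow.entity_b, node_class=hub_class)
                g.add_edge(
                    row.entity_b, srow.entity_b,
                    edge_class=hub_edge, rho=float(srow.rho),
                )

    if cutoffs is not None:
        from .correlate import correlate_cross, correlate_within

        genes = [n for n, d in g.nodes(data=True) if d["node_class"] == "gene"]
        drugs = [n for n, d in g.nodes(data=True) if d["node_class"] == "drug"]
        sub_g = DependencyMatrix(gene_m.kind, gene_m.data.loc[[x for x in genes if x in gene_m.entity_ids]])
        sub_d = DependencyMatrix(drug_m.kind, drug_m.data.loc[[x for x in drugs if x in drug_m.entity_ids]])
        tables = []
        if len(genes) >= 2:
            tables.append(correlate_within(sub_g, min_pairs=min_pairs))
        if len(drugs) >= 2:
            tables.append(correlate_within(sub_d, min_pairs=min_pairs))
        tables.append(correlate_cross(sub_g, sub_d, "all", min_pairs=min_pairs))
        corr = CorrelationTable.concat(tables)
        extra = build_global_network(corr, cutoffs, signed_mode=signed_mode)
        for a, b, d in extra.graph.edges(data=True):
            if not g.has_edge(a, b):
                g.add_edge(a, b, **d)

    prov = {
        "hub": hub, "k_drugs": k_drugs, "k_genes": k_genes,
        "ranking": ranking, "cutoffs": cutoffs or {},
    }
    return LinkageNetwork(graph=g, provenance=prov)
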