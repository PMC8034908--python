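"""Drug prioritization by average shortest-path distance to the marker genes.

Drug->target and gene-gene edges are merged into one simple undirected graph.
For each drug, breadth-first-search distances to the markers are averaged over
the reachable markers; drugs reaching no marker are excluded.  Paths never
traverse other drug nodes (drugs are leaves of the gene backbone).
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

__all__ = ["build_drug_gene_graph", "rank_drugs"]


def build_drug_gene_graph(drug_target_edges: pd.DataFrame,
                          ppi_edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected graph with node kinds; drug-drug edges are rejected."""
    g = nx.Graph()
    drugs = set(drug_target_edges.iloc[:, 0])
    for a, b in ppi_edges.iloc[:, :2].itertuples(index=False):
        if a == b:
            continue
        g.add_node(a, kind="gene")
        g.add_node(b, kind="gene")
        g.add_edge(a, b)
    for drug, gene in drug_target_edges.iloc[:, :2].itertuples(index=False):
        if gene in drugs:
            raise ValueError(f"drug-drug edge {drug}-{gene} is not allowed")
        g.add_node(drug, kind="drug")
        g.add_node(gene, kind="gene")
        g.add_edge(drug, gene)
    return g


def rank_drugs(graph: nx.Graph, markers) -> pd.DataFrame:
    """Average BFS distance from each drug to the marker genes, ascending.

    Markers absent from the graph are dropped with a warning; drugs reaching
    no marker are excluded (reported with n_reachable = 0).  Other drug nodes
    are removed before the search so paths cannot run through them.
    """
    markers = sorted(set(markers))
    if not markers:
        raise ValueError("markers must be nonempty")
    present = [m for m in markers if m in graph]
    absent = sorted(set(markers) - set(present))
    if absent:
        warnings.warn(f"markers absent from the graph: {absent}", stacklevel=2)
    if not present:
        raise ValueError("none of the markers is present in the graph")

    drugs = sorted(n for n, d in graph.nodes(data=True) if d.get("kind") == "drug")
    rows = []
    for drug in drugs:
        sub = graph.subgraph(
            [n for n, d in graph.nodes(data=True)
             if d.get("kind") != "drug" or n == drug]
        )
        dist = nx.single_source_shortest_path_length(sub, drug)
        reached = [dist[m] for m in present if m in dist]
        mean_path = sum(reached) / len(reached) if reached else float("nan")
        rows.append((drug, mean_path, len(reached)))
    table = pd.DataFrame(rows, columns=["drug", "mean_path", "n_reachable"])
    ranked = table[table["n_reachable"] > 0].sort_values(
        ["mean_path", "drug"], ignore_index=True
    )
    excluded = table[table["n_reachable"] == 0].reset_index(drop=True)
    if len(excluded):
        warnings.warn(
            f"{len(excluded)} drugs reach no marker and are excluded from the ranking",
            stacklevel=2,
        )
    return pd.concat([ranked, excluded], ignore_index=True)
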