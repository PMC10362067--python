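"""Gene-by-guQTL network: genes sharing significant variants.

A variant significantly associated with k >= 2 genes contributes one unit of
edge weight to each of its C(k,2) gene pairs; edge weight therefore counts
the shared significant variants of a gene pair.  Cliques of co-regulated
genes are read off the graph after pruning edges below a weight threshold
(the analysis keeps edges with weight > 2, i.e. at least 3 shared variants).
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import pandas as pd


def build_gene_graph(significant_pairs: list[tuple[str, str]]) -> nx.Graph:
    """Graph from (gene, variant) significant pairs.

    Nodes are genes with at least one significant guQTL; for every variant
    associated with more than one gene, each gene pair gains weight 1.  The
    per-variant gene-count histogram is stored on the graph
    (``G.graph["variant_gene_counts"]``)."""
    by_variant: dict[str, set[str]] = {}
    genes: set[str] = set()
    for gene, variant in significant_pairs:
        by_variant.setdefault(variant, set()).add(gene)
        genes.add(gene)
    G = nx.Graph()
    G.add_nodes_from(sorted(genes))
    for variant, vgenes in by_variant.items():
        for a, b in combinations(sorted(vgenes), 2):
            if G.has_edge(a, b):
                G[a][b]["weight"] += 1
            else:
                G.add_edge(a, b, weight=1)
    G.graph["variant_gene_counts"] = {v: len(g) for v, g in by_variant.items()}
    return G


def variant_gene_histogram(G: nx.Graph) -> pd.Series:
    """Number of variants associated with 1, 2, ... genes."""
    counts = pd.Series(G.graph.get("variant_gene_counts", {}))
    return counts.value_counts().sort_index()


def find_cliques(G: nx.Graph, min_weight: int = 3) -> list[list[str]]:
    """Maximal cliques of the pruned graph (edges with weight >= min_weight).

    Cliques are sorted by size (descending) then lexicographically; singleton
    cliques are suppressed.  A node may appear in several maximal cliques."""
    pruned = nx.Graph()
    pruned.add_nodes_from(G.nodes)
    for a, b, data in G.edges(data=True):
        if data.get("weight", 0) >= min_weight:
            pruned.add_edge(a, b, weight=data["weight"])
    cliques = [sorted(c) for c in nx.find_cliques(pruned) if len(c) >= 2]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def edge_table(G: nx.Graph) -> pd.DataFrame:
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d["weight"]}
        for a, b, d in sorted(G.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def clique_table(G: nx.Graph, min_weight: int = 3) -> pd.DataFrame:
    rows = []
    for i, clique in enumerate(find_cliques(G, min_weight)):
        weights = [
            G[a][b]["weight"] for a, b in combinations(clique, 2) if G.has_edge(a, b)
        ]
        rows.append(
            {
                "clique_id": i,
                "n_genes": len(clique),
                "genes": ",".join(clique),
                "min_edge_weight": min(weights),
                "max_edge_weight": max(weights),
            }
        )
    return pd.DataFrame(
        rows, columns=["clique_id", "n_genes", "genes", "min_edge_weight", "max_edge_weight"]
    )
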