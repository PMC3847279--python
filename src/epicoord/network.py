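"""Seeded protein-interaction subnetworks, PageRank hubs and modules.

A confidence-filtered undirected interaction graph is expanded from a seed
gene list by adding every gene that interacts with at least two seed genes
(the mediators), and the subnetwork induced by seed plus mediators is
ranked by PageRank and partitioned with resolution-parametrized Louvain
modularity optimization.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONFIDENCE_CUTOFF = 400        # inclusive, STRING "medium confidence"
DEFAULT_RESOLUTION = 1.66
DEFAULT_DAMPING = 0.85


def load_interactions(edges, cutoff: int = CONFIDENCE_CUTOFF) -> nx.Graph:
    """Build the confidence-filtered graph from a TSV path or DataFrame.

    Edges below ``cutoff`` are dropped (boundary kept), duplicates merged
    keeping the maximal confidence, self-loops discarded. Only genes with
    at least one retained interaction become nodes.
    """
    if not isinstance(edges, pd.DataFrame):
        path = Path(edges)
        try:
            edges = pd.read_csv(path, sep="\t")
            bad = edges["confidence"].isna() | edges["geneA"].isna() | edges["geneB"].isna()
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
                raise ValueError(f"malformed interaction row at line {line} of {path}")
        except (pd.errors.ParserError, KeyError) as exc:
            raise ValueError(f"cannot parse interaction file {path}: {exc}") from exc
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b, conf = str(row.geneA), str(row.geneB), float(row.confidence)
        if a == b or conf < cutoff:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    return g


def expand_seed(graph: nx.Graph, seed_genes) -> nx.Graph:
    """Subnetwork induced by the seed plus all genes with >= 2 seed neighbors."""
    seed = [s for s in seed_genes if graph.has_node(s)]
    missing = set(seed_genes) - set(seed)
    if missing:
        logger.info("%d seed genes absent from the graph; skipped", len(missing))
    if not seed:
        raise ValueError("no seed gene is present in the graph")
    seed_set = set(seed)
    mediators = {
        v for v in graph.nodes
        if v not in seed_set
        and sum(1 for u in graph[v] if u in seed_set) >= 2}
    sub = graph.subgraph(seed_set | mediators).copy()
    nx.set_node_attributes(sub, {v: v in seed_set for v in sub.nodes}, "seed")
    return sub


def pagerank_hubs(graph: nx.Graph,
                  damping: float = DEFAULT_DAMPING) -> pd.DataFrame:
    """PageRank over the undirected graph (each edge as two arcs), uniform
    teleport; returns genes sorted by descending score (sum = 1)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    pr = nx.pagerank(graph, alpha=damping, tol=1e-12, max_iter=500)
    df = pd.DataFrame(sorted(pr.items(), key=lambda kv: (-kv[1], kv[0])),
                      columns=["gene", "pagerank"])
    nx.set_node_attributes(graph, pr, "pagerank")
    return df


def detect_modules(graph: nx.Graph, resolution: float = DEFAULT_RESOLUTION,
                   seed: int = 0) -> dict[str, int]:
    """Louvain modules at the given resolution; ids dense from 1, ordered
    by decreasing module size (ties by smallest member name)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(graph, resolution=resolution,
                                             seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignment = {v: i + 1 for i, c in enumerate(comms) for v in sorted(c)}
    nx.set_node_attributes(graph, assignment, "module")
    return assignment


def seed_from_expression(gene_log2fc: pd.Series,
                         threshold: float = -2.0) -> list[str]:
    """Downregulated seed: genes strictly below the log2fc threshold."""
    return sorted(gene_log2fc.index[gene_log2fc < threshold])


def seed_from_clusters(labels: pd.Series, clusters) -> list[str]:
    """Merged cluster-membership seed (e.g. the EMT gene clusters)."""
    wanted = set(clusters)
    return sorted(labels.index[labels.isin(wanted)])


def hub_table(graph: nx.Graph, modules: dict[str, int],
              cluster_labels: pd.Series | None = None) -> pd.DataFrame:
    pr = nx.get_node_attributes(graph, "pagerank")
    rows = []
    for gene in graph.nodes:
        cl = None
        if cluster_labels is not None and gene in cluster_labels.index:
            cl = cluster_labels.loc[gene]
        rows.append((gene, cl, pr.get(gene, np.nan), modules.get(gene)))
    df = pd.DataFrame(rows, columns=["gene", "cluster", "pagerank", "module"])
    return df.sort_values("pagerank", ascending=False).reset_index(drop=True)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
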