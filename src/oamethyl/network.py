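"""Gene-level downstream analysis: CpG-to-gene mapping, effector-status
classification, over-representation testing, and interaction-network hub
scoring.

Interaction networks are STRING-export-style edge lists (two endpoint
columns plus an integer combined score on the 0-1000 scale); edges below
the confidence threshold (default 500, inclusive) are dropped.  Hubs are
ranked by a composite of degree and betweenness centrality, each min-max
standardized over the nodes and combined by a weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CpGAnnotation

DEFAULT_MIN_SCORE = 500
DEFAULT_TOP_K = 20


# -- gene mapping ------------------------------------------------------------

def map_cpg_to_genes(panel, annotation: CpGAnnotation
                     ) -> tuple[list[str], list[str]]:
    """Union of gene symbols linked to the panel probes.

    Returns (sorted unique gene list, probes with no gene link); probes
    absent from the annotation raise.
    """
    panel = list(panel)
    known = set(annotation.probes["cpg_id"])
    absent = [p for p in panel if p not in known]
    if absent:
        raise ValueError(f"probes missing from annotation: {absent[:10]}")
    links = annotation.links[annotation.links["cpg_id"].isin(panel)]
    genes = sorted(set(links["gene"]))
    linked = set(links["cpg_id"])
    unmapped = [p for p in panel if p not in linked]
    return genes, unmapped


def classify_effector_status(genes, validated, database_reported
                             ) -> tuple[int, int, int]:
    """Partition mapped genes into previously-validated effectors,
    database-reported effectors, and novel candidates.

    A gene in both reference lists counts once, as validated.
    """
    genes = set(genes)
    validated = set(validated)
    database_reported = set(database_reported) - validated
    n_validated = len(genes & validated)
    n_database = len(genes & database_reported)
    n_novel = len(genes) - n_validated - n_database
    return n_validated, n_database, n_novel


# -- over-representation -----------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets, GMT-compatible (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.sets:
                members = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{self.descriptions.get(name, '')}\t"
                         f"{members}\n")

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets, descriptions = {}, {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                name, desc, members = parts[0], parts[1], parts[2:]
                sets[name] = set(m for m in members if m)
                descriptions[name] = desc
        return cls(sets=sets, descriptions=descriptions)


def hypergeometric_ora(query, collection: GeneSetCollection,
                       background) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set,
    BH-adjusted across all tested sets, sorted by adjusted p.

    p = P(overlap >= observed) with the set intersected with the
    background universe and the query required to lie inside it.
    """
    from .screening import benjamini_hochberg

    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    M, N = len(background), len(query)
    rows = []
    for name, members in collection.sets.items():
        inset = members & background
        n = len(inset)
        k = len(inset & query)
        # survival function at k-1 gives P(X >= k), including k = 0 -> 1
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append({"set_name": name, "overlap_count": k, "set_size": n,
                     "query_size": N, "background_size": M,
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["adj_p"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table.sort_values(["adj_p", "p_value", "set_name"],
                             kind="mergesort").reset_index(drop=True)


# -- interaction network -----------------------------------------------------

def load_edge_list(path, min_score: int = DEFAULT_MIN_SCORE) -> nx.Graph:
    """Read a STRING-like TSV (node_a, node_b, combined_score).

    Keeps edges scoring >= min_score, drops self-loops, and merges
    duplicate undirected edges keeping the maximum score.
    """
    graph = nx.Graph()
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                a, b, score = parts[0], parts[1], int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed edge row at line {lineno}: "
                                 f"{line!r}") from exc
            if a == b or score < min_score:
                continue
            if graph.has_edge(a, b):
                score = max(score, graph[a][b]["combined_score"])
            graph.add_edge(a, b, combined_score=score)
    return graph


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo == 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def composite_node_score(graph: nx.Graph, w_degree: float = 0.5,
                         w_between: float = 0.5,
                         top_k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Rank nodes by a weighted sum of min-max standardized degree and
    betweenness centralities; descending composite, node-id tie-break.

    Betweenness uses the standard whole-graph pair normalization, so on
    disconnected graphs cross-component pairs simply contribute zero.
    """
    if abs(w_degree + w_between - 1.0) > 1e-9:
        raise ValueError("centrality weights must sum to 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    deg = nx.degree_centrality(graph)
    btw = nx.betweenness_centrality(graph, normalized=True)
    deg_c = np.array([deg[n] for n in nodes])
    btw_c = np.array([btw[n] for n in nodes])
    deg_std = _minmax(deg_c)
    btw_std = _minmax(btw_c)
    table = pd.DataFrame({
        "node": nodes,
        "degree_c": deg_c, "betweenness_c": btw_c,
        "degree_std": deg_std, "betweenness_std": btw_std,
        "composite": w_degree * deg_std + w_between * btw_std,
    })
    table = table.sort_values(["composite", "node"],
                              ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    return table.head(top_k)
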