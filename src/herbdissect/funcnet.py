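"""GO enrichment, the Jaccard functional network, and its graph statistics.

Per-module over-representation uses the hypergeometric upper tail with BH
adjustment across each module's tested terms.  The functional network joins
the top-15 terms of every module: a node per (term, module) selection, an
edge wherever the Jaccard coefficient of the two terms' gene sets exceeds
0.2 (strict).  Intramodular connectivity is the module-mean clustering
coefficient C_i = 2 e_i / (k_i (k_i - 1)); extramodular connectivity the sum
over module nodes of their degree toward other modules' nodes.  Modules are
clustered with average linkage on mean (1 - topological overlap) between
their node sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .diffexpr import benjamini_hochberg
from .patterns import GeneModule

JACCARD_THRESHOLD = 0.2
TOP_TERMS = 15
N_CLUSTERS = 4


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_enrich(
    module: GeneModule,
    annotation: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of every overlapping term.

    p = P[X >= k] with X ~ Hypergeometric(N=|universe|, K=|term|, n=|module|),
    gene sets first intersected with the universe; terms with k = 0 are not
    reported.  Columns: term_id, k, K, n, N, p, padj (BH over tested terms).
    """
    if not universe:
        raise ValueError("empty enrichment universe")
    mod_genes = set(module.genes) & universe
    n = len(mod_genes)
    N = len(universe)
    rows = []
    for term, genes in annotation.items():
        term_genes = genes & universe
        k = len(term_genes & mod_genes)
        if k == 0 or not term_genes:
            continue
        K = len(term_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(df):
        df["padj"] = benjamini_hochberg(df["p"].to_numpy())
        df.insert(0, "module_id", module.module_id)
    else:
        df["padj"] = []
        df.insert(0, "module_id", module.module_id)
    return df


def top_terms(results: pd.DataFrame, limit: int = TOP_TERMS) -> pd.DataFrame:
    """First ``limit`` terms by ascending p; ties break by larger overlap k,
    then lexical term id."""
    if limit < 0:
        raise ValueError("limit must be >= 0")
    ordered = results.sort_values(
        ["p", "k", "term_id"], ascending=[True, False, True], kind="stable"
    )
    return ordered.head(limit).reset_index(drop=True)


# ---------------------------------------------------------------------------
# network


def jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    union = a | b
    return len(a & b) / len(union)


def build_go_network(
    selected: dict[str, pd.DataFrame],
    annotation: dict[str, set[str]],
    threshold: float = JACCARD_THRESHOLD,
    dedupe: bool = False,
) -> nx.Graph:
    """Assemble the functional network from per-module selected terms.

    ``selected`` maps module_id -> term table (from :func:`top_terms`).  Each
    (term, module) selection is one node, id ``term@module``, so a term
    enriched in several modules appears once per module (their J = 1 edges
    link the copies); ``dedupe=True`` collapses such terms into a single node
    attributed to its best-p module.  Edges join every node pair with
    J(A, B) > ``threshold`` (strict).  Node attributes: term, module, p,
    genes.
    """
    picks: list[tuple[str, str, float]] = []  # (term, module, p)
    for module_id in sorted(selected):
        for _, row in selected[module_id].iterrows():
            picks.append((row["term_id"], module_id, float(row["p"])))
    if dedupe:
        best: dict[str, tuple[str, str, float]] = {}
        for term, module_id, p in picks:
            if term not in best or p < best[term][2]:
                best[term] = (term, module_id, p)
        picks = sorted(best.values())

    g = nx.Graph()
    for term, module_id, p in picks:
        node = term if dedupe else f"{term}@{module_id}"
        if term not in annotation:
            raise KeyError(f"term {term!r} has no gene set in the annotation")
        g.add_node(node, term=term, module=module_id, p=p, genes=frozenset(annotation[term]))
    nodes = list(g.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            j = jaccard(set(g.nodes[u]["genes"]), set(g.nodes[v]["genes"]))
            if j > threshold:
                g.add_edge(u, v, jaccard=j)
    return g


# ---------------------------------------------------------------------------
# connectivity statistics


@dataclass
class ConnectivityStats:
    node_table: pd.DataFrame  # node, module, degree, triangles, Ci
    module_table: pd.DataFrame  # module, n_nodes, C, extramodular


def clustering_stats(net: nx.Graph) -> ConnectivityStats:
    """Clustering coefficients and module connectivity statistics.

    C_i = 2 e_i / (k_i (k_i - 1)), defined 0 for degree < 2; the module
    statistic C is the mean C_i over its nodes.  Extramodular connectivity is
    the summed cross-module degree of the module's nodes (``total_degree``
    columns report the unrestricted sum too).
    """
    tri = nx.triangles(net)
    ci = nx.clustering(net)
    rows = [
        {
            "node": v,
            "module": net.nodes[v]["module"],
            "degree": net.degree(v),
            "triangles": tri[v],
            "Ci": ci[v],
        }
        for v in net.nodes
    ]
    node_table = pd.DataFrame(rows, columns=["node", "module", "degree", "triangles", "Ci"])

    mod_rows = []
    for module_id, sub in node_table.groupby("module"):
        if sub.empty:
            raise ValueError(f"module {module_id!r} has zero nodes")
        cross = 0
        for v in sub["node"]:
            cross += sum(1 for u in net.neighbors(v) if net.nodes[u]["module"] != module_id)
        mod_rows.append(
            {
                "module": module_id,
                "n_nodes": len(sub),
                "C": float(sub["Ci"].mean()),
                "extramodular": int(cross),
                "total_degree": int(sub["degree"].sum()),
            }
        )
    module_table = pd.DataFrame(
        mod_rows, columns=["module", "n_nodes", "C", "extramodular", "total_degree"]
    ).sort_values("module", ignore_index=True)
    return ConnectivityStats(node_table=node_table, module_table=module_table)


# ---------------------------------------------------------------------------
# topological overlap and module clustering


def topological_overlap(net: nx.Graph, nodes: list | None = None) -> pd.DataFrame:
    """Unsigned Ravasz-style TOM on the unweighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj; TOM_ii = 1; pairs where the denominator would
    involve an isolated node give 0.
    """
    if nodes is None:
        nodes = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    k = A.sum(axis=1)
    L = A @ A
    min_k = np.minimum(k[:, None], k[None, :])
    denom = min_k + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=nodes, columns=nodes)


@dataclass
class ModuleClustering:
    dissimilarity: pd.DataFrame
    linkage_matrix: np.ndarray
    labels: pd.Series  # module -> cluster id (1..n_clusters)
    cluster_members: dict[int, list[str]] = field(default_factory=dict)


def cluster_modules(net: nx.Graph, tom: pd.DataFrame, n_clusters: int = N_CLUSTERS) -> ModuleClustering:
    """Average-linkage clustering of modules on mean (1 - TOM) dissimilarity.

    The dissimilarity between two modules is the mean of 1 - TOM_ij over all
    cross-module node pairs; the dendrogram is cut into ``n_clusters``.
    """
    modules = sorted({net.nodes[v]["module"] for v in net.nodes})
    if len(modules) < n_clusters:
        raise ValueError(f"{len(modules)} modules < n_clusters={n_clusters}")
    members = {m: [v for v in tom.index if net.nodes[v]["module"] == m] for m in modules}
    M = len(modules)
    D = np.zeros((M, M))
    tom_values = tom.to_numpy()
    pos = {v: i for i, v in enumerate(tom.index)}
    for i in range(M):
        for j in range(i + 1, M):
            ii = [pos[v] for v in members[modules[i]]]
            jj = [pos[v] for v in members[modules[j]]]
            block = 1.0 - tom_values[np.ix_(ii, jj)]
            D[i, j] = D[j, i] = float(block.mean())
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    label_series = pd.Series(labels, index=pd.Index(modules, name="module"), name="cluster")
    cluster_members: dict[int, list[str]] = {}
    for m, lab in label_series.items():
        cluster_members.setdefault(int(lab), []).append(m)
    return ModuleClustering(
        dissimilarity=pd.DataFrame(D, index=modules, columns=modules),
        linkage_matrix=Z,
        labels=label_series,
        cluster_members=cluster_members,
    )


# ---------------------------------------------------------------------------
# export


def export_network(net: nx.Graph, stats: ConnectivityStats, outdir) -> None:
    """Edge list and node table as TSV (GraphML-compatible attribute names)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        [(u, v, d["jaccard"]) for u, v, d in net.edges(data=True)],
        columns=["term1", "term2", "jaccard"],
    )
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    node_table = stats.node_table.copy()
    node_table["p"] = [net.nodes[v]["p"] for v in node_table["node"]]
    node_table[["node", "module", "p", "degree", "Ci"]].to_csv(
        out / "network_nodes.tsv", sep="\t", index=False
    )
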