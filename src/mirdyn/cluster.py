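"""Graph-based functional clustering of scaled derivative curves.

Genes are linked in a mutual k-nearest-neighbour graph under the
cosine-normalized first-derivative inner-product similarity and grouped
by seeded modularity (Louvain) community detection.  Communities smaller
than a minimum size dissolve into a background "cluster 0" of otherwise
unclustered genes.  Per-cluster seed enrichment is tested against
UTR-length-matched subsamples of the background cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .fda import CurveSet, cosine_similarity
from .targets import GeneAnnotation

__all__ = [
    "build_similarity_graph",
    "cluster_graph",
    "ClusterResult",
    "cluster_seed_enrichment",
    "cluster_set_enrichment",
]


def build_similarity_graph(curves: CurveSet, k_graph: int = 20,
                           deriv_order: int = 1, window=None) -> nx.Graph:
    """Mutual k-NN graph under derivative-cosine similarity.

    Nodes are gene ids; an edge exists iff each gene is among the other's
    k most similar neighbours and the similarity is positive.  Edge
    weight = similarity.  Curves are expected RMS-scaled upstream.
    """
    n = len(curves)
    if n < k_graph + 1:
        raise ValueError(f"need >= k_graph+1={k_graph + 1} curves, got {n}")
    S = cosine_similarity(curves, deriv_order=deriv_order, window=window)
    if not np.all(np.isfinite(S)):
        i, j = np.argwhere(~np.isfinite(S))[0]
        raise ValueError(f"non-finite similarity between "
                         f"{curves.gene_ids[i]} and {curves.gene_ids[j]}")
    np.fill_diagonal(S, -np.inf)
    # top-k neighbour sets per gene (ties broken by index for determinism)
    order = np.argsort(-S, axis=1, kind="stable")[:, :k_graph]
    neigh = [set(row) for row in order]
    G = nx.Graph()
    G.add_nodes_from(sorted(curves.gene_ids))
    for i in range(n):
        for j in order[i]:
            if j > i and i in neigh[j] and S[i, j] > 0:
                G.add_edge(curves.gene_ids[i], curves.gene_ids[j],
                           weight=float(S[i, j]))
    return G


@dataclass
class ClusterResult:
    assignments: pd.Series               # gene -> cluster id (0=background)
    params: dict = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])


def cluster_graph(graph: nx.Graph, min_size: int = 10,
                  resolution: float = 1.0, rng_seed: int = 0,
                  all_genes=None) -> ClusterResult:
    """Seeded Louvain communities; small ones dissolve into cluster 0.

    Non-background ids are 1..K in decreasing size order (ties by
    smallest member id).  ``all_genes`` may extend the partition to genes
    absent from the graph (assigned 0).
    """
    genes = sorted(all_genes) if all_genes is not None \
        else sorted(graph.nodes)
    assign = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    if graph.number_of_nodes():
        # canonical node order for order-invariant, seeded detection
        H = nx.Graph()
        H.add_nodes_from(sorted(graph.nodes))
        H.add_edges_from(sorted((min(u, v), max(u, v), d)
                                for u, v, d in graph.edges(data=True)))
        comms = nx.community.louvain_communities(
            H, weight="weight", resolution=resolution, seed=rng_seed)
        kept = sorted((c for c in comms if len(c) >= min_size),
                      key=lambda c: (-len(c), min(c)))
        for cid, comm in enumerate(kept, start=1):
            assign.loc[sorted(comm)] = cid
    return ClusterResult(assign, {
        "min_size": min_size, "resolution": resolution,
        "rng_seed": rng_seed})


def cluster_seed_enrichment(cluster_genes, annotations: GeneAnnotation,
                            background_genes, n_reps: int = 10,
                            n_bins: int = 5, region: str = "utr3",
                            rng_seed: int = 0) -> tuple[float, float]:
    """Seed-carrier enrichment of a cluster vs UTR-length-matched
    background subsamples.

    ratio = cluster carrier fraction / mean carrier fraction over
    ``n_reps`` background subsamples of the same size drawn within UTR
    length-quantile bins (nearest populated bin as fallback).  Returns
    (ratio, sd over repetitions).
    """
    cluster = [g for g in cluster_genes]
    background = [g for g in background_genes if g not in set(cluster)]
    if len(background) <= len(cluster):
        raise ValueError("background must be larger than the cluster")
    carriers = annotations.carriers(
        regions=("utr3",) if region == "utr3" else ("utr3", "cds"))
    lens = annotations.table["utr3_len"]
    cl_frac = float(carriers.reindex(cluster).fillna(False).mean())
    if cl_frac == 0:
        return 0.0, 0.0

    bg_lens = lens.reindex(background).to_numpy(float)
    edges = np.quantile(bg_lens, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bg_bins = np.searchsorted(edges, bg_lens, side="right") - 1
    cl_bins = np.searchsorted(
        edges, lens.reindex(cluster).to_numpy(float), side="right") - 1
    by_bin = {b: np.flatnonzero(bg_bins == b) for b in range(n_bins)}

    rng = np.random.default_rng(rng_seed)
    fracs = []
    for _ in range(n_reps):
        picked = []
        for b in cl_bins:
            pool = by_bin.get(int(b))
            if pool is None or not len(pool):
                near = min((bb for bb in by_bin if len(by_bin[bb])),
                           key=lambda bb: abs(bb - b))
                warnings.warn(f"length bin {b} empty in background; "
                              f"using bin {near}")
                pool = by_bin[near]
            picked.append(background[int(rng.choice(pool))])
        fracs.append(float(carriers.reindex(picked).fillna(False).mean()))
    fracs = np.asarray(fracs)
    mean_bg = fracs.mean()
    ratio = cl_frac / mean_bg if mean_bg > 0 else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = float(np.std(np.where(fracs > 0, cl_frac / fracs, np.nan),
                          ddof=1)) if n_reps > 1 else 0.0
    return float(ratio), sd


def cluster_set_enrichment(cluster_genes, gene_sets: dict, universe
                           ) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in the
    cluster, BH-adjusted within the cluster."""
    universe = set(universe)
    cluster = set(cluster_genes) & universe
    if not cluster <= universe:
        raise ValueError("universe must contain the cluster")
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & universe
        if not m:
            continue
        k = len(cluster & m)
        # P(X >= k) drawing |cluster| from universe with |m| successes
        p = stats.hypergeom.sf(k - 1, len(universe), len(m), len(cluster))
        rows.append({"set": name, "n_overlap": k, "n_set": len(m),
                     "p_value": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = stats.false_discovery_control(df["p_value"])
    return df
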