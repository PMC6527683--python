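"""Cell-specific interactomes, high-PRE subnetworks and their permutation null.

The connectivity test asks whether the genes scoring high for predicted
regulatory effect in one cell type encode proteins that interact more than
expected by chance. The observed subnetwork is the subgraph of the
cell-specific interactome induced by the selected genes; its total edge
count, largest-connected-component (LCC) size and LCC edge count are
compared against the same metrics of node sets of identical size drawn
uniformly at random from the same interactome. Significance is the add-one
empirical p-value, p = (#null >= observed + 1) / (reps + 1), which can never
be exactly zero at finite replicates.

Subnetworks whose LCC has 15 or fewer nodes are flagged ineligible: very
small components are dominated by noise. A degree-binned sampler is
available behind a flag for robustness checks; the default null is plain
uniform node sampling.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import pre_scoring

logger = logging.getLogger(__name__)

DEFAULT_MIN_LCC_NODES = 15


@dataclass
class NetworkMetrics:
    """Connectivity metrics of one thresholded subnetwork.

    ``p_*`` fields and null summaries are filled only after a permutation
    test; ``eligible`` is False when the LCC has <= ``min_lcc_nodes`` nodes.
    """

    bucket: str | None = None
    n_selected: int = 0
    n_nodes: int = 0
    n_edges: int = 0
    lcc_nodes: int = 0
    lcc_edges: int = 0
    eligible: bool = False
    reps: int | None = None
    seed: int | None = None
    p_edges: float | None = None
    p_lcc_nodes: float | None = None
    p_lcc_edges: float | None = None
    null_mean_edges: float | None = None
    null_mean_lcc_nodes: float | None = None
    null_mean_lcc_edges: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def filter_interactome(ppi: nx.Graph, expressed_genes: Iterable[str], bucket: str) -> nx.Graph:
    """Restrict the global interactome to interactions realized by gene
    products expressed in the given cell bucket (induced subgraph)."""
    expressed = set(expressed_genes)
    if not expressed:
        raise ValueError(f"filter_interactome({bucket}): empty expressed gene set")
    nodes = expressed & set(ppi.nodes)
    if not nodes:
        raise ValueError(
            f"filter_interactome({bucket}): expressed genes share no nodes with the interactome"
        )
    sub = ppi.subgraph(nodes).copy()
    sub.graph["bucket"] = bucket
    logger.info(
        "filter_interactome(%s): %d/%d nodes, %d edges retained",
        bucket,
        sub.number_of_nodes(),
        ppi.number_of_nodes(),
        sub.number_of_edges(),
    )
    return sub


def largest_connected_component(graph: nx.Graph) -> set:
    """Node set of the LCC. Ties on node count break by more edges, then by
    the lexicographically smallest sorted node tuple, so results are
    deterministic across platforms."""
    if graph.number_of_nodes() == 0:
        return set()
    components = [set(c) for c in nx.connected_components(graph)]
    def key(c):
        return (-len(c), -graph.subgraph(c).number_of_edges(), tuple(sorted(map(str, c))))
    return min(components, key=key)


def extract_subnetwork(
    interactome: nx.Graph,
    selected_genes: Iterable[str],
    min_lcc_nodes: int = DEFAULT_MIN_LCC_NODES,
    filter_on: str = "lcc",
) -> tuple[nx.Graph, NetworkMetrics]:
    """Induced subgraph of the selected genes plus its observed metrics.

    ``filter_on`` applies the >``min_lcc_nodes`` eligibility rule to the LCC
    (default) or to the whole subnetwork (``"subnetwork"``).
    """
    selected = set(selected_genes)
    sub = interactome.subgraph(selected & set(interactome.nodes)).copy()
    lcc = largest_connected_component(sub)
    lcc_edges = sub.subgraph(lcc).number_of_edges()
    size_for_filter = sub.number_of_nodes() if filter_on == "subnetwork" else len(lcc)
    metrics = NetworkMetrics(
        bucket=interactome.graph.get("bucket"),
        n_selected=len(selected),
        n_nodes=sub.number_of_nodes(),
        n_edges=sub.number_of_edges(),
        lcc_nodes=len(lcc),
        lcc_edges=lcc_edges,
        eligible=size_for_filter > min_lcc_nodes,
    )
    return sub, metrics


# ---------------------------------------------------------------------------
# Null model


def _adjacency_sets(graph: nx.Graph) -> tuple[list, dict]:
    nodes = sorted(graph.nodes, key=str)
    adj = {v: set(graph[v]) for v in nodes}
    return nodes, adj


def _induced_metrics(members: set, adj: Mapping) -> tuple[int, int, int]:
    """(edges, lcc_nodes, lcc_edges) of the induced subgraph, via neighbor-set
    intersections and BFS; avoids per-replicate graph construction."""
    n_edges = 0
    inner = {}
    for v in members:
        nb = adj[v] & members
        inner[v] = nb
        n_edges += len(nb)
    n_edges //= 2
    best_nodes, best_edges = 0, 0
    unseen = set(members)
    while unseen:
        root = unseen.pop()
        comp_nodes, comp_deg = 1, len(inner[root])
        queue = deque(inner[root] & unseen)
        unseen -= inner[root]
        while queue:
            v = queue.popleft()
            comp_nodes += 1
            comp_deg += len(inner[v])
            fresh = inner[v] & unseen
            queue.extend(fresh)
            unseen -= fresh
        comp_edges = comp_deg // 2
        if (comp_nodes, comp_edges) > (best_nodes, best_edges):
            best_nodes, best_edges = comp_nodes, comp_edges
    return n_edges, best_nodes, best_edges


def _dense_metrics(sub: np.ndarray) -> tuple[int, int, int]:
    """(edges, lcc_nodes, lcc_edges) from a boolean induced adjacency matrix,
    via vectorized breadth-first sweeps."""
    k = sub.shape[0]
    deg = sub.sum(axis=1)
    n_edges = int(deg.sum()) // 2
    unvisited = np.ones(k, dtype=bool)
    best = (0, 0)
    while unvisited.any():
        start = int(np.argmax(unvisited))
        comp = np.zeros(k, dtype=bool)
        comp[start] = True
        frontier = comp.copy()
        while True:
            new = sub[frontier].any(axis=0) & ~comp
            if not new.any():
                break
            comp |= new
            frontier = new
        unvisited &= ~comp
        cand = (int(comp.sum()), int(deg[comp].sum()) // 2)
        if cand > best:
            best = cand
    return n_edges, best[0], best[1]


# dense adjacency is only worth materializing for modest graphs
_DENSE_NODE_LIMIT = 4000


def sample_null(
    interactome: nx.Graph,
    k: int,
    reps: int,
    seed: int | np.random.Generator = 0,
    degree_reference: Iterable[str] | None = None,
    degree_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Metrics of ``reps`` node sets of size ``k`` sampled uniformly at random
    without replacement from the interactome.

    Returns arrays ``edges``, ``lcc_nodes``, ``lcc_edges`` of length ``reps``.
    With ``degree_reference`` given, sampling instead preserves the reference
    set's degree-decile composition (robustness-check sampler, not the
    default null).
    """
    nodes, adj = _adjacency_sets(interactome)
    n = len(nodes)
    if k > n:
        raise ValueError(f"sample_null: k={k} exceeds interactome size {n}")
    if reps < 1:
        raise ValueError("sample_null: reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bins = None
    if degree_reference is not None:
        degrees = np.array([len(adj[v]) for v in nodes])
        edges_q = np.quantile(degrees, np.linspace(0, 1, degree_bins + 1)[1:-1])
        bin_of = np.searchsorted(edges_q, degrees, side="right")
        by_bin = {b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)}
        node_index = {v: i for i, v in enumerate(nodes)}
        ref_idx = [node_index[v] for v in degree_reference if v in node_index]
        ref_bins, ref_counts = np.unique(bin_of[ref_idx], return_counts=True)
        bins = [(by_bin[b], int(c)) for b, c in zip(ref_bins, ref_counts)]

    edges = np.empty(reps, dtype=np.int64)
    lcc_n = np.empty(reps, dtype=np.int64)
    lcc_e = np.empty(reps, dtype=np.int64)
    node_arr = np.array(nodes, dtype=object)
    dense = None
    if n <= _DENSE_NODE_LIMIT:
        index = {v: i for i, v in enumerate(nodes)}
        dense = np.zeros((n, n), dtype=bool)
        for v, neighbors in adj.items():
            iv = index[v]
            for w in neighbors:
                dense[iv, index[w]] = True
    for i in range(reps):
        if bins is None:
            idx = rng.choice(n, size=k, replace=False)
        else:
            idx = np.concatenate(
                [rng.choice(pool, size=c, replace=False) for pool, c in bins]
            )
        if dense is not None:
            edges[i], lcc_n[i], lcc_e[i] = _dense_metrics(dense[np.ix_(idx, idx)])
        else:
            members = set(node_arr[idx])
            edges[i], lcc_n[i], lcc_e[i] = _induced_metrics(members, adj)
    return {"edges": edges, "lcc_nodes": lcc_n, "lcc_edges": lcc_e}


def empirical_p(observed: float, null: Sequence[float]) -> float:
    """Add-one empirical p-value: (#null >= observed + 1) / (reps + 1)."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("empirical_p: empty null distribution")
    return float((int(np.sum(null >= observed)) + 1) / (null.size + 1))


def enrichment_test(
    interactome: nx.Graph,
    selected_genes: Iterable[str],
    reps: int = 10_000,
    seed: int = 0,
    min_lcc_nodes: int = DEFAULT_MIN_LCC_NODES,
    degree_matched: bool = False,
    null_graph: nx.Graph | None = None,
) -> NetworkMetrics:
    """Full connectivity test of a selected gene set against the random-node
    null. ``null_graph`` overrides the graph nodes are sampled from (e.g. the
    unfiltered global PPI); default is the cell-specific interactome itself."""
    sub, metrics = extract_subnetwork(interactome, selected_genes, min_lcc_nodes)
    metrics.reps = reps
    metrics.seed = seed
    source = null_graph if null_graph is not None else interactome
    k = sub.number_of_nodes()
    if k == 0:
        logger.warning("enrichment_test: empty selection; no null sampled")
        return metrics
    null = sample_null(
        source,
        k,
        reps,
        seed=seed,
        degree_reference=(set(sub.nodes) if degree_matched else None),
    )
    metrics.p_edges = empirical_p(metrics.n_edges, null["edges"])
    metrics.p_lcc_nodes = empirical_p(metrics.lcc_nodes, null["lcc_nodes"])
    metrics.p_lcc_edges = empirical_p(metrics.lcc_edges, null["lcc_edges"])
    metrics.null_mean_edges = float(null["edges"].mean())
    metrics.null_mean_lcc_nodes = float(null["lcc_nodes"].mean())
    metrics.null_mean_lcc_edges = float(null["lcc_edges"].mean())
    return metrics


# ---------------------------------------------------------------------------
# Sensitivity grid


def sensitivity_grid(
    effects_by_tier: Mapping[str, pd.DataFrame | None],
    proxies: pd.DataFrame | None,
    catalogue: pd.DataFrame,
    interactomes: Mapping[str, nx.Graph],
    tiers: Sequence[str] = ("GW", "SR", "NR"),
    r2_values: Sequence[float] = (0.1, 0.5, 0.8),
    q_values: Sequence[float] = (10, 25, 50),
    eqtl: pd.DataFrame | None = None,
    reps: int = 10_000,
    seed: int = 0,
    min_lcc_nodes: int = DEFAULT_MIN_LCC_NODES,
) -> pd.DataFrame:
    """Connectivity metrics over the full SNP-tier x LD-threshold x
    PRE-percentile grid, one row per (tier, r2, q, bucket).

    A tier with no effect list yields rows with ``status='absent'`` and the
    run continues. Each cell of the grid gets its own derived seed so rows
    are individually reproducible.
    """
    from . import catalog_io

    totals = pre_scoring.bucket_totals(catalogue, eqtl=eqtl)
    rows = []
    for ti, tier in enumerate(tiers):
        effects = effects_by_tier.get(tier)
        for ri, r2 in enumerate(r2_values):
            if effects is not None:
                region_snps = catalog_io.expand_ld(effects, proxies, r2_min=r2)
                pre = pre_scoring.compute_pre(region_snps, catalogue, totals, eqtl=eqtl)
                gene_pre = pre_scoring.aggregate_gene_pre(pre)
            for qi, q in enumerate(q_values):
                for bi, (bucket, graph) in enumerate(sorted(interactomes.items())):
                    base = {"tier": tier, "r2_min": r2, "pre_q": q, "bucket": bucket}
                    if effects is None:
                        rows.append({**base, "status": "absent"})
                        continue
                    selected = pre_scoring.select_high_pre(gene_pre, bucket, q)
                    cell_seed = seed + 1000 * ti + 100 * ri + 10 * qi + bi
                    metrics = enrichment_test(
                        graph,
                        selected,
                        reps=reps,
                        seed=cell_seed,
                        min_lcc_nodes=min_lcc_nodes,
                    )
                    record = metrics.to_dict()
                    record.pop("bucket", None)
                    rows.append({**base, "status": "ok", **record})
    return pd.DataFrame(rows)
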