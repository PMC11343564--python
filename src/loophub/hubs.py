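"""Promoter-hub network reconstruction from binary loops.

Anchors become nodes (identity = exact coordinates), loops become edges
weighted by PET count, and clusters are the connected components of the
resulting graph.  Cluster statistics count promoter- and enhancer-class
nodes per component; over-representation of hub gene lists in named gene
sets uses the upper-tail hypergeometric test with Benjamini-Hochberg
correction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .annotate import AnnotatedLoop
from .intervals import GenomicInterval

log = logging.getLogger(__name__)


def _node_key(anchor: GenomicInterval) -> tuple[str, int, int]:
    return (anchor.chrom, anchor.start, anchor.end)


def build_graph(annotated: Sequence[AnnotatedLoop]) -> nx.Graph:
    """Anchors-as-nodes, loops-as-edges graph.

    Nodes are deduplicated by exact anchor coordinates and carry the
    anchor's functional class; parallel loops between the same anchor pair
    are merged into one edge with summed PET weight.
    """
    g = nx.Graph()
    merged = 0
    for al in annotated:
        ka = _node_key(al.loop.anchor_a)
        kb = _node_key(al.loop.anchor_b)
        for key, cls in ((ka, al.class_a), (kb, al.class_b)):
            if key not in g:
                g.add_node(key, cls=cls)
        if g.has_edge(ka, kb):
            g[ka][kb]["weight"] += al.loop.pet_count
            g[ka][kb]["n_loops"] += 1
            merged += 1
        else:
            g.add_edge(ka, kb, weight=al.loop.pet_count, n_loops=1)
    if merged:
        log.info("build_graph: merged %d parallel loops into existing edges", merged)
    log.info("build_graph: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


@dataclass
class ClusterStats:
    cluster_id: int
    n_nodes: int
    n_promoters: int
    n_enhancers: int
    total_pets: int
    nodes: list[tuple[str, int, int]]
    genes: list[str] = field(default_factory=list)


def clusters(
    graph: nx.Graph,
    gene_lookup: Optional[Mapping[tuple[str, int, int], str]] = None,
) -> list[ClusterStats]:
    """Connected components as cluster statistics, largest first.

    ``gene_lookup`` optionally maps a promoter node key to its gene id, to
    populate per-cluster gene lists.
    """
    out = []
    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    for cid, comp in enumerate(components):
        nodes = sorted(comp)
        classes = [graph.nodes[n]["cls"] for n in nodes]
        sub = graph.subgraph(comp)
        genes = []
        if gene_lookup is not None:
            genes = sorted({gene_lookup[n] for n in nodes if n in gene_lookup})
        out.append(
            ClusterStats(
                cluster_id=cid,
                n_nodes=len(nodes),
                n_promoters=sum(c == "promoter" for c in classes),
                n_enhancers=sum(c == "enhancer" for c in classes),
                total_pets=int(sum(d["weight"] for _, _, d in sub.edges(data=True))),
                nodes=nodes,
                genes=genes,
            )
        )
    return out


def assign_genes_to_promoter_nodes(
    graph: nx.Graph,
    genes: Sequence,
    tss_halfwidth: int = 500,
) -> dict[tuple[str, int, int], str]:
    """Map each promoter-class node to the gene whose TSS window contains
    the anchor midpoint; ties broken by nearest TSS."""
    lookup: dict[tuple[str, int, int], str] = {}
    by_chrom: dict[str, list] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for node, data in graph.nodes(data=True):
        if data.get("cls") != "promoter":
            continue
        chrom, start, end = node
        mid = (start + end) // 2
        candidates = [
            g for g in by_chrom.get(chrom, ())
            if abs(mid - g.tss) <= tss_halfwidth
        ]
        if candidates:
            best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
            lookup[node] = best.gene_id
    return lookup


def compare_cluster_sizes(
    sizes_a: Sequence[int], sizes_b: Sequence[int]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for node counts per cluster.

    Exact null distribution for small samples (<= 20 total, no ties across
    groups required by scipy's exact mode); normal approximation with tie
    correction otherwise.
    """
    if len(sizes_a) < 3 or len(sizes_b) < 3:
        raise ValueError(
            "need >= 3 clusters per group for a rank-sum comparison; "
            "report descriptive statistics instead"
        )
    method = "exact" if len(sizes_a) + len(sizes_b) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(sizes_a, sizes_b, alternative="two-sided", method=method)
    return float(res.pvalue)


def merge_duplicate_genes(
    gene_pets: Sequence[tuple[str, float]]
) -> dict[str, float]:
    """Merge duplicate gene symbols, keeping the median of their PET counts."""
    grouped: dict[str, list[float]] = {}
    for name, pets in gene_pets:
        grouped.setdefault(name, []).append(pets)
    return {name: float(median(v)) for name, v in grouped.items()}


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    n_hub: int
    universe: int
    p_value: float
    q_value: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.q_value <= 0.05


def hub_gene_enrichment(
    hub_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of hub genes in each gene set.

    For a universe of N genes containing K set members, drawing n hub genes
    with k in the set: p = P(X >= k) under Hypergeometric(N, K, n).
    Benjamini-Hochberg q-values are computed across the tested sets; hub
    genes absent from the universe are logged and dropped.
    """
    universe_set = set(universe)
    hub = set(hub_genes)
    dropped = hub - universe_set
    if dropped:
        log.warning(
            "hub_gene_enrichment: %d hub genes absent from universe, dropped: %s",
            len(dropped), sorted(dropped)[:10],
        )
    hub &= universe_set
    n_universe = len(universe_set)
    n_hub = len(hub)
    results = []
    for name, members in gene_sets.items():
        members_set = set(members) & universe_set
        k = len(hub & members_set)
        big_k = len(members_set)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_hub))
        results.append(
            EnrichmentResult(name, k, big_k, n_hub, n_universe, min(1.0, p))
        )
    _benjamini_hochberg(results)
    for r in results:
        r.q_value = min(1.0, r.q_value)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def _benjamini_hochberg(results: list[EnrichmentResult]) -> None:
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_value)
    qs = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        q = results[i].p_value * m / rank_from_end
        prev = min(prev, q)
        qs[i] = prev
    for i, r in enumerate(results):
        r.q_value = qs[i]


def to_sif(graph: nx.Graph) -> list[str]:
    """Simple-interaction-format lines (nodeA  pp  nodeB) for export."""
    lines = []
    for a, b in graph.edges():
        na = f"{a[0]}:{a[1]}-{a[2]}"
        nb = f"{b[0]}:{b[1]}-{b[2]}"
        lines.append(f"{na}\tpp\t{nb}")
    return lines
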