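"""Cluster-and-filter post-processing of enriched gene sets.

Annotation collections are highly redundant (nested and overlapping
terms), so independent per-set tests return clusters of near-duplicate
hits.  The remedy here is computed on the collection itself, before any
enrichment: build a gene-set graph whose edges carry Jaccard similarity
above a threshold, partition it into modules by iterated weighted-
modularity maximization, and afterwards report only the most significant
(marker) set of each module, listing the remaining enriched sets beneath
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from networkx.algorithms.community import louvain_communities, modularity

from .enrichment import EnrichmentResult
from .weighting import GeneSet, GeneSetCollection

__all__ = [
    "jaccard",
    "build_geneset_graph",
    "ModulePartition",
    "partition_modules",
    "ModuleReport",
    "FilteredResults",
    "cluster_and_filter",
]


def jaccard(A: GeneSet, B: GeneSet) -> float:
    """Jaccard similarity |A∩B| / |A∪B| of two gene sets' full member sets."""
    if not A.members or not B.members:
        raise ValueError("Jaccard similarity is undefined for empty sets")
    inter = len(A.members & B.members)
    union = len(A.members | B.members)
    return inter / union


def build_geneset_graph(
    collection: GeneSetCollection, threshold: float = 0.15
) -> nx.Graph:
    """Gene-set relatedness graph.

    Nodes are set names (inserted in sorted order so downstream
    partitioning is independent of collection order); edges connect pairs
    whose Jaccard similarity is strictly greater than ``threshold`` and
    carry that similarity as weight.
    """
    if len(collection) < 1:
        raise ValueError("collection must contain at least one gene set")
    graph = nx.Graph()
    ordered = sorted(collection, key=lambda s: s.name)
    graph.add_nodes_from(s.name for s in ordered)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            sim = jaccard(a, b)
            if sim > threshold:
                graph.add_edge(a.name, b.name, weight=sim)
    return graph


@dataclass
class ModulePartition:
    """Assignment of gene sets to redundancy modules (ids contiguous from 1)."""

    module_of: dict[str, int]
    members: dict[int, list[str]]

    @property
    def n_modules(self) -> int:
        return len(self.members)


def partition_modules(graph: nx.Graph, seed: int = 0) -> ModulePartition:
    """Partition the gene-set graph into modules.

    Iterated weighted-modularity maximization (Louvain passes repeated
    until the modularity gain drops below 1e-7); isolated nodes become
    singleton modules.  Deterministic given ``seed``.  Module ids are
    renumbered contiguously from 1 in order of each module's
    lexicographically smallest member.
    """
    if graph.number_of_edges() == 0:
        communities = [{n} for n in graph.nodes]
    else:
        communities = louvain_communities(
            graph, weight="weight", threshold=1e-7, seed=seed
        )
    ordered = sorted(communities, key=lambda c: min(c))
    module_of: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    for mid, community in enumerate(ordered, start=1):
        members[mid] = sorted(community)
        for name in community:
            module_of[name] = mid
    return ModulePartition(module_of=module_of, members=members)


def partition_modularity(graph: nx.Graph, partition: ModulePartition) -> float:
    """Weighted modularity of a partition on the gene-set graph."""
    return modularity(
        graph, [set(v) for v in partition.members.values()], weight="weight"
    )


@dataclass
class ModuleReport:
    """One redundancy module of the filtered results."""

    module_id: int
    marker: EnrichmentResult
    others: list[EnrichmentResult]


@dataclass
class FilteredResults:
    """Enriched gene sets reduced to one marker set per redundancy module."""

    modules: list[ModuleReport]
    significance: float

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def marker_names(self) -> list[str]:
        return [m.marker.set_name for m in self.modules]


def cluster_and_filter(
    results: list[EnrichmentResult],
    partition: ModulePartition,
    significance: float,
    *,
    pvalue_attr: str = "p_final",
) -> FilteredResults:
    """Reduce enriched results to one marker gene set per module.

    Keeps results whose ``pvalue_attr`` (raw final p by default; an
    adjusted p by configuration) is below ``significance``, groups them by
    their pre-computed module, and within each module selects the
    minimum-p member as the marker (ties broken by name).  Modules are
    emitted by ascending marker p; the remaining enriched members are
    listed beneath their marker.
    """
    missing = [r.set_name for r in results if r.set_name not in partition.module_of]
    if missing:
        raise KeyError(f"results not present in the partition: {sorted(missing)}")
    enriched = [r for r in results if getattr(r, pvalue_attr) < significance]
    groups: dict[int, list[EnrichmentResult]] = {}
    for r in enriched:
        groups.setdefault(partition.module_of[r.set_name], []).append(r)

    modules: list[ModuleReport] = []
    for mid, group in groups.items():
        group = sorted(group, key=lambda r: (getattr(r, pvalue_attr), r.set_name))
        modules.append(ModuleReport(module_id=mid, marker=group[0], others=group[1:]))
    modules.sort(key=lambda mod: (getattr(mod.marker, pvalue_attr), mod.marker.set_name))
    return FilteredResults(modules=modules, significance=significance)
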