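"""Functional association network: data model, degrees, efficiency, perturbation.

The background network is an undirected graph over gene identifiers whose
edges carry confidence weights in ``(0, 1]`` (unweighted input is stored as
weight exactly 1).  All downstream weighting is driven by two quantities
computed here: weighted degrees and the background network efficiency, the
mean reciprocal shortest-path length over ordered gene pairs — a density
measure in ``[0, 1]`` that equals 1 only on complete graphs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "net_degree",
    "network_efficiency",
    "remove_edges",
    "rewire_edges",
]


class GeneNetwork:
    """Undirected, weighted gene network.

    Parameters
    ----------
    genes
        Ordered collection of unique gene identifiers.  May include genes
        that have no edges (isolated genes).
    edges
        Iterable of ``(gene_a, gene_b, weight)`` triples.  Self-loops are
        dropped (with a logged count); duplicate unordered pairs keep the
        maximum weight (with a logged warning).  Weights must lie in
        ``(0, 1]``.
    """

    def __init__(
        self,
        genes: Sequence[str],
        edges: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        self._genes: tuple[str, ...] = tuple(genes)
        if len(set(self._genes)) != len(self._genes):
            raise ValueError("gene identifiers must be unique")
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._genes)}

        seen: dict[tuple[int, int], float] = {}
        n_self = 0
        n_dup = 0
        for a, b, w in edges:
            try:
                ia, ib = self._index[a], self._index[b]
            except KeyError as exc:
                raise KeyError(f"edge endpoint {exc.args[0]!r} is not a network gene")
            if ia == ib:
                n_self += 1
                continue
            w = float(w)
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"edge weight for ({a!r}, {b!r}) must be in (0, 1], got {w}"
                )
            key = (ia, ib) if ia < ib else (ib, ia)
            if key in seen:
                n_dup += 1
                seen[key] = max(seen[key], w)
            else:
                seen[key] = w
        if n_self:
            logger.info("dropped %d self-loop edge(s)", n_self)
        if n_dup:
            logger.warning(
                "collapsed %d duplicate edge pair(s), keeping the maximum weight", n_dup
            )

        m = len(self._genes)
        if seen:
            ij = np.array(sorted(seen), dtype=np.int64)
            self._ei = ij[:, 0]
            self._ej = ij[:, 1]
            self._w = np.array([seen[tuple(p)] for p in ij], dtype=float)
        else:
            self._ei = np.empty(0, dtype=np.int64)
            self._ej = np.empty(0, dtype=np.int64)
            self._w = np.empty(0, dtype=float)
        data = np.concatenate([self._w, self._w])
        rows = np.concatenate([self._ei, self._ej])
        cols = np.concatenate([self._ej, self._ei])
        self._adj: sp.csr_matrix = sp.csr_matrix(
            (data, (rows, cols)), shape=(m, m)
        )
        self._degrees: np.ndarray = np.asarray(self._adj.sum(axis=1)).ravel()

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    @property
    def m(self) -> int:
        """Number of genes in the network."""
        return len(self._genes)

    @property
    def n_edges(self) -> int:
        return len(self._w)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse adjacency with edge weights; zero diagonal."""
        return self._adj

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree vector, aligned with :attr:`genes`."""
        return self._degrees

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Edges as ``(gene_a, gene_b, weight)`` with a < b by index order."""
        return [
            (self._genes[i], self._genes[j], float(w))
            for i, j, w in zip(self._ei, self._ej, self._w)
        ]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"unknown gene identifier: {gene!r}") from None

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.index(g) for g in genes], dtype=np.int64)

    def weight(self, a: str, b: str) -> float:
        """Edge weight between two genes (0 if no edge). Symmetric."""
        return float(self._adj[self.index(a), self.index(b)])

    def __repr__(self) -> str:
        return f"GeneNetwork(m={self.m}, edges={self.n_edges})"


def net_degree(net: GeneNetwork, gene: str) -> float:
    """Weighted degree of ``gene`` in the background network.

    Sum of edge weights over the gene's neighbors; 0 for isolated genes.
    """
    return float(net.degrees[net.index(gene)])


def network_efficiency(net: GeneNetwork) -> float:
    """Background network efficiency (bgNE).

    Mean of ``1 / SP_ij`` over all ordered gene pairs ``i != j``, where
    ``SP_ij`` is the hop-count shortest path on the binarized edge set.
    Disconnected pairs contribute 0.  Lies in ``[0, 1]``; equals 1 exactly
    on complete graphs, and grows with network density.
    """
    m = net.m
    if m < 2:
        raise ValueError(f"network efficiency requires at least 2 genes, got {m}")
    sp_len = shortest_path(net.adjacency, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp_len
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (m * (m - 1)))


def remove_edges(net: GeneNetwork, fraction: float, seed: int) -> GeneNetwork:
    """Delete ``floor(fraction * |edges|)`` uniformly chosen edges.

    The gene roster is unchanged: genes left without edges become isolated.
    Deterministic given ``seed``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    edges = net.edge_list()
    n_drop = int(np.floor(fraction * len(edges)))
    keep = np.ones(len(edges), dtype=bool)
    if n_drop:
        keep[rng.choice(len(edges), size=n_drop, replace=False)] = False
    return GeneNetwork(net.genes, [e for e, k in zip(edges, keep) if k])


def rewire_edges(net: GeneNetwork, fraction: float, seed: int) -> GeneNetwork:
    """Randomly rewire a fraction of edges, emulating network noise.

    Each edge is independently selected with probability ``fraction``; one of
    its endpoints (chosen at random) is reassigned to a uniformly random
    gene.  Rewired edges keep their original weight; self-loops and duplicate
    pairs are resolved by redrawing the new endpoint.  Edge count and gene
    roster are preserved.  Deterministic given ``seed``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    m = net.m
    genes = net.genes
    edges = net.edge_list()
    idx_edges: list[tuple[int, int]] = [
        (net.index(a), net.index(b)) for a, b, _ in edges
    ]
    occupied = {(min(i, j), max(i, j)) for i, j in idx_edges}
    weights = [w for _, _, w in edges]

    new_edges: list[tuple[str, str, float]] = []
    for (i, j), w in zip(idx_edges, weights):
        key = (min(i, j), max(i, j))
        if rng.random() < fraction:
            moving_end = int(rng.integers(2))  # which endpoint is reassigned
            kept = j if moving_end == 0 else i
            occupied.discard(key)
            while True:
                cand = int(rng.integers(m))
                new_key = (min(kept, cand), max(kept, cand))
                if cand != kept and new_key not in occupied:
                    break
            occupied.add(new_key)
            i, j = kept, cand
        new_edges.append((genes[i], genes[j], w))
    return GeneNetwork(genes, new_edges)
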