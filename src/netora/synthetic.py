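"""Synthetic benchmark scenarios with known ground truth.

A planted-partition graph stands in for a curated functional association
network: genes are split into communities, intra-community edges appear
with probability ``within_prob`` and all others with ``edge_prob``
(``within_prob == edge_prob`` degenerates to Erdős–Rényi).  Gene sets are
drawn either as coherent network neighborhoods (a seed gene plus its
closest neighbors, emulating annotation terms that map onto dense network
regions) or as uniform gene draws (incoherent decoys).  Interesting gene
lists come in two modes: null (uniform draws, for calibration) and
planted (a fraction ``effect`` of the list drawn from the target set's
highest-contribution genes, so the signal includes both members and
strongly linked neighbors).

Every generator is deterministic given the scenario seed and names carry
the ground-truth labels needed to score detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .config import RunConfig
from .enrichment import InterestingGeneList, run_weighted_ora
from .network import GeneNetwork, network_efficiency
from .weighting import GeneSet, GeneSetCollection, contribution_profile

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "CalibrationReport",
    "simulate_network",
    "simulate_genesets",
    "simulate_gene_list",
    "null_calibration",
    "planted_scenario",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic benchmark condition.

    Defaults describe the calibration condition used throughout: a sparse
    500-gene Erdős–Rényi network (edge probability 0.02, about 10 expected
    partners per gene — the order of magnitude of a curated functional
    network's core), 50 gene sets of 10-50 genes, half coherent, and
    interesting lists of 30 genes, the scale of a typical hit list.
    """

    m: int = 500
    edge_prob: float = 0.02
    n_modules: int = 5
    within_prob: float = 0.02
    set_sizes: tuple[int, int] = (10, 50)
    n_sets: int = 50
    coherent_fraction: float = 0.5
    effect: float = 0.0
    n_list: int = 30
    weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_prob <= 1.0 and 0.0 <= self.within_prob <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.within_prob < self.edge_prob:
            raise ValueError("within_prob must be >= edge_prob")
        if not (0.0 <= self.coherent_fraction <= 1.0 and 0.0 <= self.effect <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        lo, hi = self.set_sizes
        if lo < 2 or hi < lo or hi > self.m:
            raise ValueError("set sizes must satisfy 2 <= lo <= hi <= m")
        if self.m < 2 or self.n_modules < 1 or self.n_sets < 1:
            raise ValueError("infeasible scenario parameters")
        if not (1 <= self.n_list <= self.m):
            raise ValueError("n_list must lie in [1, m]")


def planted_scenario(seed: int = 0) -> SyntheticScenario:
    """The planted-signal recovery condition.

    A 300-gene network with ten strong communities, 20 gene sets (ten
    coherent, one per community, so every set represents a distinct
    functional module), and a 60%-planted interesting list of 30 genes.
    """
    return SyntheticScenario(
        m=300,
        edge_prob=0.02,
        n_modules=10,
        within_prob=0.3,
        set_sizes=(10, 25),
        n_sets=20,
        coherent_fraction=0.5,
        effect=0.6,
        n_list=30,
        seed=seed,
    )


def _gene_names(m: int) -> list[str]:
    width = max(4, len(str(m - 1)))
    return [f"g{i:0{width}d}" for i in range(m)]


def community_labels(scenario: SyntheticScenario) -> np.ndarray:
    """Community index per gene (contiguous blocks, deterministic)."""
    return (np.arange(scenario.m) * scenario.n_modules) // scenario.m


def simulate_network(scenario: SyntheticScenario) -> GeneNetwork:
    """Planted-partition graph over ``scenario.m`` genes.

    Intra-community pairs get an edge with ``within_prob``, all others
    with ``edge_prob``; weights are 1, or Uniform(0.5, 1] when the
    scenario's ``weighted`` flag is set.
    """
    rng = np.random.default_rng(scenario.seed)
    m = scenario.m
    labels = community_labels(scenario)
    iu, ju = np.triu_indices(m, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, scenario.within_prob, scenario.edge_prob)
    present = rng.random(len(iu)) < p
    ei, ej = iu[present], ju[present]
    if scenario.weighted:
        w = 1.0 - rng.random(len(ei)) * 0.5  # Uniform(0.5, 1]
    else:
        w = np.ones(len(ei))
    genes = _gene_names(m)
    return GeneNetwork(genes, [(genes[i], genes[j], wi) for i, j, wi in zip(ei, ej, w)])


def _neighborhood_set(
    net: GeneNetwork, seed_idx: int, size: int, labels: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Seed gene plus nearest network neighbors, breadth-first, up to ``size``."""
    adj = net.adjacency
    chosen = [seed_idx]
    chosen_set = {seed_idx}
    frontier = [seed_idx]
    while len(chosen) < size and frontier:
        next_frontier: list[int] = []
        # neighbors of the frontier, strongest edges first, name-stable
        cand: dict[int, float] = {}
        for node in frontier:
            row = adj[node]
            for j, w in zip(row.indices, row.data):
                if j not in chosen_set:
                    cand[j] = max(cand.get(j, 0.0), float(w))
        for j in sorted(cand, key=lambda j: (-cand[j], j)):
            if len(chosen) >= size:
                break
            chosen.append(j)
            chosen_set.add(j)
            next_frontier.append(j)
        frontier = next_frontier
    if len(chosen) < size:
        # sparse corner: pad from the seed's community, then from the rest
        pool = [int(i) for i in np.flatnonzero(labels == labels[seed_idx]) if i not in chosen_set]
        pool += [i for i in range(net.m) if i not in chosen_set and labels[i] != labels[seed_idx]]
        for j in pool[: size - len(chosen)]:
            chosen.append(j)
            chosen_set.add(j)
    return chosen


def simulate_genesets(
    net: GeneNetwork, scenario: SyntheticScenario
) -> GeneSetCollection:
    """Gene-set collection with ground-truth labels in the set names.

    Coherent sets (named ``coh###_c<community>``) are network
    neighborhoods grown from a random seed gene; incoherent sets
    (``rand###``) are uniform draws.  Sizes are uniform over
    ``scenario.set_sizes``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    labels = community_labels(scenario)
    lo, hi = scenario.set_sizes
    if hi > net.m:
        raise ValueError("requested set size exceeds the network size")
    n_coh = int(round(scenario.coherent_fraction * scenario.n_sets))
    sizes = rng.integers(lo, hi + 1, size=scenario.n_sets)
    genes = net.genes

    sets: list[GeneSet] = []
    for idx in range(scenario.n_sets):
        size = int(sizes[idx])
        if idx < n_coh:
            community = idx % scenario.n_modules
            pool = np.flatnonzero(labels == community)
            seed_idx = int(rng.choice(pool))
            members_idx = _neighborhood_set(net, seed_idx, size, labels, rng)
            name = f"coh{idx:03d}_c{community}"
        else:
            members_idx = rng.choice(net.m, size=size, replace=False).tolist()
            name = f"rand{idx:03d}"
        sets.append(GeneSet(name=name, members=frozenset(genes[i] for i in members_idx)))
    return GeneSetCollection(sets)


def simulate_gene_list(
    net: GeneNetwork,
    target: Optional[GeneSet],
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> InterestingGeneList:
    """Interesting gene list, null or planted.

    Null mode (``target is None`` or ``effect == 0``): a uniform draw of
    ``n_list`` genes without replacement.  Planted mode:
    ``ceil(effect * n_list)`` genes sampled from the target set's top-G
    pool — the ``k`` network genes with the highest contribution score
    against the target, which mixes annotated members with strongly linked
    neighbors — and the remainder drawn uniformly from the other genes.
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    m = net.m
    if scenario.n_list > m:
        raise ValueError("n_list exceeds the network size")
    genes = np.array(net.genes)
    if target is None or scenario.effect == 0.0:
        picked = rng.choice(m, size=scenario.n_list, replace=False)
        return InterestingGeneList(genes[picked].tolist())

    bgNE = network_efficiency(net)
    profile = contribution_profile(net, target, bgNE)
    order = np.lexsort((genes, -profile.G))  # G descending, name ascending
    pool = order[: profile.k]
    n_eff = min(int(np.ceil(scenario.effect * scenario.n_list)), len(pool))
    planted = rng.choice(pool, size=n_eff, replace=False)
    rest_pool = np.setdiff1d(np.arange(m), planted)
    rest = rng.choice(rest_pool, size=scenario.n_list - n_eff, replace=False)
    picked = np.concatenate([planted, rest])
    return InterestingGeneList(genes[picked].tolist())


@dataclass
class CalibrationReport:
    """Frequency of random significance per gene set under null lists."""

    frequencies: dict[str, float]
    median_frequency: float
    alpha: float
    n_draws: int


def null_calibration(
    net: GeneNetwork,
    collection: GeneSetCollection,
    n_list: int,
    n_draws: int,
    alpha: float,
    seed: int,
    config: RunConfig | None = None,
) -> CalibrationReport:
    """Frequency-of-random-significance experiment.

    Draws ``n_draws`` uniformly random interesting lists, runs the full
    weighted pipeline on each, and records per gene set the fraction of
    lists for which it is declared significant (final p below ``alpha``).
    An unbiased method has frequencies scattered around ``alpha`` with
    median close to it.
    """
    if n_draws < 20:
        raise ValueError("calibration needs at least 20 draws")
    if config is None:
        config = RunConfig(permutations=200)
    scenario = SyntheticScenario(
        m=net.m, n_list=n_list, set_sizes=(2, 2), seed=seed
    )
    counts: dict[str, int] = {name: 0 for name in collection.names}
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_draws) % (2**31)
    for d in range(n_draws):
        lst = simulate_gene_list(net, None, scenario, seed=int(child_seeds[2 * d]))
        cfg = replace(config, seed=int(child_seeds[2 * d + 1]))
        for res in run_weighted_ora(net, collection, lst, cfg):
            if res.p_final < alpha:
                counts[res.set_name] += 1
    freqs = {name: counts[name] / n_draws for name in counts}
    return CalibrationReport(
        frequencies=freqs,
        median_frequency=float(np.median(list(freqs.values()))),
        alpha=alpha,
        n_draws=n_draws,
    )
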