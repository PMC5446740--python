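"""Planted-module benchmark generator.

Builds a connected random interactome, plants one connected ground-truth
module per disease (diseases in the same overlap group share a connected
core, so phenotypically similar diseases share proteins), carves a connected
seed out of each planted module, and derives the phenotypic similarity
matrix as the pairwise Jaccard similarity of the planted modules plus
optional truncated Gaussian noise.

With zero noise and seeds equal to the planted modules the objective is
exactly zero, so the generator gives the optimizer a recoverable target:
re-expanding the seeds back toward the planted modules is precisely the
move that minimizes the objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .annealer import ModuleState
from .network import ProteinNetwork, frontier, is_connected_in
from .similarity import PhenotypeSimilarityMatrix, jaccard

__all__ = ["SyntheticBenchmark", "generate_benchmark"]


@dataclass(frozen=True)
class SyntheticBenchmark:
    """A planted-module dataset: network, ground truth, seeds and the
    derived phenotypic similarity matrix."""

    network: ProteinNetwork
    planted: Mapping[str, frozenset[str]]
    seeds: Mapping[str, frozenset[str]]
    phen: PhenotypeSimilarityMatrix
    noise_sd: float
    rng_seed: int

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return self.phen.disease_ids

    def initial_states(self) -> list["ModuleState"]:
        """Seeded module states ready for annealing."""
        return [
            ModuleState(d, frozenset(self.seeds[d])) for d in self.disease_ids
        ]

    def planted_as_table(self) -> dict[str, set[str]]:
        return {d: set(ps) for d, ps in self.planted.items()}


def _random_connected_graph(
    n: int, n_extra_edges: int, degree_skew: bool, rng: np.random.Generator
) -> ProteinNetwork:
    """Uniform random attachment tree plus random extra edges.

    The tree guarantees connectivity; extra edges are sampled uniformly
    (or degree-preferentially when ``degree_skew`` is set) and de-duplicated
    by the network constructor.
    """
    width = len(str(n - 1))
    names = [f"P{i:0{width}d}" for i in range(n)]
    edges: list[tuple[str, str]] = []
    degree = np.ones(n)
    for i in range(1, n):
        if degree_skew:
            w = degree[:i] / degree[:i].sum()
            j = rng.choice(i, p=w)
        else:
            j = rng.integers(i)
        edges.append((names[i], names[int(j)]))
        degree[i] += 1
        degree[int(j)] += 1
    for _ in range(n_extra_edges):
        a = int(rng.integers(n))
        if degree_skew:
            b = int(rng.choice(n, p=degree / degree.sum()))
        else:
            b = int(rng.integers(n))
        if a != b:
            edges.append((names[a], names[b]))
            degree[a] += 1
            degree[b] += 1
    return ProteinNetwork(edges, nodes=names)


def _grow_connected(
    start: set[str],
    size: int,
    network: ProteinNetwork,
    rng: np.random.Generator,
    within: set[str] | None = None,
) -> set[str]:
    """Grow a connected set from ``start`` to ``size`` members by uniform
    random frontier expansion, optionally restricted to ``within``."""
    module = set(start)
    while len(module) < size:
        cand = frontier(module, network)
        if within is not None:
            cand &= within
        if not cand:
            break
        items = sorted(cand)
        module.add(items[rng.integers(len(items))])
    return module


def generate_benchmark(
    n_proteins: int = 500,
    n_diseases: int = 20,
    mean_module_size: int = 15,
    overlap_groups: int = 5,
    seed_fraction: float = 0.4,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    core_fraction: float = 2 / 3,
    extra_edge_factor: float = 2.0,
    degree_skew: bool = False,
) -> SyntheticBenchmark:
    """Generate a planted-module benchmark.

    Parameters
    ----------
    n_proteins, n_diseases
        Interactome size and number of diseases.
    mean_module_size
        Mean (Poisson) size of the planted modules.
    overlap_groups
        Number of disease groups; diseases in the same group share a common
        connected core, giving the phenotypic similarity matrix
        off-diagonal structure to recover.
    seed_fraction
        Fraction of each planted module carved out as the connected seed.
    noise_sd
        Standard deviation of Gaussian noise added to the planted Jaccard
        similarities (clipped to [0, 1]); 0 gives a noiseless target.
    rng_seed
        Seed for every random choice; identical seeds reproduce the
        benchmark exactly.
    core_fraction
        Size of a group's shared core relative to the mean module size.
        The core must dominate the module for the planted structure to be
        identifiable: a pairwise-Jaccard objective pins down the shared
        intersection of group-mates but says nothing about which unique
        proteins fill the remainder, so only when within-group target
        similarities exceed the initial seed–seed similarity does
        optimization pull modules back onto the planted cores.
    extra_edge_factor
        Extra random edges beyond the spanning tree, as a multiple of
        ``n_proteins``; controls the background degree.
    degree_skew
        Attach edges preferentially to high-degree proteins, mimicking
        hub-dominated interactomes.
    """
    if min(n_proteins, n_diseases, mean_module_size, overlap_groups) < 1:
        raise ValueError("sizes must be positive")
    if not (0 < seed_fraction <= 1):
        raise ValueError("seed_fraction must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not (0 < core_fraction <= 1):
        raise ValueError("core_fraction must lie in (0, 1]")
    if overlap_groups > n_diseases:
        raise ValueError("more overlap groups than diseases")
    if mean_module_size * overlap_groups > n_proteins:
        raise ValueError("planted modules cannot fit in the network")

    rng = np.random.default_rng(rng_seed)
    network = _random_connected_graph(
        n_proteins, int(extra_edge_factor * n_proteins), degree_skew, rng
    )
    proteins = sorted(network.nodes)

    core_size = max(2, round(mean_module_size * core_fraction))
    cores: list[set[str]] = []
    for _ in range(overlap_groups):
        start = {proteins[rng.integers(len(proteins))]}
        cores.append(_grow_connected(start, core_size, network, rng))

    width = len(str(n_diseases - 1))
    disease_ids = [f"D{i:0{width}d}" for i in range(n_diseases)]
    planted: dict[str, frozenset[str]] = {}
    seeds: dict[str, frozenset[str]] = {}
    for i, disease in enumerate(disease_ids):
        core = cores[i % overlap_groups]
        size = max(len(core) + 1, int(rng.poisson(mean_module_size)))
        module = _grow_connected(set(core), size, network, rng)
        planted[disease] = frozenset(module)
        seed_size = max(1, math.ceil(seed_fraction * len(module)))
        core_members = sorted(core & module)
        start = {core_members[rng.integers(len(core_members))]}
        seed = _grow_connected(start, seed_size, network, rng, within=module)
        seeds[disease] = frozenset(seed)
        assert is_connected_in(set(seed), network)

    n = n_diseases
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard(
                set(planted[disease_ids[i]]), set(planted[disease_ids[j]])
            )
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        values = np.clip(values + noise, 0.0, 1.0)
    phen = PhenotypeSimilarityMatrix(tuple(disease_ids), values)

    return SyntheticBenchmark(
        network=network,
        planted=planted,
        seeds=seeds,
        phen=phen,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )
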