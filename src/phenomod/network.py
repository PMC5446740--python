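"""Protein–protein interaction network model and connectivity primitives.

The interactome is an undirected simple graph over opaque string protein
identifiers.  Every operation the optimizer needs — induced-subgraph
connectivity, largest connected components, module frontiers, and cascade
removal of proteins disconnected from a seed — lives here.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "ProteinNetwork",
    "is_connected_in",
    "largest_connected_component",
    "frontier",
    "cascade_remove",
]


class ProteinNetwork:
    """Undirected simple graph of protein–protein interactions.

    Self-loops are dropped and duplicate / reversed-duplicate edges merged
    at construction time, so the adjacency structure is always that of a
    simple undirected graph.  Identifiers are case-sensitive opaque strings.

    Parameters
    ----------
    edges
        Iterable of ``(protein_a, protein_b)`` pairs.
    nodes
        Optional extra isolated proteins to include.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:  # self-loop: meaningless for module connectivity
                g.add_node(a)
                continue
            g.add_edge(a, b)
        self._g = g

    # -- basic queries -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, protein: str) -> bool:
        return protein in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, protein: str) -> set[str]:
        """All interaction partners of ``protein``."""
        return set(self._g[protein])

    def degree(self, protein: str) -> int:
        return self._g.degree[protein]

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self._g.edges)

    def component_of(self, protein: str) -> set[str]:
        """The connected component of the full network containing ``protein``."""
        return set(nx.node_connected_component(self._g, protein))


def _require_subset(proteins: set[str], network: ProteinNetwork, what: str) -> None:
    missing = [p for p in proteins if p not in network]
    if missing:
        raise ValueError(
            f"{what} contains proteins absent from the network: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
        )


def is_connected_in(proteins: set[str], network: ProteinNetwork) -> bool:
    """Is the subgraph induced by ``proteins`` connected?

    Raises
    ------
    ValueError
        If ``proteins`` is empty or contains an identifier not in the network.
    """
    if not proteins:
        raise ValueError("connectivity of the empty protein set is undefined")
    _require_subset(set(proteins), network, "protein set")
    proteins = set(proteins)
    start = next(iter(proteins))
    seen = {start}
    queue = deque([start])
    g = network.graph
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v in proteins and v not in seen:
                seen.add(v)
                queue.append(v)
    return len(seen) == len(proteins)


def largest_connected_component(
    proteins: Iterable[str], network: ProteinNetwork
) -> set[str]:
    """Largest connected component of the subgraph induced by ``proteins``.

    Proteins absent from the network are ignored (known disease proteins are
    projected into the interactome before seeding).  Among maximum-size
    components, the one containing the lexicographically smallest protein
    identifier is returned, which makes the choice deterministic and
    independent of iteration order.  The result is empty iff no protein is
    present in the network.
    """
    present = {p for p in proteins if p in network}
    if not present:
        return set()
    sub = network.graph.subgraph(present)
    components = [set(c) for c in nx.connected_components(sub)]
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    return min(tied, key=min)


def frontier(module: set[str], network: ProteinNetwork) -> set[str]:
    """Proteins adjacent to the module but outside it (candidate additions)."""
    _require_subset(set(module), network, "module")
    out: set[str] = set()
    g = network.graph
    for p in module:
        out.update(g[p])
    out.difference_update(module)
    return out


def cascade_remove(
    module: set[str],
    seed: set[str],
    victim: str,
    network: ProteinNetwork,
) -> set[str]:
    """Remove ``victim`` from a connected module, cascading disconnections.

    Deletes ``victim`` and every protein that is thereby no longer reachable
    from any seed protein via paths inside the remaining module.  Seed
    proteins are immutable and may never be the victim.  The returned set is
    connected and contains the seed.
    """
    module = set(module)
    seed = set(seed)
    if victim in seed:
        raise ValueError(f"cannot remove seed protein {victim!r}")
    if victim not in module:
        raise ValueError(f"victim {victim!r} is not in the module")
    if not seed <= module:
        raise ValueError("seed must be a subset of the module")
    remaining = module - {victim}
    # keep exactly the proteins reachable from the seed inside `remaining`
    seen = set(seed)
    queue = deque(seed)
    g = network.graph
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v in remaining and v not in seen:
                seen.add(v)
                queue.append(v)
    return seen
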