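"""Synthetic networks and planted gene sets for end-to-end validation.

Real gene-centered interactomes differ in size, density and degree-tail
shape, contain protein complexes as locally dense modules, pathways as
network-proximal gene sets and disease genes as cohesive neighborhoods, and
related resources look like controlled rewirings of one another.  The
generators here reproduce exactly those statistical features at test scale
(10^3 genes): heavy- or light-tailed random graphs, planted dense complexes,
snowball-sampled disease modules with a tunable cohesiveness dial, and
degree-preserving rewiring families.  Every generator is deterministic under
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .network_io import GeneSet, Interactome

NETWORK_MODELS = ("ba", "er", "duplication_divergence")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic interactome."""

    n_genes: int = 1000
    n_edges: int = 3000          # target; BA/DD reach it within model granularity
    model: str = "ba"
    rng_seed: int = 0
    name: str = "synthetic"


def _gene_label(i: int) -> str:
    return f"G{i + 1:06d}"


def _relabel(graph: nx.Graph, name: str) -> Interactome:
    """Map integer nodes to stable G000001... identifiers (sorted node order)."""
    nodes = sorted(graph.nodes)
    mapping = {node: _gene_label(i) for i, node in enumerate(nodes)}
    return Interactome(name, nx.relabel_nodes(graph, mapping, copy=True))


def gen_network(spec: SyntheticSpec) -> Interactome:
    """Generate a connected simple graph according to the spec.

    Models: ``ba`` (Barabasi-Albert preferential attachment, heavy tail),
    ``er`` (Erdos-Renyi G(n, m), Poisson degrees) and
    ``duplication_divergence`` (gene-duplication growth, heavy tail with high
    clustering).  If the raw model yields fragments, the largest connected
    component is taken, so the realized gene count may fall slightly below
    ``n_genes`` for er/duplication_divergence.
    """
    if spec.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    seed = int(spec.rng_seed)
    if spec.model == "ba":
        m = max(1, round(spec.n_edges / spec.n_genes))
        if spec.n_genes <= m:
            raise ValueError("edge target infeasible for the BA model")
        g = nx.barabasi_albert_graph(spec.n_genes, m, seed=seed)
    elif spec.model == "er":
        max_edges = spec.n_genes * (spec.n_genes - 1) // 2
        if spec.n_edges > max_edges:
            raise ValueError("edge target exceeds the complete graph")
        g = nx.gnm_random_graph(spec.n_genes, spec.n_edges, seed=seed)
    elif spec.model == "duplication_divergence":
        # retention probability tuned so the expected density matches the target
        p = min(0.9, max(0.1, spec.n_edges / (spec.n_genes * 10.0)))
        g = nx.duplication_divergence_graph(spec.n_genes, p, seed=seed)
    else:
        raise ValueError(f"unknown model {spec.model!r}")
    if not nx.is_connected(g):
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    return _relabel(g, spec.name)


def plant_complex(
    net: Interactome,
    size: int,
    internal_density: float,
    rng_seed: Optional[int] = None,
    set_id: str = "planted_complex",
) -> tuple[Interactome, GeneSet]:
    """Plant a complex-like dense module: random genes + internal edges.

    Edges are only added (never removed) among ``size`` randomly chosen genes
    until the internal edge density reaches ``internal_density``.  Returns
    the augmented network and the planted set labeled ``complex``.
    """
    if not 3 <= size <= net.n_genes:
        raise ValueError("size must be in [3, n_genes]")
    if not 0.0 < internal_density <= 1.0:
        raise ValueError("internal_density must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    genes = sorted(net.genes)
    members = sorted(rng.choice(genes, size=size, replace=False))
    out = net.copy()
    possible = [
        (members[i], members[j])
        for i in range(size)
        for j in range(i + 1, size)
    ]
    target = int(np.ceil(internal_density * len(possible)))
    present = [e for e in possible if out.graph.has_edge(*e)]
    absent = [e for e in possible if not out.graph.has_edge(*e)]
    need = target - len(present)
    if need > 0:
        pick = rng.choice(len(absent), size=need, replace=False)
        for idx in pick:
            out.add_edge(*absent[idx])
    return out, GeneSet(id=set_id, category="complex", members=frozenset(members))


def plant_disease_module(
    net: Interactome,
    size: int,
    cohesiveness: float,
    rng_seed: Optional[int] = None,
    set_id: str = "planted_disease",
    category: str = "disease",
) -> GeneSet:
    """Grow a disease-like gene set by seeded snowball sampling.

    ``cohesiveness`` is the fraction of members drawn from the expanding
    neighborhood of a random start gene (1 = a fully cohesive connected
    module, 0 = a uniform random gene set).  No edges are modified.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    if not 0.0 <= cohesiveness <= 1.0:
        raise ValueError("cohesiveness must be in [0, 1]")
    if size > net.n_genes:
        raise ValueError("size exceeds the network")
    rng = np.random.default_rng(rng_seed)
    genes = sorted(net.genes)
    n_cohesive = int(round(cohesiveness * size))
    members: list[str] = []
    member_set: set[str] = set()
    if n_cohesive > 0:
        start = genes[int(rng.integers(len(genes)))]
        members.append(start)
        member_set.add(start)
        frontier = sorted(set(net.graph.neighbors(start)))
        while len(members) < n_cohesive:
            frontier = [g for g in frontier if g not in member_set]
            if not frontier:  # neighborhood exhausted; fall back to random fill
                break
            nxt = frontier[int(rng.integers(len(frontier)))]
            members.append(nxt)
            member_set.add(nxt)
            frontier = sorted(set(frontier) | set(net.graph.neighbors(nxt)))
    remaining = [g for g in genes if g not in member_set]
    n_random = size - len(members)
    if n_random > 0:
        pick = rng.choice(len(remaining), size=n_random, replace=False)
        for idx in sorted(pick):
            members.append(remaining[idx])
    return GeneSet(id=set_id, category=category, members=frozenset(members))


def plant_proximal_set(
    net: Interactome,
    size: int,
    cohesiveness: float,
    rng_seed: Optional[int] = None,
    set_id: str = "planted_pathway",
) -> GeneSet:
    """Pathway-like network-proximal gene set (snowball sampling, no new edges)."""
    return plant_disease_module(
        net, size, cohesiveness, rng_seed, set_id=set_id, category="pathway"
    )


def rewire_family(
    net: Interactome,
    fractions: Sequence[float],
    rng_seed: Optional[int] = None,
) -> list[Interactome]:
    """Degree-preserving rewired variants at the requested edge fractions.

    Each variant applies double-edge swaps touching the stated fraction of
    edges (each swap rewires two edges), preserving the degree sequence
    exactly; the largest connected component is then retained so downstream
    analyses see a connected network.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    out = []
    for f in fractions:
        g = net.graph.copy()
        n_swaps = max(1, int(round(f * net.n_edges / 2.0)))
        seed = int(rng.integers(2**31 - 1))
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps + 100, seed=seed)
        if not nx.is_connected(g):
            g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        out.append(Interactome(f"{net.name}_rw{int(round(100 * f))}", g))
    return out
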