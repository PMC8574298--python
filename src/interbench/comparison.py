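"""Inter-network correlation stack, similarity network and reproducibility index.

Every analysis type t (topology T, protein-complex CCF, pathway CCF, pathway
cross-talk, disease-gene prioritization) yields one or more network-by-network
Spearman correlation matrices C_j.  These are averaged per type into C_t, the
C_t are summed into the overall weight matrix C_I, which defines a directed
top-k similarity network whose communities are found by fast-greedy modularity
optimization.  The aggregate reproducibility index of network i is

    R_i = sum_t [ sum_{j != i} c_ijt / (n - 1) ]

the sum over analysis types of its mean correlation with all other networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network_io import Interactome

logger = logging.getLogger(__name__)

ANALYSIS_TYPES = ("T", "PC", "PATH", "PCT", "DGP")


def spearman_matrix(vectors: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-network value vectors.

    For each pair the vectors are aligned on the positions where both are
    defined (per-pair intersection, not the global one); ties receive average
    ranks.  At least three shared positions are required per pair.
    """
    names = list(vectors)
    if len(names) < 2:
        raise ValueError("need at least two vectors")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            va, vb = vectors[a].dropna(), vectors[b].dropna()
            shared = va.index.intersection(vb.index)
            if len(shared) < 3:
                raise ValueError(
                    f"pair ({a}, {b}): only {len(shared)} shared positions (< 3)"
                )
            rho, _ = stats.spearmanr(va.loc[shared], vb.loc[shared])
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def average_matrices(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Elementwise mean of aligned correlation matrices; diagonal reset to 1."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape != first.shape or list(m.index) != list(first.index) \
                or list(m.columns) != list(first.columns):
            raise ValueError("matrices differ in shape or network ordering")
    out = sum(np.asarray(m, dtype=float) for m in matrices) / len(matrices)
    np.fill_diagonal(out, 1.0)  # self-correlations by definition
    return pd.DataFrame(out, index=first.index, columns=first.columns)


@dataclass
class CorrelationStack:
    """Per-analysis-type correlation matrices and their aggregates."""

    matrices: dict[str, list[pd.DataFrame]] = field(default_factory=dict)

    def add(self, analysis_type: str, matrix: pd.DataFrame) -> None:
        self.matrices.setdefault(analysis_type, []).append(matrix)

    @property
    def net_names(self) -> list[str]:
        for mats in self.matrices.values():
            return list(mats[0].index)
        return []

    @property
    def types(self) -> list[str]:
        return list(self.matrices)

    def c_t(self, analysis_type: str) -> pd.DataFrame:
        return average_matrices(self.matrices[analysis_type])

    def c_i(self) -> pd.DataFrame:
        return overall_similarity(self)


def overall_similarity(stack: CorrelationStack) -> pd.DataFrame:
    """C_I: elementwise sum of the per-type averages present in the stack."""
    if not stack.matrices:
        raise ValueError("empty correlation stack")
    missing = [t for t in ANALYSIS_TYPES if t not in stack.matrices]
    if missing:
        logger.warning("correlation stack missing analysis types: %s", ", ".join(missing))
    c_ts = [stack.c_t(t) for t in stack.types]
    out = c_ts[0].copy()
    for m in c_ts[1:]:
        out = out + m
    return out


@dataclass
class SimilarityNetwork:
    graph: nx.DiGraph          # each network points to its top-k most similar
    communities: dict[str, int]
    modularity: float
    k: int


def similarity_network(C_I: pd.DataFrame, k: int = 4) -> SimilarityNetwork:
    """Directed top-k similarity graph over C_I with fast-greedy communities.

    Each network points to its k most similar networks (C_I off-diagonal;
    ties broken lexicographically by target name).  Community structure is
    found by Clauset-Newman-Moore fast-greedy modularity optimization on the
    undirected simple projection (an edge survives if either direction exists).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(C_I.index)
    if len(names) < 3:
        raise ValueError("need at least three networks")
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for a in names:
        others = [b for b in names if b != a]
        # decreasing similarity, ties resolved by lexicographic target name
        others.sort(key=lambda b: (-C_I.loc[a, b], b))
        for b in others[: min(k, len(others))]:
            g.add_edge(a, b, weight=float(C_I.loc[a, b]))
    und = nx.Graph()
    und.add_nodes_from(names)
    und.add_edges_from((u, v) for u, v in g.edges)
    h = ig.Graph(
        n=len(names),
        edges=[(names.index(u), names.index(v)) for u, v in und.edges],
        directed=False,
    )
    dend = h.community_fastgreedy()
    clustering = dend.as_clustering()
    membership = clustering.membership
    communities = {name: int(membership[i]) for i, name in enumerate(names)}
    return SimilarityNetwork(
        graph=g,
        communities=communities,
        modularity=float(clustering.modularity),
        k=k,
    )


def aggregate_R(stack: CorrelationStack) -> pd.Series:
    """Reproducibility index R_i per network.

    Sum over the stack's analysis types of the mean off-diagonal correlation
    of network i's row of C_t.  Missing types simply do not contribute.
    """
    names = stack.net_names
    if not names:
        raise ValueError("empty correlation stack")
    n = len(names)
    r = pd.Series(0.0, index=names, name="R")
    for t in stack.types:
        ct = stack.c_t(t)
        offdiag_sum = ct.sum(axis=1) - np.diag(ct.values)
        r = r + offdiag_sum / (n - 1)
    return r


def overlap_matrix(nets: Sequence[Interactome], mode: str = "genes") -> pd.DataFrame:
    """Asymmetric pairwise overlap: |shared items| / |items of the column network|."""
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    if mode not in ("genes", "edges"):
        raise ValueError("mode must be 'genes' or 'edges'")
    items = {
        net.name: (net.genes if mode == "genes" else net.edge_set()) for net in nets
    }
    names = [net.name for net in nets]
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for r in names:
        for c in names:
            if r == c:
                continue
            mat.loc[r, c] = len(items[r] & items[c]) / len(items[c])
    return mat
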