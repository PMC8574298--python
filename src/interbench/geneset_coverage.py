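"""Connected component fraction (CCF) of gene sets in interaction networks.

CCF = |S_C| / |S| where S_C are the members of a gene set S having at least
one edge to another member of S in the network.  Members absent from the
network count in the denominator but can never be connected, which makes the
score comparable across networks of different gene coverage.  Connection
means a direct within-set edge, not a path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network_io import GeneSet, GeneSetCollection, Interactome


def ccf(S: GeneSet, net: Interactome) -> float:
    """Fraction of set members connected to at least one other member."""
    members = S.members
    if not members:
        raise ValueError("empty gene set")
    g = net.graph
    connected = 0
    for gene in members:
        if gene not in g:
            continue
        if any(nb in members for nb in g.neighbors(gene)):
            connected += 1
    return connected / len(members)


@dataclass
class CCFMatrix:
    """Gene-set x interactome matrix of CCF values with per-set summaries."""

    values: pd.DataFrame  # rows: set ids, columns: net names
    categories: pd.Series  # set id -> category
    sizes: pd.Series       # set id -> member count

    @property
    def set_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def net_names(self) -> list[str]:
        return list(self.values.columns)

    def mean(self) -> pd.Series:
        """Per-set mean CCF across interactomes."""
        return self.values.mean(axis=1)

    def sd(self) -> pd.Series:
        """Per-set sample standard deviation of CCF across interactomes."""
        return self.values.std(axis=1, ddof=1).fillna(0.0)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "category", self.categories)
        out.insert(1, "size", self.sizes)
        out.to_csv(path, sep="\t", index_label="set_id")


def ccf_matrix(coll: GeneSetCollection, nets: Sequence[Interactome]) -> CCFMatrix:
    """CCF of every gene set in every network (collection already size-filtered)."""
    names = [net.name for net in nets]
    if len(set(names)) != len(names):
        raise ValueError("interactome names must be unique")
    data = {
        net.name: [ccf(s, net) for s in coll]
        for net in nets
    }
    values = pd.DataFrame(data, index=pd.Index(coll.ids(), name="set_id"))
    categories = pd.Series({s.id: s.category for s in coll}, name="category")
    sizes = pd.Series({s.id: s.size for s in coll}, name="size")
    return CCFMatrix(values=values, categories=categories, sizes=sizes)


def count_covered(m: CCFMatrix, threshold: float = 0.5) -> pd.Series:
    """Per-interactome number of gene sets with CCF strictly above threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (m.values > threshold).sum(axis=0)


def union_network(nets: Sequence[Interactome], name: str = "union") -> Interactome:
    """Edge-union of several networks (used to probe CCF monotonicity)."""
    out = Interactome(name)
    for net in nets:
        for u, v, d in net.graph.edges(data=True):
            out.add_edge(u, v, d.get("confidence"))
    return out
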