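"""Pathway cross-talk (PCT) via network diffusion.

S12 is the mean normalized steady-state mass found on pathway P2's genes when
the diffusion is seeded from P1's genes; PCT(P1, P2) = (S12 + S21) / 2.  The
normalized profile sums to one, so S12 is the average proportion of a unit of
substance, injected through P1, that ends up on each P2 gene.  Higher PCT
means shorter paths between the two gene sets.

Set members absent from the interactome are dropped from both the seed and
the denominator |P2| by default (diffusion is only defined on network genes);
``count_absent`` switches to the full set size for the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import NetworkDiffusion
from .network_io import GeneSet, GeneSetCollection, Interactome

logger = logging.getLogger(__name__)


def _target_score(profile_prime: np.ndarray, index: dict, members, count_absent: bool) -> float:
    present = [g for g in members if g in index]
    if not present:
        raise ValueError("gene set is disjoint from the interactome")
    denom = len(members) if count_absent else len(present)
    return float(sum(profile_prime[index[g]] for g in present)) / denom


def pct_pair(
    P1: GeneSet,
    P2: GeneSet,
    net: Interactome,
    alpha: float = 0.7,
    count_absent: bool = False,
    model: Optional[NetworkDiffusion] = None,
) -> float:
    """PCT between two gene sets on one interactome."""
    if model is None:
        model = NetworkDiffusion(alpha=alpha).fit(net)
    index = model.index_
    prof1 = model.profile(P1.members, normalized=True).x_star
    prof2 = model.profile(P2.members, normalized=True).x_star
    s12 = _target_score(prof1, index, P2.members, count_absent)
    s21 = _target_score(prof2, index, P1.members, count_absent)
    return (s12 + s21) / 2.0


@dataclass
class PCTMatrix:
    """Symmetric pathway x pathway cross-talk matrix on one interactome."""

    values: pd.DataFrame
    net_name: str

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.values.index)

    def offdiag_pairs(self) -> pd.Series:
        """Long-format off-diagonal upper-triangle values indexed by (a, b)."""
        ids = self.pathway_ids
        data = {
            (a, b): self.values.loc[a, b]
            for a, b in combinations(ids, 2)
        }
        return pd.Series(data).rename_axis(["pathway_a", "pathway_b"])


def pct_matrix(
    coll: GeneSetCollection,
    net: Interactome,
    alpha: float = 0.7,
    count_absent: bool = False,
) -> PCTMatrix:
    """All-pairs PCT on one interactome (one diffusion per pathway, not per pair)."""
    model = NetworkDiffusion(alpha=alpha).fit(net)
    index = model.index_
    usable, dropped = [], []
    for s in coll:
        if any(g in index for g in s.members):
            usable.append(s)
        else:
            dropped.append(s.id)
    if dropped:
        logger.warning(
            "%s: dropped %d gene sets disjoint from the network: %s",
            net.name, len(dropped), ", ".join(dropped[:5]),
        )
    profiles = {s.id: model.profile(s.members, normalized=True).x_star for s in usable}
    ids = [s.id for s in usable]
    by_id = {s.id: s for s in usable}
    n = len(ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j < i:
                continue
            s_ab = _target_score(profiles[a], index, by_id[b].members, count_absent)
            s_ba = _target_score(profiles[b], index, by_id[a].members, count_absent)
            mat[i, j] = mat[j, i] = (s_ab + s_ba) / 2.0
    values = pd.DataFrame(mat, index=pd.Index(ids, name="pathway"), columns=ids)
    return PCTMatrix(values=values, net_name=net.name)


@dataclass
class PCTConservation:
    """Cross-interactome conservation of each pathway pair's cross-talk."""

    mean: pd.Series
    sd: pd.Series
    snr: pd.Series  # mean/sd; inf where sd == 0

    def median_snr(self) -> float:
        finite = self.snr[np.isfinite(self.snr)]
        return float(finite.median()) if len(finite) else float("nan")


def pct_conservation(matrices: Sequence[PCTMatrix]) -> PCTConservation:
    """Per-pair mean, sample sd and signal-to-noise ratio across interactomes.

    The diagonal (self cross-talk) is excluded.  Matrices must share the
    pathway set; rows/columns are aligned by id.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two PCT matrices")
    ids = sorted(matrices[0].pathway_ids)
    for m in matrices[1:]:
        if sorted(m.pathway_ids) != ids:
            raise ValueError("PCT matrices do not share a common pathway set")
    stacked = pd.concat(
        [m.values.loc[ids, ids].pipe(_upper_series) for m in matrices], axis=1
    )
    mean = stacked.mean(axis=1)
    sd = stacked.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = mean / sd
    snr[sd == 0] = np.inf
    return PCTConservation(mean=mean, sd=sd, snr=snr)


def _upper_series(df: pd.DataFrame) -> pd.Series:
    ids = list(df.index)
    data = {(a, b): df.loc[a, b] for a, b in combinations(ids, 2)}
    return pd.Series(data).rename_axis(["pathway_a", "pathway_b"])
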