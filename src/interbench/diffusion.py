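"""Symmetric-normalized network diffusion.

The engine shared by pathway cross-talk scoring and disease-gene
prioritization.  A seed vector ``x0`` (non-negative, typically binary over a
gene list) is smoothed over the network through

    x_{t+1} = alpha * W x_t + (1 - alpha) * x0,      W = D^{-1/2} A D^{-1/2}

until the steady state ``x*`` is reached.  ``alpha`` in (0, 1) weights how far
the initial information spreads (default 0.7).  Since the spectral radius of W
is <= 1, the iteration contracts and converges to
(1 - alpha) (I - alpha W)^{-1} x0; the dense closed form is used as the test
oracle, the production path is sparse iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .network_io import Interactome


class ConvergenceError(RuntimeError):
    """Diffusion iteration hit max_iter before reaching the tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"diffusion did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )


def normalize_adjacency(net: Interactome) -> tuple[sp.csr_matrix, list[str]]:
    """Symmetrically normalized adjacency W = D^{-1/2} A D^{-1/2}.

    Returns the sparse matrix together with the canonical gene order indexing
    its rows/columns.  Isolated genes have no degree to normalize by and are
    rejected.
    """
    genes = net.gene_order()
    if not genes:
        raise ValueError("empty interactome")
    deg = np.array([net.graph.degree[g] for g in genes], dtype=float)
    if np.any(deg == 0):
        bad = genes[int(np.argmin(deg))]
        raise ValueError(f"isolated gene {bad!r}: degree 0 cannot be normalized")
    index = {g: i for i, g in enumerate(genes)}
    rows, cols, vals = [], [], []
    inv_sqrt = 1.0 / np.sqrt(deg)
    for u, v in net.graph.edges:
        i, j = index[u], index[v]
        w = inv_sqrt[i] * inv_sqrt[j]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(len(genes), len(genes)))
    return W, genes


def diffuse(
    W,
    x0: np.ndarray,
    alpha: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Iterate x <- alpha W x + (1-alpha) x0 to the steady state.

    Stops when the max absolute change falls below ``tol``; raises
    :class:`ConvergenceError` if ``max_iter`` is exhausted first.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("seed vector must be non-negative")
    if not np.any(x0 > 0):
        raise ValueError("seed vector must not be all zero")
    x = x0.copy()
    base = (1.0 - alpha) * x0
    for _ in range(max_iter):
        x_next = alpha * (W @ x) + base
        residual = float(np.max(np.abs(x_next - x)))
        x = x_next
        if residual < tol:
            return x
    raise ConvergenceError(residual, max_iter)


def diffuse_closed_form(W, x0: np.ndarray, alpha: float = 0.7) -> np.ndarray:
    """Dense closed form (1-alpha)(I - alpha W)^{-1} x0 — oracle for small graphs."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    Wd = W.toarray() if sp.issparse(W) else np.asarray(W, dtype=float)
    n = Wd.shape[0]
    return (1.0 - alpha) * np.linalg.solve(np.eye(n) - alpha * Wd, np.asarray(x0, float))


def normalize_profile(x_star: np.ndarray) -> np.ndarray:
    """Rescale a steady-state profile to unit sum (enables cross-seed comparison)."""
    x_star = np.asarray(x_star, dtype=float)
    total = x_star.sum()
    if total <= 0:
        raise ValueError("cannot normalize a profile with non-positive sum")
    return x_star / total


@dataclass
class DiffusionProfile:
    """Per-gene steady-state scores from one seed vector on one interactome."""

    net_name: str
    alpha: float
    genes: list[str]
    x0: np.ndarray
    x_star: np.ndarray
    normalized: bool = False

    def normalized_profile(self) -> "DiffusionProfile":
        if self.normalized:
            return self
        return DiffusionProfile(
            net_name=self.net_name,
            alpha=self.alpha,
            genes=self.genes,
            x0=self.x0,
            x_star=normalize_profile(self.x_star),
            normalized=True,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tx0\tx_star\n")
            for g, a, b in zip(self.genes, self.x0, self.x_star):
                fh.write(f"{g}\t{a:g}\t{b:.10g}\n")


class NetworkDiffusion(BaseEstimator, TransformerMixin):
    """Network-diffusion smoother with the scikit-learn transformer contract.

    ``fit`` takes an :class:`Interactome` and caches its normalized adjacency;
    ``transform`` maps seed vectors (2d array, rows = samples over the fitted
    gene order) or gene sets to steady-state profiles.

    Parameters
    ----------
    alpha : float, default 0.7
        Restart weight in (0, 1); larger values spread the signal further.
    tol : float, default 1e-8
        Max-abs convergence tolerance of the fixed-point iteration.
    max_iter : int, default 10000
        Iteration cap; exceeded => :class:`ConvergenceError`.
    """

    def __init__(self, alpha: float = 0.7, tol: float = 1e-8, max_iter: int = 10_000):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, net: Interactome, y=None):
        W, genes = normalize_adjacency(net)
        self.W_ = W
        self.genes_ = genes
        self.index_ = {g: i for i, g in enumerate(genes)}
        self.net_name_ = net.name
        return self

    def seed_vector(self, seeds: Iterable[str]) -> np.ndarray:
        """Binary x0 over the fitted gene order; genes outside the network are ignored."""
        x0 = np.zeros(len(self.genes_))
        for g in seeds:
            i = self.index_.get(g)
            if i is not None:
                x0[i] = 1.0
        return x0

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        rows = np.atleast_2d(X)
        out = np.vstack(
            [diffuse(self.W_, row, self.alpha, self.tol, self.max_iter) for row in rows]
        )
        return out[0] if single else out

    def profile(self, seeds: Iterable[str], normalized: bool = False) -> DiffusionProfile:
        """Diffuse a binary seed gene set into a :class:`DiffusionProfile`."""
        x0 = self.seed_vector(seeds)
        x_star = diffuse(self.W_, x0, self.alpha, self.tol, self.max_iter)
        prof = DiffusionProfile(
            net_name=self.net_name_, alpha=self.alpha, genes=self.genes_,
            x0=x0, x_star=x_star,
        )
        return prof.normalized_profile() if normalized else prof
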