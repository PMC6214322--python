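"""Programmatic generators for toy networks and synthetic pipeline inputs.

Two small deterministic topologies exercise the contrast between the
game-theoretic index and classical centralities:

* ``make_star_of_stars`` — a hub adjacent to branch nodes, each branch
  carrying its own leaves.  The hub dominates every classical measure,
  yet removing a branch node isolates its leaves, and the relevance index
  ranks the branches first.
* ``make_clique_flower`` — a hub adjacent to one connector per clique.
  Here the connectors lead on the index, degree and eigenvector
  centrality, while shortest-path measures still favour the hub.

The random generators provide a correlation-like symmetric matrix (for
threshold-robustness studies) and expression matrices with planted
co-expression modules (for end-to-end pipeline tests).  All generators
are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .graph import Network

__all__ = [
    "make_star_of_stars",
    "make_clique_flower",
    "random_correlation_like_matrix",
    "synthetic_expression",
    "random_network",
]


def make_star_of_stars(branches: int = 5, leaves_per_branch: int = 3) -> Network:
    """Hub "1" joined to ``branches`` branch nodes, each with its own leaves.

    Node labels: hub "1"; branches "2"…; leaves numbered consecutively,
    grouped by branch.  (5, 3) gives the 21-node, 20-edge topology with
    degree sequence hub 5, branches 4, leaves 1.
    """
    if branches < 1 or leaves_per_branch < 0:
        raise ValueError("need branches >= 1 and leaves_per_branch >= 0")
    net = Network(nodes=["1"])
    next_leaf = 2 + branches
    for b in range(branches):
        branch = str(2 + b)
        net.add_edge_unchecked("1", branch)
        for _ in range(leaves_per_branch):
            net.add_edge_unchecked(branch, str(next_leaf))
            next_leaf += 1
    return net


def make_clique_flower(n_cliques: int = 3, clique_size: int = 4) -> Network:
    """Hub "1" joined to one connector per clique; each clique fully connected.

    Connectors are labelled "2"…; remaining clique members follow, grouped
    by clique.  (3, 4) gives 13 nodes and 21 edges with degrees
    (3, 4, 4, 4, 3 x 9).
    """
    if n_cliques < 1 or clique_size < 2:
        raise ValueError("need n_cliques >= 1 and clique_size >= 2")
    net = Network(nodes=["1"])
    next_member = 2 + n_cliques
    for c in range(n_cliques):
        connector = str(2 + c)
        net.add_edge_unchecked("1", connector)
        members = [connector] + [
            str(next_member + m) for m in range(clique_size - 1)
        ]
        next_member += clique_size - 1
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                net.add_edge_unchecked(members[a], members[b])
    return net


def random_correlation_like_matrix(n: int, seed: int) -> pd.DataFrame:
    """Symmetric matrix with unit diagonal and i.i.d. Uniform[0, 1] off-diagonals.

    Emulates a correlation matrix of a fictitious all-positively-correlated
    dataset; the upper triangle is drawn and mirrored, so the result is a
    pure function of (n, seed).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    m = np.ones((n, n))
    iu, ju = np.triu_indices(n, k=1)
    draws = rng.uniform(0.0, 1.0, size=iu.size)
    m[iu, ju] = draws
    m[ju, iu] = draws
    genes = [f"g{i+1}" for i in range(n)]
    return pd.DataFrame(m, index=genes, columns=genes)


def synthetic_expression(
    n_genes: int,
    n_samples: int,
    modules: list[tuple[int, float]] = (),
    noise_sd: float = 1.0,
    missing_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression matrix with planted co-expression modules.

    Each module ``(size, within_corr)`` shares a latent standard-normal
    profile; member genes are latent + independent Gaussian noise with the
    noise variance calibrated so the expected within-module Pearson
    correlation is ``within_corr`` (members of a module correlate through
    the shared latent only).  Background genes are independent
    N(0, noise_sd^2).  Missing entries are planted uniformly at rate
    ``missing_frac``.
    """
    modules = list(modules)
    if sum(size for size, _ in modules) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = np.empty((n_genes, n_samples))
    row = 0
    for size, within_corr in modules:
        if not 0 <= within_corr < 1:
            raise ValueError("within_corr must be in [0, 1)")
        latent = rng.standard_normal(n_samples)
        # members x_i = latent + eps_i with Var(eps) chosen so that
        # corr(x_i, x_j) = 1/(1+Var(eps)) = within_corr
        if within_corr == 0:
            values[row : row + size] = rng.standard_normal((size, n_samples))
        else:
            eps_sd = math.sqrt(1.0 / within_corr - 1.0)
            values[row : row + size] = latent + eps_sd * rng.standard_normal(
                (size, n_samples)
            )
        row += size
    if row < n_genes:
        values[row:] = noise_sd * rng.standard_normal((n_genes - row, n_samples))
    if missing_frac > 0:
        mask = rng.uniform(size=values.shape) < missing_frac
        values = np.where(mask, np.nan, values)
    genes = [f"g{i+1}" for i in range(n_genes)]
    samples = [f"s{j+1}" for j in range(n_samples)]
    return pd.DataFrame(values, index=genes, columns=samples)


def random_network(n: int, edge_prob: float, seed: int) -> Network:
    """Erdős–Rényi G(n, p) network with string labels "1"… (test utility)."""
    rng = np.random.default_rng(seed)
    labels = [str(i + 1) for i in range(n)]
    net = Network(nodes=labels)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.uniform() < edge_prob:
                net.add_edge_unchecked(labels[a], labels[b])
    return net
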