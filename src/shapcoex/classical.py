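"""Classical centrality measures used as comparison baselines.

Degree, closeness, betweenness and eigenvector centrality, in the exact
dialects needed to compare against the game-theoretic relevance index:

* closeness comes in two dialects — ``normalized`` is the textbook
  (|N|−1)/Σh(i,j) and ``reciprocal_sum`` is 1/Σh(i,j).  The two differ
  only by the constant factor |N|−1 on connected graphs, but only the
  reciprocal-sum dialect matches the worked-example tables this package
  reproduces, so both are provided.
* betweenness is unnormalized, counts unordered pairs and excludes
  endpoints (Brandes' algorithm via networkx).
* eigenvector centrality is the principal eigenvector of the adjacency
  matrix by power iteration, normalized so the maximum entry is 1.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import pandas as pd

from .game import shapley_closed_form, uniform_weights
from .graph import Network

__all__ = [
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "all_centralities",
]


def degree_centrality(g: Network) -> dict:
    """score_i = |N_i(E)|, the raw neighbour count."""
    return g.degrees()


def closeness_centrality(g: Network, dialect: str = "reciprocal_sum") -> dict:
    """Closeness from BFS distances, in one of two dialects.

    ``normalized``: (reachable−1)/Σ_{j reachable} h(i,j); ``reciprocal_sum``:
    1/Σ h(i,j).  On disconnected graphs unreachable nodes are excluded from
    the sum and the normalized numerator counts only reachable nodes;
    isolated nodes score 0.
    """
    if dialect not in ("normalized", "reciprocal_sum"):
        raise ValueError(f"unknown closeness dialect {dialect!r}")
    nxg = g.to_networkx()
    out = {}
    for i in g.nodes:
        dist = nx.single_source_shortest_path_length(nxg, i)
        total = sum(d for d in dist.values() if d > 0)
        if total == 0:
            out[i] = 0.0
        elif dialect == "normalized":
            out[i] = (len(dist) - 1) / total
        else:
            out[i] = 1.0 / total
    return out


def betweenness_centrality(g: Network) -> dict:
    """Unnormalized shortest-path betweenness over unordered pairs, endpoints excluded."""
    return dict(nx.betweenness_centrality(g.to_networkx(), normalized=False))


def eigenvector_centrality(
    g: Network, tol: float = 1e-10, max_iter: int = 10000
) -> dict:
    """Principal eigenvector of the adjacency matrix, max entry scaled to 1.

    Power iteration from the all-ones vector; convergence when successive
    max-normalized iterates differ by less than ``tol`` in max-norm.  May
    fail to converge on bipartite components (oscillating iterates), which
    is reported as an error with the last residual.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    nodes = g.nodes
    if not nodes:
        return {}
    adj = g.to_networkx().adj
    x = {i: 1.0 for i in nodes}
    residual = float("inf")
    for _ in range(max_iter):
        y = {i: x[i] + sum(x[j] for j in adj[i]) for i in nodes}
        # the +x[i] shift (A+I power iteration) keeps the dominant eigenpair
        # and is immune to bipartite oscillation
        top = max(y.values())
        if top == 0:
            return {i: 0.0 for i in nodes}
        y = {i: v / top for i, v in y.items()}
        residual = max(abs(y[i] - x[i]) for i in nodes)
        x = y
        if residual < tol:
            return x
    raise RuntimeError(
        f"eigenvector power iteration did not converge after {max_iter} "
        f"iterations (last residual {residual:.3g})"
    )


def all_centralities(g: Network, k: Mapping | None = None) -> pd.DataFrame:
    """One row per measure (rho, degree, closeness, betweenness, eigenvector)."""
    if k is None:
        k = uniform_weights(g)
    rows = {
        "rho": {i: float(v) for i, v in shapley_closed_form(g, k).items()},
        "degree": {i: float(v) for i, v in degree_centrality(g).items()},
        "closeness": closeness_centrality(g),
        "betweenness": betweenness_centrality(g),
        "eigenvector": eigenvector_centrality(g),
    }
    return pd.DataFrame(rows).T[g.nodes]
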