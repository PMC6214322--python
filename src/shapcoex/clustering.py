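"""Greedy overlapping cluster detection by cohesiveness maximization.

A deterministic greedy grower in the style of cohesiveness-based
protein-complex detection: the cohesiveness of a node set S is

    f(S) = e_in(S) / (e_in(S) + e_bound(S) + penalty * |S|)

where e_in counts edges inside S, e_bound edges crossing the boundary,
and the penalty term models unobserved interactions.  Seeds are taken in
decreasing degree order; each seed is grown (or shrunk) one node at a
time by the move that most increases f, until no move improves it.
Near-duplicate clusters are merged by the overlap score
|A∩B|^2/(|A||B|), and clusters that are too small or too sparse are
discarded.  The pipeline equally accepts cluster files produced by
external tools, so this module is a self-contained default, not the only
route to cluster-based weights.
"""

from __future__ import annotations

import warnings
from typing import Iterable

from .graph import Network, node_sort_key

__all__ = [
    "greedy_cohesive_clusters",
    "cohesiveness",
    "cluster_density",
    "read_clusters",
    "write_clusters",
]


def _edge_counts(adj, S: set[str]) -> tuple[int, int]:
    e_in = 0
    e_bound = 0
    for i in S:
        for j in adj[i]:
            if j in S:
                e_in += 1
            else:
                e_bound += 1
    return e_in // 2, e_bound


def cohesiveness(g: Network, S: Iterable[str], penalty: float = 2.0) -> float:
    """f(S) = e_in / (e_in + e_bound + penalty·|S|); 0 for the empty set."""
    S = set(S)
    if not S:
        return 0.0
    e_in, e_bound = _edge_counts(g.to_networkx().adj, S)
    return e_in / (e_in + e_bound + penalty * len(S))


def cluster_density(g: Network, S: Iterable[str]) -> float:
    """Internal edge density e_in / (|S| choose 2); defined as 0 for |S| < 2."""
    S = set(S)
    if len(S) < 2:
        return 0.0
    e_in, _ = _edge_counts(g.to_networkx().adj, S)
    return e_in / (len(S) * (len(S) - 1) / 2)


def _grow_from_seed(adj, seed: str, penalty: float) -> set[str]:
    S = {seed}
    e_in, e_bound = 0, len(adj[seed])

    def f(ei: int, eb: int, size: int) -> float:
        denom = ei + eb + penalty * size
        return ei / denom if denom > 0 else 0.0

    current = f(e_in, e_bound, 1)
    while True:
        best = None  # (f, kind, label-key, node, new e_in, new e_bound)
        boundary = set()
        for i in S:
            boundary.update(j for j in adj[i] if j not in S)
        for cand in boundary:
            into = sum(1 for j in adj[cand] if j in S)
            ei = e_in + into
            eb = e_bound - into + (len(adj[cand]) - into)
            score = f(ei, eb, len(S) + 1)
            move = (score, 1, node_sort_key(cand), cand, ei, eb)
            if best is None or _better(move, best):
                best = move
        if len(S) > 1:
            for cand in S:
                into = sum(1 for j in adj[cand] if j in S)
                ei = e_in - into
                eb = e_bound - (len(adj[cand]) - into) + into
                score = f(ei, eb, len(S) - 1)
                move = (score, 0, node_sort_key(cand), cand, ei, eb)
                if best is None or _better(move, best):
                    best = move
        if best is None or best[0] <= current + 1e-12:
            return S
        score, kind, _, node, e_in, e_bound = best
        if kind == 1:
            S.add(node)
        else:
            S.remove(node)
        current = score


def _better(move, best) -> bool:
    # strictly higher cohesiveness wins; ties prefer additions, then the
    # smallest label (numeric-aware) — all deterministic
    if move[0] != best[0]:
        return move[0] > best[0]
    if move[1] != best[1]:
        return move[1] > best[1]
    return move[2] < best[2]


def _overlap_score(a: set[str], b: set[str]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def greedy_cohesive_clusters(
    g: Network,
    min_size: int = 5,
    min_density: float = 0.5,
    penalty: float = 2.0,
    merge_overlap: float = 0.8,
) -> list[set[str]]:
    """Detect overlapping cohesive clusters; deterministic for a given network.

    Returns clusters sorted by size descending (ties by smallest member
    label).  An empty list is a legal result.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not 0 <= min_density <= 1:
        raise ValueError("min_density must be in [0, 1]")
    adj = g.to_networkx().adj
    seeds = sorted(g.nodes, key=lambda n: (-len(adj[n]), node_sort_key(n)))
    covered: set[str] = set()
    raw: list[set[str]] = []
    for seed in seeds:
        if seed in covered or not adj[seed]:
            continue
        S = _grow_from_seed(adj, seed, penalty)
        if S not in raw:
            raw.append(S)
        covered.update(S)

    # merge highly overlapping clusters (union), iterating to a fixed point
    merged = True
    while merged:
        merged = False
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                if _overlap_score(raw[i], raw[j]) >= merge_overlap:
                    raw[i] = raw[i] | raw[j]
                    del raw[j]
                    merged = True
                    break
            if merged:
                break

    kept = [
        S
        for S in raw
        if len(S) >= min_size and cluster_density(g, S) >= min_density
    ]
    kept.sort(key=lambda S: (-len(S), min(node_sort_key(n) for n in S)))
    return kept


def read_clusters(path) -> list[set[str]]:
    """One cluster per line, tab-separated member ids; blank lines skipped."""
    clusters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            members = line.split("\t")
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}: duplicate members within cluster on line {lineno}",
                    stacklevel=2,
                )
            clusters.append(unique)
    return clusters


def write_clusters(clusters: Iterable[Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for cluster in clusters:
            fh.write("\t".join(sorted(cluster, key=node_sort_key)) + "\n")
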