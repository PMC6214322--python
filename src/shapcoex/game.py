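"""The coalitional game on a gene network and its Shapley-value relevance index.

Given a network <N, E> and an a-priori weight vector k, the game assigns
to each coalition S of genes the worth

    v(S) = sum of k_j over j in S ∪ N_S(E),        v(∅) = 0,

i.e. the total a-priori importance of the coalition together with
everything it directly touches.  The Shapley value of this game — the
average marginal contribution of each gene over all orderings — admits a
closed form

    rho_i = sum over j in N_i(E) ∪ {i} of k_j / (d_j(E) + 1),

computable in O(|N| + |E|).  ``shapley_bruteforce`` evaluates the Shapley
value from its definition with exact rational arithmetic and serves as the
independent oracle for the closed form on small graphs.

Weights may be any finite reals (the closed form is linear in k); the
three schemes used in practice are uniform weights, 0/1 key-gene
indicator weights, and cluster-membership counts.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping

from .graph import Network

__all__ = [
    "coalition_value",
    "shapley_bruteforce",
    "shapley_closed_form",
    "uniform_weights",
    "keygene_weights",
    "cluster_count_weights",
    "read_weights_tsv",
    "write_weights_tsv",
    "write_scores_tsv",
]

BRUTEFORCE_MAX_NODES = 12


def _check_weights(g: Network, k: Mapping[str, object]) -> None:
    for n in g.nodes:
        if n not in k:
            raise KeyError(f"weight missing for node {n!r}")


def coalition_value(g: Network, k: Mapping, S: Iterable[str]):
    """Worth v(S) = Σ_{j ∈ S ∪ N_S(E)} k_j, with v(∅) = 0 by convention."""
    S = set(S)
    if not S:
        return 0
    for i in S:
        if i not in g:
            raise KeyError(f"coalition member {i!r} is not a node of the network")
    covered = S | g.coalition_neighbors(S)
    return sum(k[j] for j in covered)


def shapley_bruteforce(g: Network, k: Mapping, exact: bool = True) -> dict:
    """Shapley value computed from the definition (oracle; exponential cost).

    Uses the subset-weighted form Σ_{S⊆N\\{i}} |S|!(n−|S|−1)!/n! · [v(S∪{i})−v(S)],
    equivalent to averaging marginal vectors over all n! orders.  With
    ``exact`` the accumulation is in rational arithmetic (weights are
    converted via :class:`fractions.Fraction`), so small-fixture values are
    bit-exact.
    """
    nodes = g.nodes
    n = len(nodes)
    if n > BRUTEFORCE_MAX_NODES:
        raise ValueError(
            f"brute-force Shapley is limited to {BRUTEFORCE_MAX_NODES} nodes "
            f"(got {n}); use shapley_closed_form"
        )
    _check_weights(g, k)
    if exact:
        kk = {i: Fraction(k[i]) for i in nodes}
        zero = Fraction(0)
    else:
        kk = {i: float(k[i]) for i in nodes}
        zero = 0.0

    # cache v over all 2^n coalitions, indexed by frozenset
    values: dict[frozenset, object] = {frozenset(): zero}
    for r in range(1, n + 1):
        for S in combinations(nodes, r):
            values[frozenset(S)] = coalition_value(g, kk, S)

    fact = [math.factorial(r) for r in range(n + 1)]
    out = {}
    for i in nodes:
        others = [x for x in nodes if x != i]
        acc = zero
        for r in range(n):
            coeff = Fraction(fact[r] * fact[n - r - 1], fact[n])
            if not exact:
                coeff = float(coeff)
            for S in combinations(others, r):
                fs = frozenset(S)
                acc += coeff * (values[fs | {i}] - values[fs])
        out[i] = acc
    return out


def shapley_closed_form(g: Network, k: Mapping, exact: bool = False) -> dict:
    """rho_i = Σ_{j ∈ N_i ∪ {i}} k_j/(d_j+1) for every node, in O(|N|+|E|).

    ``exact`` switches to rational arithmetic so printed fractions are
    reproduced exactly; the default float mode is what large networks use.
    """
    _check_weights(g, k)
    deg = g.degrees()
    if exact:
        share = {j: Fraction(k[j]) / (deg[j] + 1) for j in g.nodes}
    else:
        share = {j: float(k[j]) / (deg[j] + 1) for j in g.nodes}
    nbrs = g.to_networkx().adj
    out = {}
    for i in g.nodes:
        acc = share[i]
        for j in nbrs[i]:
            acc += share[j]
        out[i] = acc
    return out


def uniform_weights(g: Network) -> dict:
    """k_i = 1 for every gene (no a-priori knowledge)."""
    return {i: 1 for i in g.nodes}


def keygene_weights(g: Network, key_set: Iterable[str], strict: bool = False) -> dict:
    """Indicator weights: k_i = 1 for key-genes, 0 otherwise.

    Key ids absent from the network (e.g. filtered out during
    preprocessing) are reported with a warning, or raise in strict mode.
    """
    key_set = set(key_set)
    missing = sorted(i for i in key_set if i not in g)
    if missing:
        msg = f"key-gene ids not in the network: {missing}"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg, stacklevel=2)
    return {i: (1 if i in key_set else 0) for i in g.nodes}


def cluster_count_weights(g: Network, clusters, strict: bool = False) -> dict:
    """k_i = number of clusters gene i belongs to; un-clustered genes get 0."""
    counts = {i: 0 for i in g.nodes}
    missing = set()
    for cluster in clusters:
        for i in cluster:
            if i in counts:
                counts[i] += 1
            else:
                missing.add(i)
    if missing:
        msg = f"cluster members not in the network: {sorted(missing)}"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg, stacklevel=2)
    return counts


# -- I/O ------------------------------------------------------------------

def read_weights_tsv(path) -> dict:
    """Two-column TSV: gene id, weight."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, value = line.split("\t")[:2]
            out[gene] = float(value)
    return out


def write_weights_tsv(k: Mapping, path) -> None:
    with open(path, "w") as fh:
        for gene, value in k.items():
            fh.write(f"{gene}\t{value}\n")


def write_scores_tsv(scores: Mapping, path, name: str = "score") -> None:
    """Gene id, score, rank (ties share the minimum rank)."""
    items = list(scores.items())
    by_score = sorted(items, key=lambda kv: -float(kv[1]))
    ranks: dict[str, int] = {}
    for pos, (gene, value) in enumerate(by_score, start=1):
        prev = by_score[pos - 2] if pos > 1 else None
        if prev is not None and float(prev[1]) == float(value):
            ranks[gene] = ranks[prev[0]]
        else:
            ranks[gene] = pos
    with open(path, "w") as fh:
        fh.write(f"gene\t{name}\trank\n")
        for gene, value in items:
            fh.write(f"{gene}\t{float(value):.12g}\t{ranks[gene]}\n")
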