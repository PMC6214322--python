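"""Evaluation machinery for comparing relevance measures on a network.

Top-fraction gene selection, selection-overlap and score-correlation
tables, neighbour coverage of a selection, removal profiles (how the
network fragments when a selection is deleted) and the threshold
robustness workflow (how stable the top list is across correlation
cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coexpression import build_network
from .game import shapley_closed_form, uniform_weights
from .graph import Network, node_sort_key

__all__ = [
    "SelectionList",
    "RemovalProfile",
    "top_fraction",
    "overlap_table",
    "score_correlation_table",
    "neighbor_coverage",
    "removal_profile",
    "threshold_robustness",
]


@dataclass
class SelectionList:
    """The top ceil(fraction·|N|) nodes of one measure, in rank order."""

    measure: str
    nodes: list[str]
    fraction: float

    def __len__(self) -> int:
        return len(self.nodes)

    def as_set(self) -> set[str]:
        return set(self.nodes)


@dataclass
class RemovalProfile:
    """Component-size distribution of the network after deleting a node set."""

    size_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return sum(self.size_histogram.values())

    @property
    def n_singletons(self) -> int:
        return self.size_histogram.get(1, 0)

    @property
    def n_remaining_nodes(self) -> int:
        return sum(size * count for size, count in self.size_histogram.items())


def top_fraction(
    scores: Mapping[str, float], fraction: float, measure: str = "score"
) -> SelectionList:
    """Select the ceil(fraction·|N|) highest-scoring nodes.

    Ties at the cutoff are broken by ascending node label (numeric-aware),
    so the selection is deterministic and independent of input order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = math.ceil(fraction * len(scores))
    ranked = sorted(scores, key=lambda i: (-float(scores[i]), node_sort_key(i)))
    return SelectionList(measure=measure, nodes=ranked[:m], fraction=fraction)


def overlap_table(
    lists: Iterable[SelectionList], scores: Mapping[str, Mapping[str, float]] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pairwise |list_p ∩ list_q| counts, plus (optionally) the Pearson
    correlation of the two measures' scores restricted to each intersection.

    ``scores`` maps measure name -> full score vector; when given, the
    second returned table holds the parenthesized correlations (NaN when
    the intersection has fewer than 2 genes or either restriction is
    constant).
    """
    lists = list(lists)
    names = [sl.measure for sl in lists]
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    corr = pd.DataFrame(np.nan, index=names, columns=names) if scores is not None else None
    for p in lists:
        for q in lists:
            common = p.as_set() & q.as_set()
            counts.loc[p.measure, q.measure] = len(common)
            if scores is not None and len(common) >= 2:
                genes = sorted(common, key=node_sort_key)
                x = np.array([float(scores[p.measure][i]) for i in genes])
                y = np.array([float(scores[q.measure][i]) for i in genes])
                if x.std() > 0 and y.std() > 0:
                    corr.loc[p.measure, q.measure] = np.corrcoef(x, y)[0, 1]
    return counts, corr


def score_correlation_table(scores: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Pairwise Pearson correlations of full score vectors (NaN for constant ones)."""
    names = list(scores)
    genes = list(next(iter(scores.values())))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    vectors = {
        name: np.array([float(scores[name][g]) for g in genes]) for name in names
    }
    for p in names:
        for q in names:
            x, y = vectors[p], vectors[q]
            if x.std() > 0 and y.std() > 0:
                mat.loc[p, q] = np.corrcoef(x, y)[0, 1]
    return mat


def neighbor_coverage(g: Network, S: Iterable[str]) -> int:
    """|N_S(E) \\ S|: distinct genes outside S directly connected to S."""
    S = set(S)
    if not S:
        return 0
    return len(g.coalition_neighbors(S) - S)


def removal_profile(g: Network, S: Iterable[str]) -> RemovalProfile:
    """Component-size histogram of the network with the node set S deleted."""
    parts = g.remove_nodes(S).connected_components()
    hist: dict[int, int] = {}
    for size in parts.sizes:
        hist[size] = hist.get(size, 0) + 1
    return RemovalProfile(size_histogram=hist)


def threshold_robustness(
    c: pd.DataFrame,
    thresholds: Iterable[float],
    fraction: float = 0.05,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Stability of the top-fraction Shapley selection across cutoffs.

    For each threshold: build the network, compute the relevance index
    (uniform weights unless given) and select the top fraction; the
    returned matrix holds pairwise overlap counts between the selections.
    """
    thresholds = list(thresholds)
    selections = {}
    for t in thresholds:
        net = build_network(c, t)
        k = weights if weights is not None else uniform_weights(net)
        rho = shapley_closed_form(net, k)
        selections[t] = top_fraction(rho, fraction, measure=str(t)).as_set()
    table = pd.DataFrame(
        0, index=[str(t) for t in thresholds], columns=[str(t) for t in thresholds],
        dtype=int,
    )
    for a in thresholds:
        for b in thresholds:
            table.loc[str(a), str(b)] = len(selections[a] & selections[b])
    return table
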