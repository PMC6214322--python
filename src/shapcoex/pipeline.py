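"""End-to-end analysis orchestration: preprocess -> network -> weights ->
relevance + classical centralities -> selections -> comparison tables.

The configuration is a flat key=value structure (file or CLI flags); the
result bundle carries every intermediate artifact so callers can write or
inspect any stage.  Re-running the same configuration is byte-reproducible.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import coexpression, clustering, compare, game
from .classical import all_centralities
from .graph import Network, load_edge_list

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "make_weights"]

MEASURES = ("rho", "degree", "closeness", "betweenness", "eigenvector")


@dataclass
class AnalysisConfig:
    """Settings for a full relevance analysis.

    ``weight_scheme`` is one of ``uniform``, ``keygenes:<path>``,
    ``clusters:<path>`` or ``cluster-auto`` (run the built-in overlapping
    clusterer and use membership counts as weights).
    """

    expression_path: str | None = None
    network_path: str | None = None
    max_missing_frac: float = 0.8
    min_sd: float = 0.5
    corr_threshold: float = 0.8
    use_absolute: bool = False
    weight_scheme: str = "uniform"
    selection_fraction: float = 0.05
    closeness_dialect: str = "reciprocal_sum"
    cluster_min_size: int = 5
    cluster_min_density: float = 0.5
    verbose: bool = False

    def validate(self) -> None:
        if (self.expression_path is None) == (self.network_path is None):
            raise ValueError("provide exactly one of expression_path / network_path")
        for name in ("max_missing_frac", "selection_fraction", "cluster_min_density"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")


@dataclass
class AnalysisResult:
    network: Network
    weights: dict
    scores: dict[str, dict]
    selections: dict[str, compare.SelectionList]
    overlap_counts: pd.DataFrame
    overlap_correlations: pd.DataFrame
    score_correlations: pd.DataFrame
    neighbor_coverages: dict[str, int]
    removal_profiles: dict[str, compare.RemovalProfile]
    clusters: list[set[str]] | None = None
    config: AnalysisConfig | None = None


def make_weights(net: Network, cfg: AnalysisConfig):
    scheme = cfg.weight_scheme
    clusters = None
    if scheme == "uniform":
        k = game.uniform_weights(net)
    elif scheme.startswith("keygenes:"):
        path = scheme.split(":", 1)[1]
        with open(path) as fh:
            keys = [line.strip() for line in fh if line.strip()]
        k = game.keygene_weights(net, keys)
    elif scheme.startswith("clusters:"):
        clusters = clustering.read_clusters(scheme.split(":", 1)[1])
        k = game.cluster_count_weights(net, clusters)
    elif scheme == "cluster-auto":
        clusters = clustering.greedy_cohesive_clusters(
            net, min_size=cfg.cluster_min_size, min_density=cfg.cluster_min_density
        )
        k = game.cluster_count_weights(net, clusters)
    else:
        path = scheme  # plain path to a weights TSV
        k = game.read_weights_tsv(path)
    return k, clusters


def run_analysis(cfg: AnalysisConfig) -> AnalysisResult:
    cfg.validate()
    log = _logger(cfg.verbose)

    if cfg.expression_path is not None:
        log("preprocess: reading expression matrix")
        m = coexpression.read_expression_tsv(cfg.expression_path)
        m = coexpression.preprocess(m, cfg.max_missing_frac, cfg.min_sd)
        log(f"preprocess: {m.shape[0]} genes x {m.shape[1]} samples retained")
        c = coexpression.pearson_matrix(m)
        net = coexpression.build_network(c, cfg.corr_threshold, cfg.use_absolute)
    else:
        net = load_edge_list(cfg.network_path)
    log(f"network: {net.n_nodes} nodes, {net.n_edges} edges")

    k, clusters = make_weights(net, cfg)

    table = all_centralities(net, k)
    if cfg.closeness_dialect != "reciprocal_sum":
        from .classical import closeness_centrality

        table.loc["closeness"] = pd.Series(
            closeness_centrality(net, cfg.closeness_dialect)
        )
    scores = {measure: table.loc[measure].to_dict() for measure in MEASURES}

    selections = {
        measure: compare.top_fraction(scores[measure], cfg.selection_fraction, measure)
        for measure in MEASURES
    }
    counts, corrs = compare.overlap_table(selections.values(), scores)
    score_corrs = compare.score_correlation_table(scores)
    coverages = {
        measure: compare.neighbor_coverage(net, sel.as_set())
        for measure, sel in selections.items()
    }
    profiles = {
        measure: compare.removal_profile(net, sel.as_set())
        for measure, sel in selections.items()
    }
    log("analysis complete")
    return AnalysisResult(
        network=net,
        weights=k,
        scores=scores,
        selections=selections,
        overlap_counts=counts,
        overlap_correlations=corrs,
        score_correlations=score_corrs,
        neighbor_coverages=coverages,
        removal_profiles=profiles,
        clusters=clusters,
        config=cfg,
    )


def _logger(verbose: bool):
    t0 = time.monotonic()

    def log(msg: str) -> None:
        if verbose:
            print(f"[{time.monotonic() - t0:7.2f}s] {msg}", file=sys.stderr)

    return log
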