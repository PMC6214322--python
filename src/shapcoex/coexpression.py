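"""Co-expression network construction from an expression matrix.

The pipeline mirrors standard microarray preprocessing: drop genes with
too many missing values, impute the rest with the row mean, drop flat
(low standard deviation) profiles, compute the gene-gene Pearson
correlation matrix, and connect two genes when their correlation exceeds
a fixed threshold (strictly).  All boundary comparisons are strict
("greater than", "smaller than", "higher than"); ties at a boundary are
therefore kept/excluded accordingly and this is documented behaviour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import Network

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "filter_missing",
    "impute_row_mean",
    "filter_low_sd",
    "pearson_matrix",
    "build_network",
    "write_correlation_tsv",
    "read_correlation_tsv",
    "preprocess",
]

# An expression matrix is a pandas DataFrame: rows = genes (unique ids in the
# index), columns = samples, NaN = missing.  A correlation matrix is a square
# DataFrame with unit diagonal, symmetric to machine precision.


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene id, header row of sample ids.

    Empty fields and "NA" are missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    return df.astype(float)


def write_expression_tsv(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", na_rep="NA")


def filter_missing(m: pd.DataFrame, max_missing_frac: float = 0.8) -> pd.DataFrame:
    """Drop genes whose fraction of missing entries is strictly above the cutoff."""
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.isna().mean(axis=1)
    return m.loc[frac <= max_missing_frac]


def impute_row_mean(m: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing entry by the mean of its own gene's observed values."""
    all_missing = m.isna().all(axis=1)
    if all_missing.any():
        bad = m.index[all_missing].tolist()
        raise ValueError(f"rows with no observed values (filter first): {bad}")
    return m.T.fillna(m.mean(axis=1)).T


def filter_low_sd(m: pd.DataFrame, min_sd: float = 0.5, ddof: int = 1) -> pd.DataFrame:
    """Drop genes whose sample standard deviation is strictly below ``min_sd``."""
    if m.isna().any().any():
        raise ValueError("filter_low_sd expects an imputed (complete) matrix")
    sd = m.std(axis=1, ddof=ddof)
    return m.loc[sd >= min_sd]


def pearson_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix (symmetric, unit diagonal)."""
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    if m.isna().any().any():
        raise ValueError("pearson_matrix expects a complete matrix")
    values = m.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = m.index[sd == 0].tolist()
        raise ValueError(f"zero-variance gene profiles: {bad}")
    r = np.corrcoef(values)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(r, index=m.index, columns=m.index)


def build_network(
    c: pd.DataFrame, threshold: float, use_absolute: bool = False
) -> Network:
    """Connect genes i, j when their correlation strictly exceeds ``threshold``.

    All genes remain as (possibly isolated) nodes.  With ``use_absolute``
    the comparison is on \\|r\\|, the convention of many co-expression
    pipelines; the default thresholds the raw (signed) correlation.
    """
    genes = [str(g) for g in c.index]
    r = c.to_numpy(dtype=float)
    if use_absolute:
        r = np.abs(r)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = r[iu, ju] > threshold
    net = Network(nodes=genes)
    for i, j in zip(iu[mask], ju[mask]):
        net.add_edge_unchecked(genes[i], genes[j])
    return net


def write_correlation_tsv(c: pd.DataFrame, path) -> None:
    c.to_csv(path, sep="\t", float_format="%.17g")


def read_correlation_tsv(path) -> pd.DataFrame:
    c = pd.read_csv(path, sep="\t", index_col=0)
    c.index = c.index.astype(str)
    c.columns = c.columns.astype(str)
    return c


def preprocess(
    m: pd.DataFrame,
    max_missing_frac: float = 0.8,
    min_sd: float = 0.5,
) -> pd.DataFrame:
    """Full preprocessing chain: missing filter -> row-mean imputation -> SD filter."""
    return filter_low_sd(impute_row_mean(filter_missing(m, max_missing_frac)), min_sd)
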