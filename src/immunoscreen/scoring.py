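"""Single-sample tumor-immunity scores.

Three signature scores orient all downstream filtering — higher always means a
stronger anti-tumor immune state:

* ``immune`` — an ssGSEA-style rank-weighted enrichment of an immune
  infiltrate gene set in the sample's expression profile;
* ``CYT`` — cytolytic activity, the geometric mean of *GZMA* and *PRF1*
  expression on the linear scale;
* ``MHC`` — antigen-presentation capacity, the mean per-gene z-scored
  expression of the MHC machinery set.

The ssGSEA statistic for a gene set S in one sample: rank all genes by
descending expression (ties broken lexicographically by symbol); walking down
the ranked list accumulate

    score = sum_i [ P_in(i) - P_out(i) ]

where P_in(i) is the weighted fraction of S seen by position i (weights =
(descending rank value)^alpha, alpha = 0.25) and P_out(i) the unweighted
fraction of genes outside S. A set whose genes sit at the top of the profile
scores high.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ssgsea_score",
    "cyt_score",
    "mhc_score",
    "feature_abundance",
    "signature_scores",
]


def _ranked_order(expr: pd.Series) -> pd.Series:
    """Genes sorted by descending expression, ties by gene symbol."""
    df = pd.DataFrame({"v": expr.to_numpy(), "g": expr.index})
    df = df.sort_values(["v", "g"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["v"].to_numpy(), index=df["g"].to_numpy())


def ssgsea_score(expr: pd.Series, gene_set: list[str], alpha: float = 0.25) -> float:
    """ssGSEA-style enrichment of ``gene_set`` in one sample's profile."""
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError(f"gene set has no overlap with the expression vector")
    ranked = _ranked_order(expr)
    n = len(ranked)
    in_set = np.isin(ranked.index.to_numpy(), list(present))
    # descending rank value: top gene gets n, bottom gets 1
    rank_value = np.arange(n, 0, -1, dtype=float)
    w = np.where(in_set, rank_value ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    n_out = n - in_set.sum()
    if n_out == 0:
        p_out = np.zeros(n)
    else:
        p_out = np.cumsum(~in_set) / n_out
    return float(np.sum(p_in - p_out))


def cyt_score(expr_gzma: float, expr_prf1: float, pseudocount: float = 0.01) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 (linear scale)."""
    if expr_gzma < 0 or expr_prf1 < 0:
        raise ValueError("cyt_score expects non-negative linear-scale expression")
    return float(np.sqrt((expr_gzma + pseudocount) * (expr_prf1 + pseudocount)))


def _zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def mhc_score(expr_z: pd.Series, mhc_set: list[str]) -> float:
    """Mean z-scored expression over the MHC set for one sample.

    ``expr_z`` is the sample's column from a per-gene z-scored matrix.
    """
    present = [g for g in mhc_set if g in expr_z.index]
    if not present:
        raise ValueError("MHC set has no overlap with the expression vector")
    return float(expr_z.loc[present].mean())


def feature_abundance(expr: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-sample abundance of immune-related features (samples x features).

    Feature score = mean per-gene z-scored expression of the feature's gene
    set; a single-gene feature reduces to that gene's z. Features whose gene
    set has no overlap with the matrix are dropped with a warning. The
    catalog's polarity/category columns are untouched (carried by index).
    """
    if len(catalog) == 0:
        raise ValueError("feature catalog is empty")
    z = _zscore_rows(expr)
    cols = {}
    for feat, row in catalog.iterrows():
        present = [g for g in row["genes"] if g in z.index]
        if not present:
            logger.warning("feature_abundance: feature %r has no gene overlap; dropped", feat)
            continue
        cols[feat] = z.loc[present].mean(axis=0)
    return pd.DataFrame(cols, index=expr.columns)


def signature_scores(
    expr: pd.DataFrame,
    gene_sets,
    alpha: float = 0.25,
    log_base: float = 2.0,
    pseudocount: float = 0.01,
    cyt_log: bool = True,
) -> pd.DataFrame:
    """Compute the immune / CYT / MHC signature scores for every sample.

    ``expr`` is log-scale (genes x samples); CYT is computed on the linear
    scale ``log_base**expr`` and, with ``cyt_log=True`` (default), reported
    back on the log scale: the geometric mean of expression is log-normal
    across samples, and downstream linear regressions behave far better on
    its logarithm (the status coefficient then reads as a log-fold effect on
    cytolytic activity). Returns a samples x {immune, CYT, MHC} frame.
    """
    immune_set = gene_sets["immune"]
    cyt_set = gene_sets["CYT"]
    mhc_set = gene_sets["MHC"]
    missing_cyt = [g for g in cyt_set if g not in expr.index]
    if missing_cyt:
        raise ValueError(f"CYT genes missing from expression matrix: {missing_cyt}")
    z = _zscore_rows(expr)
    linear = np.power(log_base, expr.loc[cyt_set])
    out = pd.DataFrame(index=expr.columns, columns=["immune", "CYT", "MHC"], dtype=float)
    for s in expr.columns:
        out.at[s, "immune"] = ssgsea_score(expr[s], immune_set, alpha=alpha)
        out.at[s, "CYT"] = cyt_score(
            float(linear.at[cyt_set[0], s]), float(linear.at[cyt_set[1], s]),
            pseudocount=pseudocount)
        out.at[s, "MHC"] = mhc_score(z[s], mhc_set)
    if cyt_log:
        out["CYT"] = np.log(out["CYT"]) / np.log(log_base)
    return out
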