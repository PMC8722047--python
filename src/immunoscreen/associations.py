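"""Covariate-adjusted association screens and the filters built on them.

Every analysis here follows the same template: regress a per-sample readout
(signature score, feature abundance, expression, or a binary status) on a
gene's binary functional status, adjust for cancer type, correct the whole
family of tests with Benjamini-Hochberg, and apply a sign-plus-significance
rule. The individual filters differ only in the readout and the rule:

* three-signature filter — a sensitizer is *functional* iff its inactivation
  is significantly negatively associated with all of immune, CYT and MHC
  scores (resistors: positive with all three);
* subtype-specific genes — one-vs-rest logistic regression of status on
  immune-subtype membership, flagged at adj. P < 0.05 and log2 OR > 1.5;
* S-/R-related features — per cancer type, count features whose association
  direction matches the gene's role and the feature's polarity;
* OG/TSG network — Wilcoxon rank-sum of regulator expression between driver
  event and non-event samples, edges at adj. P < 0.05 and |lfc| > 0.25;
* proliferation independence — mean CERES-style dependency in [-0.25, 0.25].
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "fit_linear_association",
    "fit_logistic_association",
    "associate_signatures",
    "filter_functional_regulators",
    "subtype_specific_genes",
    "associate_features",
    "count_related_features",
    "og_tsg_network",
    "proliferation_independent",
]

IMMUNE_SUBTYPES = ("C1", "C2", "C3", "C4", "C5", "C6")


def _status_frame(status) -> pd.DataFrame:
    """Accept a StatusMatrix or a genes x samples binary DataFrame."""
    if isinstance(status, pd.DataFrame):
        return status
    values = getattr(status, "values", None)
    if isinstance(values, pd.DataFrame):
        return values
    raise TypeError("status must be a StatusMatrix or genes x samples DataFrame")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved.

    Missing entries pass through as NaN and do not count toward the family
    size. Values outside [0, 1] raise ValueError.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _design_with_dummies(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    """Dummy-code categorical covariates; reference = most frequent level."""
    import statsmodels.api as sm

    X = pd.DataFrame(index=index)
    if covariates is not None:
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                ref = s.value_counts().idxmax()
                for level in sorted(s.unique()):
                    if level == ref:
                        continue
                    X[f"{col}[{level}]"] = (s == level).astype(float)
            else:
                X[col] = s.astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_linear_association(
    y: pd.Series,
    status,
    covariates: pd.DataFrame | None = None,
    min_events: int = 5,
) -> dict:
    """OLS of a continuous score on a binary status plus covariate dummies.

    Returns dict(coef, p, n, flag) where coef is the status slope and p the
    two-sided t-test on it. A status vector with fewer than ``min_events``
    members in either class yields a record flagged "insufficient_events"
    with missing p. A constant response returns coef 0, p 1 by contract.
    """
    import statsmodels.api as sm

    status = pd.Series(np.asarray(status, dtype=float), index=y.index)
    n = len(y)
    n1 = int(status.sum())
    if min(n1, n - n1) < min_events:
        return {"coef": np.nan, "p": np.nan, "n": n, "flag": "insufficient_events"}
    if np.ptp(y.to_numpy()) == 0.0:
        return {"coef": 0.0, "p": 1.0, "n": n, "flag": "constant_response"}
    X = _design_with_dummies(covariates, y.index)
    X.insert(1, "status", status)
    fit = sm.OLS(y.astype(float), X).fit()
    return {"coef": float(fit.params["status"]), "p": float(fit.pvalues["status"]),
            "n": n, "flag": "ok"}


def fit_logistic_association(
    outcome,
    predictor,
    index=None,
    min_events: int = 5,
    maxiter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Logistic regression of a binary outcome on one binary predictor.

    Returns dict(log2_or, p, n, flag); perfect separation or non-convergence
    is flagged with missing p rather than reporting infinite odds ratios.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    n = y.size
    if y.sum() < min_events or (1 - y).sum() < min_events:
        return {"log2_or": np.nan, "p": np.nan, "n": n, "flag": "insufficient_events"}
    # a 2x2 margin with an empty cell is perfect separation for this design
    tab = np.array([[(y[x == a] == b).sum() for b in (0, 1)] for a in (0, 1)])
    if (tab == 0).any():
        return {"log2_or": np.nan, "p": np.nan, "n": n, "flag": "separation"}
    X = sm.add_constant(pd.DataFrame({"x": x}))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, tol=tol)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return {"log2_or": np.nan, "p": np.nan, "n": n, "flag": "separation"}
    if not fit.mle_retvals.get("converged", True):
        return {"log2_or": np.nan, "p": np.nan, "n": n, "flag": "non_convergence"}
    coef = float(fit.params["x"])
    return {"log2_or": coef / np.log(2.0), "p": float(fit.pvalues["x"]),
            "n": n, "flag": "ok"}


def associate_signatures(
    scores: pd.DataFrame,
    status,
    annotations: pd.DataFrame,
    covariate_cols: tuple[str, ...] = ("cancer_type",),
    min_events: int = 5,
) -> pd.DataFrame:
    """Regress every signature score on every gene's status, BH over the family.

    ``scores``: samples x signatures; ``status``: a StatusMatrix or its binary
    genes x samples frame. One BH family covers all gene x signature tests.
    """
    values = _status_frame(status)
    samples = scores.index
    cov = annotations.loc[samples, list(covariate_cols)] if covariate_cols else None
    rows = []
    for gene in values.index:
        st = values.loc[gene].reindex(samples)
        for sig in scores.columns:
            res = fit_linear_association(scores[sig], st, cov, min_events=min_events)
            rows.append((gene, sig, "signature", res["coef"], res["p"], res["n"], res["flag"]))
    table = pd.DataFrame(rows, columns=["gene", "target", "target_class",
                                        "coef", "p", "n", "flag"])
    table["adj_p"] = bh_adjust(table["p"])
    return table


def filter_functional_regulators(
    assoc: pd.DataFrame,
    catalog,
    alpha: float = 0.05,
    signatures: tuple[str, ...] = ("immune", "CYT", "MHC"),
):
    """Keep regulators whose status associates consistently with all signatures.

    A sensitizer survives iff all three signature associations have
    adj_p < alpha and coef < 0 (inactivation lowers immune activity); a
    resistor iff all three have adj_p < alpha and coef > 0. Catalog genes
    lacking a record for any signature are excluded and logged.
    """
    from .screens import RegulatorCatalog

    roles = catalog.roles() if hasattr(catalog, "roles") else dict(catalog)
    kept_rows = []
    for gene, role in roles.items():
        sub = assoc[(assoc["gene"] == gene) & (assoc["target"].isin(signatures))]
        if len(sub) < len(signatures) or set(sub["target"]) != set(signatures):
            logger.warning("filter_functional_regulators: %s lacks records for all "
                           "signatures; excluded", gene)
            continue
        sig_ok = (sub["adj_p"] < alpha).all()
        if role == "sensitizer":
            direction_ok = (sub["coef"] < 0).all()
        else:
            direction_ok = (sub["coef"] > 0).all()
        if sig_ok and direction_ok:
            kept_rows.append((gene, role))
    table = pd.DataFrame(kept_rows, columns=["gene", "role"]).set_index("gene")
    table["support"] = [[] for _ in range(len(table))]
    table["n_screens"] = 0
    if hasattr(catalog, "table"):
        common = table.index.intersection(catalog.table.index)
        table.loc[common, "support"] = catalog.table.loc[common, "support"]
        table.loc[common, "n_screens"] = catalog.table.loc[common, "n_screens"]
    return RegulatorCatalog(table=table)


def subtype_specific_genes(
    status,
    subtypes: pd.Series,
    alpha: float = 0.05,
    lor_cut: float = 1.5,
    min_events: int = 5,
) -> pd.DataFrame:
    """One-vs-rest logistic detection of immune-subtype-specific event patterns.

    For every gene x subtype pair, regress the gene's binary status on the
    subtype-membership indicator; flag the pair specific iff BH-adjusted
    p < alpha and log2 OR > lor_cut. Samples without a subtype label are
    excluded. BH spans all gene x subtype tests.
    """
    values = _status_frame(status)
    labelled = subtypes.dropna()
    rows = []
    for gene in values.index:
        st = values.loc[gene].reindex(labelled.index)
        for sub in sorted(labelled.unique()):
            member = (labelled == sub).astype(float)
            res = fit_logistic_association(st, member, min_events=min_events)
            rows.append((gene, sub, "subtype", res["log2_or"], res["p"],
                         res["n"], res["flag"]))
    table = pd.DataFrame(rows, columns=["gene", "target", "target_class",
                                        "log2_or", "p", "n", "flag"])
    table["adj_p"] = bh_adjust(table["p"])
    table["specific"] = (table["adj_p"] < alpha) & (table["log2_or"] > lor_cut)
    table["specific"] = table["specific"].fillna(False)
    return table


def associate_features(
    feature_scores: pd.DataFrame,
    status,
    annotations: pd.DataFrame,
    min_events: int = 3,
) -> pd.DataFrame:
    """Per-cancer-type association of feature abundance with gene status.

    Associations are computed within each cancer type separately (stratified,
    no covariates) and BH-corrected as one family across all
    gene x feature x cancer tests.
    """
    values = _status_frame(status)
    samples = feature_scores.index
    cancer = annotations.loc[samples, "cancer_type"]
    rows = []
    for ct, idx in samples.to_series().groupby(cancer):
        block = feature_scores.loc[idx.index]
        for gene in values.index:
            st = values.loc[gene].reindex(idx.index)
            for feat in feature_scores.columns:
                res = fit_linear_association(block[feat], st, None, min_events=min_events)
                rows.append((gene, feat, "feature", ct, res["coef"], res["p"],
                             res["n"], res["flag"]))
    table = pd.DataFrame(rows, columns=["gene", "target", "target_class",
                                        "cancer_type", "coef", "p", "n", "flag"])
    table["adj_p"] = bh_adjust(table["p"])
    return table


def count_related_features(
    assoc: pd.DataFrame,
    roles: dict[str, str],
    polarity: pd.Series,
    alpha: float = 0.05,
    per_cancer: bool = False,
) -> pd.DataFrame:
    """Count S-/R-related features per gene (summed over cancer types).

    An S-related feature of a sensitizer is an anti-tumor feature with a
    significant negative association (immune activity drops when the gene is
    inactivated) or a pro-tumor feature with a significant positive one.
    R-related features of resistors mirror this with flipped signs.
    ``polarity`` maps feature -> {anti_tumor, pro_tumor}.
    """
    df = assoc.copy()
    df["polarity"] = df["target"].map(polarity)
    df["role"] = df["gene"].map(roles)
    sig = df["adj_p"] < alpha
    sens = df["role"] == "sensitizer"
    anti = df["polarity"] == "anti_tumor"
    related = sig & (
        (sens & ((anti & (df["coef"] < 0)) | (~anti & (df["coef"] > 0))))
        | (~sens & ((anti & (df["coef"] > 0)) | (~anti & (df["coef"] < 0))))
    )
    df["related"] = related.fillna(False)
    group_cols = ["gene", "cancer_type"] if per_cancer else ["gene"]
    counts = df.groupby(group_cols)["related"].sum().astype(int).reset_index()
    counts = counts.rename(columns={"related": "n_related"})
    counts["role"] = counts["gene"].map(roles)
    return counts


def og_tsg_network(
    expr: pd.DataFrame,
    driver_status,
    driver_classes: dict[str, str],
    roles: dict[str, str],
    alpha: float = 0.05,
    lfc_cut: float = 0.25,
    min_events: int = 5,
) -> pd.DataFrame:
    """Infer regulator <- OG/TSG edges from expression shifts upon driver events.

    For each (regulator, driver) pair the regulator's log expression is
    compared between driver-event and non-event samples: lfc = mean difference,
    p = two-sided Wilcoxon rank-sum, BH across all pairs. A sensitizer-driver
    edge requires significant down-regulation (lfc < -lfc_cut); a
    resistor-driver edge significant up-regulation (lfc > +lfc_cut).
    ``driver_classes`` maps driver -> {"OG", "TSG"}.
    """
    dvalues = _status_frame(driver_status)
    samples = expr.columns
    rows = []
    for driver in dvalues.index:
        ev = dvalues.loc[driver].reindex(samples).astype(bool).to_numpy()
        if ev.sum() < min_events or (~ev).sum() < min_events:
            continue
        for reg, role in roles.items():
            if reg not in expr.index:
                continue
            x = expr.loc[reg].to_numpy(dtype=float)
            a, b = x[ev], x[~ev]
            lfc = float(a.mean() - b.mean())
            try:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            except ValueError:  # all-identical values
                p = 1.0
            rows.append((reg, role, driver, driver_classes.get(driver, "NA"), lfc, p))
    table = pd.DataFrame(rows, columns=["regulator", "role", "driver",
                                        "driver_class", "lfc", "p"])
    if len(table) == 0:
        table["adj_p"] = []
        table["edge"] = []
        return table
    table["adj_p"] = bh_adjust(table["p"])
    sens = table["role"] == "sensitizer"
    table["edge"] = (table["adj_p"] < alpha) & np.where(
        sens, table["lfc"] < -lfc_cut, table["lfc"] > lfc_cut)
    return table


def proliferation_independent(
    dep: pd.DataFrame, low: float = -0.25, high: float = 0.25
) -> list[str]:
    """Genes whose mean dependency (CERES-style) lies in [low, high] inclusive.

    Near-zero essentiality across cell lines means knocking the gene out does
    not by itself change proliferation, so survival associations are unlikely
    to be confounded by fitness effects.
    """
    if low >= high:
        raise ValueError("low must be < high")
    means = dep.mean(axis=1)
    return means.index[(means >= low) & (means <= high)].tolist()
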