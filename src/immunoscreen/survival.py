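"""CTIS scoring and survival / response evaluation.

CTIS (CRISPR screening-based tumor-intrinsic immune score) is the difference
between the mean expression of a sensitizer panel and a resistor panel;
higher CTIS indicates a stronger tumor-intrinsic anti-tumor immune state. The
default six-gene panel (four sensitizers JAK1, NFKB2, PPP6C, TNFRSF1B; two
resistors PIGM, TPR) ships as configuration so downstream analysis does not
depend on the panel-search substitute provided here.

Evaluation utilities: covariate-adjusted Cox proportional-hazards screening
(Efron ties), log-rank tests, Harrell's concordance index and ROC AUC (both
with the 0.5 tie convention), plus a greedy cross-validated C-index panel
selector that stands in for minimal-depth random-survival-forest gene
selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CTISPanel",
    "DEFAULT_PANEL",
    "ctis_score",
    "cox_screen",
    "logrank_test",
    "concordance_index",
    "roc_auc",
    "select_panel_greedy",
]


@dataclass(frozen=True)
class CTISPanel:
    sensitizers: tuple[str, ...] = ("JAK1", "NFKB2", "PPP6C", "TNFRSF1B")
    resistors: tuple[str, ...] = ("PIGM", "TPR")

    def __post_init__(self) -> None:
        if not self.sensitizers or not self.resistors:
            raise ValueError("both panel halves must be non-empty")
        if set(self.sensitizers) & set(self.resistors):
            raise ValueError("panel halves must be disjoint")


DEFAULT_PANEL = CTISPanel()


def ctis_score(expr: pd.DataFrame, panel: CTISPanel = DEFAULT_PANEL,
               scale: str = "zscore") -> pd.Series:
    """Per-sample CTIS: mean(sensitizer expression) - mean(resistor expression).

    ``expr`` is log-scale genes x samples. With ``scale="zscore"`` (default)
    each gene is standardized across the cohort first, which makes the two
    panel halves commensurable across cohorts; ``scale="raw"`` uses the matrix
    as is. Missing panel genes raise with the offending list.
    """
    genes = list(panel.sensitizers) + list(panel.resistors)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"panel genes missing from expression matrix: {missing}")
    block = expr.loc[genes].astype(float)
    if scale == "zscore":
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1).replace(0.0, np.nan)
        block = block.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    elif scale != "raw":
        raise ValueError(f"scale must be 'zscore' or 'raw', got {scale!r}")
    sens = block.loc[list(panel.sensitizers)].mean(axis=0)
    res = block.loc[list(panel.resistors)].mean(axis=0)
    out = sens - res
    out.name = "CTIS"
    return out


def cox_screen(
    predictor: pd.Series,
    survival: pd.DataFrame,
    covariate_cols: tuple[str, ...] = ("cancer_type", "age"),
    min_events: int = 5,
) -> dict:
    """Cox PH regression of survival on one predictor plus covariates.

    ``survival`` must carry columns ``time`` (> 0) and ``event`` (0/1) and the
    requested covariates. Returns dict(hr, ci_low, ci_high, coef, p, n,
    n_events, flag). Efron tie handling (lifelines default); non-convergence
    and monotone-likelihood problems are flagged, not raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = survival.loc[predictor.index, ["time", "event"]].copy()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if np.ptp(predictor.to_numpy(dtype=float)) == 0.0:
        raise ValueError("predictor is constant")
    n_events = int(df["event"].sum())
    if n_events < min_events:
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "coef": np.nan,
                "p": np.nan, "n": len(df), "n_events": n_events,
                "flag": "insufficient_events"}
    df["x"] = predictor.astype(float)
    for col in covariate_cols:
        if col not in survival.columns:
            continue
        s = survival.loc[predictor.index, col]
        if s.dtype == object:
            ref = s.value_counts().idxmax()
            for level in sorted(s.dropna().unique()):
                if level != ref:
                    df[f"{col}[{level}]"] = (s == level).astype(float)
        else:
            df[col] = s.astype(float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError):
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "coef": np.nan,
                "p": np.nan, "n": len(df), "n_events": n_events,
                "flag": "non_convergence"}
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = 1.959963984540054  # N(0,1) 97.5% quantile
    return {
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - z * se)),
        "ci_high": float(np.exp(coef + z * se)),
        "coef": coef,
        "p": float(cph.summary.loc["x", "p"]),
        "n": len(df),
        "n_events": n_events,
        "flag": "ok",
    }


def logrank_test(time, event, group) -> tuple[float, float]:
    """Mantel-Cox log-rank test across >= 2 groups; returns (chi2, p)."""
    from lifelines.statistics import multivariate_logrank_test

    group = pd.Series(np.asarray(group))
    if group.nunique() < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(np.asarray(time, dtype=float),
                                    group, np.asarray(event, dtype=int))
    return float(res.test_statistic), float(res.p_value)


def concordance_index(score, time, event) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly by score.

    Higher score is expected to go with longer survival. A pair (i, j) is
    comparable when the shorter observed time is an event; score ties count
    0.5. Raises if no pair is comparable.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    n = s.size
    num = 0.0
    den = 0
    for i in range(n):
        if not e[i]:
            continue
        # j with longer time than the event at i (strictly) is comparable
        longer = t > t[i]
        den += int(longer.sum())
        num += (s[longer] > s[i]).sum() + 0.5 * (s[longer] == s[i]).sum()
    if den == 0:
        raise ValueError("no comparable pairs")
    return float(num / den)


def roc_auc(score, label) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(label, dtype=bool)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def _cv_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [idx[k::n_folds] for k in range(n_folds)]


def select_panel_greedy(
    candidates: list[str],
    roles: dict[str, str],
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    k: int = 6,
    n_folds: int = 3,
    seed: int = 0,
) -> CTISPanel:
    """Greedy forward panel search maximizing cross-validated C-index.

    A documented substitute for minimal-depth random-survival-forest gene
    selection: starting from an empty panel, repeatedly add the candidate
    whose inclusion (on its role-appropriate side of the CTIS difference)
    maximizes the mean held-out C-index of the resulting score. Deterministic
    given ``seed`` (fold assignment) and the candidate order (ties broken by
    first-seen candidate).
    """
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds candidate pool size {len(candidates)}")
    samples = [s for s in expr.columns if s in survival.index]
    t = survival.loc[samples, "time"].to_numpy(dtype=float)
    e = survival.loc[samples, "event"].to_numpy(dtype=bool)
    z = expr.loc[:, samples]
    mu = z.mean(axis=1)
    sd = z.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = z.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)

    rng = np.random.default_rng(seed)
    folds = _cv_folds(len(samples), n_folds, rng)

    def cv_cindex(panel_genes: list[str]) -> float:
        sens = [g for g in panel_genes if roles[g] == "sensitizer"]
        res = [g for g in panel_genes if roles[g] == "resistor"]
        score = np.zeros(len(samples))
        if sens:
            score += z.loc[sens].to_numpy(dtype=float).mean(axis=0)
        if res:
            score -= z.loc[res].to_numpy(dtype=float).mean(axis=0)
        vals = []
        for fold in folds:
            try:
                vals.append(concordance_index(score[fold], t[fold], e[fold]))
            except ValueError:
                continue
        return float(np.mean(vals)) if vals else 0.5

    chosen: list[str] = []
    remaining = [g for g in candidates if g in expr.index]
    while len(chosen) < k and remaining:
        best_gene, best_val = None, -np.inf
        for g in remaining:
            val = cv_cindex(chosen + [g])
            if val > best_val:
                best_gene, best_val = g, val
        chosen.append(best_gene)
        remaining.remove(best_gene)
    sens = tuple(g for g in chosen if roles[g] == "sensitizer")
    res = tuple(g for g in chosen if roles[g] == "resistor")
    if not sens or not res:
        logger.warning("select_panel_greedy: one panel half empty; forcing the "
                       "best candidate of the missing role")
        missing_role = "resistor" if not res else "sensitizer"
        pool = [g for g in remaining if roles[g] == missing_role]
        if pool:
            swap = max(pool, key=lambda g: cv_cindex(chosen[:-1] + [g]))
            chosen[-1] = swap
            sens = tuple(g for g in chosen if roles[g] == "sensitizer")
            res = tuple(g for g in chosen if roles[g] == "resistor")
    return CTISPanel(sensitizers=sens, resistors=res)
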