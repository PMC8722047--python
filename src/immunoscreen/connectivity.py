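"""Connectivity-map style drug-reversal ranking.

Given a query signature — genes whose activity should be pushed *up*
(sensitizers, tumor-immunity-related TSGs, ICB enhancers) and genes to push
*down* (resistors, immunity-related OGs, ICB suppressors) — each drug's
induced expression-change profile is scored with three established signature
matching statistics:

* KS connectivity: difference of signed Kolmogorov-Smirnov enrichment scores
  of the up and down sets in the drug's ranked profile, zeroed when both
  enrichments share a sign, then scaled across the drug cohort;
* XSum: sum of the drug's change values over query-up genes minus query-down
  genes, restricted to the drug's most extreme ``n_extreme`` genes;
* RGES: the same ES difference as KS but without the same-sign zeroing.

Scores from the three methods live on incommensurable scales, so drugs are
ranked per method (lower = stronger reversal after orientation), ranks are
converted to rank ratios, and the ratios are fused with the Stuart
order-statistic Q — the joint probability that N iid uniform order statistics
fall below the observed ratios. Consistently top-ranked drugs get small Q.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QuerySignature",
    "build_query_signature",
    "filter_drugs_by_phase",
    "ks_enrichment",
    "ks_connectivity",
    "xsum_score",
    "rges_score",
    "stuart_q",
    "score_drugs",
    "rank_aggregate",
]

PHASE_ORDER = {"preclinical": 0, "phase1": 1, "phase2": 2, "phase3": 3, "launched": 4}


@dataclass
class QuerySignature:
    """Up/down gene sets describing the desired expression shift."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)}")


def build_query_signature(
    sensitizers=(), resistors=(), tsgs=(), ogs=(),
    icb_enhancers=(), icb_suppressors=(),
) -> QuerySignature:
    """Union positive regulators into ``up``, negative into ``down``.

    up = sensitizers | immunity-related TSGs | ICB enhancers; down = resistors
    | immunity-related OGs | ICB suppressors. A gene landing on both sides is
    removed from both (logged).
    """
    up, down, seen_up, seen_down = [], [], set(), set()
    for src in (sensitizers, tsgs, icb_enhancers):
        for g in src:
            if g not in seen_up:
                up.append(g)
                seen_up.add(g)
    for src in (resistors, ogs, icb_suppressors):
        for g in src:
            if g not in seen_down:
                down.append(g)
                seen_down.add(g)
    conflict = seen_up & seen_down
    if conflict:
        logger.warning("build_query_signature: %d gene(s) on both sides removed: %s",
                       len(conflict), sorted(conflict))
        up = [g for g in up if g not in conflict]
        down = [g for g in down if g not in conflict]
    return QuerySignature(up=up, down=down)


def filter_drugs_by_phase(
    matrix: pd.DataFrame,
    phases: pd.Series,
    min_phase: str = "phase3",
) -> pd.DataFrame:
    """Keep drug columns whose clinical phase is at least ``min_phase``.

    Phase order: preclinical < phase1 < phase2 < phase3 < launched. The
    default keeps drugs that have passed phase II trials (phase3 or launched).
    Unannotated drugs are excluded and logged.
    """
    if min_phase not in PHASE_ORDER:
        raise ValueError(f"unknown phase {min_phase!r}")
    cut = PHASE_ORDER[min_phase]
    keep = []
    n_unannotated = 0
    for drug in matrix.columns:
        ph = phases.get(drug)
        if ph is None or (isinstance(ph, float) and np.isnan(ph)):
            n_unannotated += 1
            continue
        if PHASE_ORDER.get(ph, -1) >= cut:
            keep.append(drug)
    if n_unannotated:
        logger.warning("filter_drugs_by_phase: %d unannotated drug(s) excluded",
                       n_unannotated)
    if not keep:
        logger.warning("filter_drugs_by_phase: no drugs pass %s", min_phase)
    return matrix[keep]


def ks_enrichment(positions, n: int) -> float:
    """Signed KS enrichment of tag genes at sorted 1-based ``positions``.

    a = max_j [j/t - V(j)/n], b = max_j [V(j)/n - (j-1)/t]; ES = a if a >= b
    else -b. Positive ES: tags concentrate at the top of the ranking.
    """
    v = np.asarray(positions, dtype=float)
    t = v.size
    if t == 0:
        raise ValueError("empty tag set")
    if np.any(v[1:] <= v[:-1]):
        raise ValueError("positions must be strictly increasing")
    if v[0] < 1 or v[-1] > n:
        raise ValueError("positions must lie in [1, n]")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a >= b else -b


def _positions_in_ranking(tags, ranking_index: dict[str, int]) -> np.ndarray:
    pos = sorted(ranking_index[g] for g in tags if g in ranking_index)
    return np.asarray(pos, dtype=int)


def _rank_profile(profile: pd.Series) -> list[str]:
    """Gene order by descending change value; ties by symbol for determinism."""
    df = pd.DataFrame({"v": profile.to_numpy(dtype=float), "g": profile.index})
    df = df.sort_values(["v", "g"], ascending=[False, True], kind="mergesort")
    return df["g"].tolist()


def ks_connectivity_raw(up, down, ranking: list[str]) -> float:
    """Unscaled CMap-style connectivity score for one drug ranking."""
    index = {g: i + 1 for i, g in enumerate(ranking)}
    n = len(ranking)
    pos_up = _positions_in_ranking(up, index)
    pos_down = _positions_in_ranking(down, index)
    if pos_up.size == 0 or pos_down.size == 0:
        raise ValueError("up and down sets must each overlap the ranking")
    es_up = ks_enrichment(pos_up, n)
    es_down = ks_enrichment(pos_down, n)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return es_up - es_down


def ks_connectivity(query: QuerySignature, matrix: pd.DataFrame) -> pd.Series:
    """Cohort-scaled KS connectivity scores, one per drug column.

    Raw scores are divided by the cohort maximum (positives) or the absolute
    cohort minimum (negatives), the CMap convention; scaling is rank-
    preserving within each sign.
    """
    raw = {}
    for drug in matrix.columns:
        ranking = _rank_profile(matrix[drug])
        raw[drug] = ks_connectivity_raw(query.up, query.down, ranking)
    s = pd.Series(raw, name="ks")
    pos_max = s[s > 0].max()
    neg_min = s[s < 0].min()
    scaled = s.copy()
    if pd.notna(pos_max) and pos_max > 0:
        scaled[s > 0] = s[s > 0] / pos_max
    if pd.notna(neg_min) and neg_min < 0:
        scaled[s < 0] = s[s < 0] / abs(neg_min)
    return scaled


def xsum_score(up, down, profile: pd.Series, n_extreme: int = 500) -> float:
    """eXtreme Sum: sum of change values over query genes in the extreme tails.

    E = union of the ``n_extreme`` largest and ``n_extreme`` smallest genes by
    change value; XSum = sum(change over up & E) - sum(change over down & E).
    Negative values indicate reversal of the query.
    """
    if n_extreme < 1:
        raise ValueError("n_extreme must be >= 1")
    order = _rank_profile(profile)
    k = min(n_extreme, len(order))
    extreme = set(order[:k]) | set(order[-k:])
    up_sum = float(sum(profile[g] for g in up if g in extreme and g in profile.index))
    down_sum = float(sum(profile[g] for g in down if g in extreme and g in profile.index))
    return up_sum - down_sum


def rges_score(up, down, ranking: list[str]) -> float:
    """Reverse gene expression score: ES_up - ES_down, no same-sign zeroing.

    More negative = the drug pushes query-up genes down and query-down genes
    up, i.e. stronger reversal.
    """
    index = {g: i + 1 for i, g in enumerate(ranking)}
    n = len(ranking)
    pos_up = _positions_in_ranking(up, index)
    pos_down = _positions_in_ranking(down, index)
    if pos_up.size == 0 or pos_down.size == 0:
        raise ValueError("up and down sets must each overlap the ranking")
    return ks_enrichment(pos_up, n) - ks_enrichment(pos_down, n)


def stuart_q(rank_ratios) -> float:
    """Stuart order-statistic Q for one drug's per-method rank ratios.

    Q = N! V_N where V follows the recursion
    V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_(N-k+1)^i / i!, V_0 = 1, over the
    ascending-sorted ratios: the probability that N iid Uniform(0,1) order
    statistics jointly fall below the observed ratios. Small Q = consistently
    near the top across methods.
    """
    r = np.sort(np.asarray(rank_ratios, dtype=float))
    if r.size == 0:
        raise ValueError("empty rank-ratio vector")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("rank ratios must lie in (0, 1]")
    n = r.size
    v = [1.0]
    for k in range(1, n + 1):
        rk = r[n - k]  # r_(N-k+1), 1-based
        total = 0.0
        for i in range(1, k + 1):
            total += (-1) ** (i - 1) * v[k - i] * rk ** i / math.factorial(i)
        v.append(total)
    return float(math.factorial(n) * v[n])


@dataclass
class ConnectivityResult:
    """Per-drug method scores, oriented ranks, rank ratios, and aggregated Q."""

    table: pd.DataFrame
    methods: tuple[str, ...]
    excluded: list[str] = field(default_factory=list)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)


def score_drugs(
    query: QuerySignature,
    matrix: pd.DataFrame,
    methods: tuple[str, ...] = ("xsum", "ks", "rges"),
    n_extreme: int = 500,
) -> pd.DataFrame:
    """Raw per-method scores for every drug column (drugs x methods).

    Drugs whose profile has no overlap with either query side are excluded
    (logged) rather than silently ranked.
    """
    usable, excluded = [], []
    for drug in matrix.columns:
        genes = set(matrix.index)
        if (set(query.up) & genes) and (set(query.down) & genes):
            usable.append(drug)
        else:
            excluded.append(drug)
    if excluded:
        logger.warning("score_drugs: %d drug(s) excluded for zero query overlap",
                       len(excluded))
    sub = matrix[usable]
    out = pd.DataFrame(index=usable, columns=list(methods), dtype=float)
    if "ks" in methods:
        out["ks"] = ks_connectivity(query, sub)
    for drug in usable:
        profile = sub[drug]
        ranking = _rank_profile(profile)
        if "xsum" in methods:
            out.at[drug, "xsum"] = xsum_score(query.up, query.down, profile, n_extreme)
        if "rges" in methods:
            out.at[drug, "rges"] = rges_score(query.up, query.down, ranking)
    return out


# orientation: +1 means "already lower = stronger reversal", -1 means negate
METHOD_ORIENTATION = {"xsum": +1, "ks": +1, "rges": +1}


def rank_aggregate(scores: pd.DataFrame, methods: tuple[str, ...] | None = None
                   ) -> ConnectivityResult:
    """Fuse per-method drug scores into a Stuart-Q ranking.

    All three methods are oriented so that a *lower* score means stronger
    reversal (XSum and RGES are natively reversal-negative; the KS
    connectivity score likewise: a reversing drug has negative connectivity).
    Per method: ascending ranks with ties averaged, rank ratio = rank /
    n_drugs; per drug Q = stuart_q(ratios); final order ascending Q, ties by
    mean rank ratio then drug id.
    """
    if methods is None:
        methods = tuple(scores.columns)
    if len(methods) < 2:
        raise ValueError("rank aggregation needs >= 2 methods")
    n = len(scores)
    table = scores[list(methods)].copy()
    ratios = pd.DataFrame(index=table.index, columns=list(methods), dtype=float)
    for m in methods:
        oriented = table[m] * METHOD_ORIENTATION.get(m, +1)
        ranks = oriented.rank(method="average", ascending=True)
        table[f"rank_{m}"] = ranks
        ratios[m] = ranks / n
    table["q"] = [stuart_q(ratios.loc[d].to_numpy()) for d in table.index]
    table["mean_rank_ratio"] = ratios.mean(axis=1)
    table["_drug"] = table.index
    table = table.sort_values(["q", "mean_rank_ratio", "_drug"], kind="mergesort")
    table = table.drop(columns="_drug")
    table["final_rank"] = np.arange(1, len(table) + 1)
    return ConnectivityResult(table=table, methods=tuple(methods))
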