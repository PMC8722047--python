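"""Per-sample binary functional-event calling from mutation, CNV and expression.

Loss-of-function (*inactivation*) events are called for screen-derived
regulators and tumor suppressor genes; gain-of-function (*activation*) events
for oncogenes. The rules are deliberately conservative and multi-omic:

inactivation(sample, gene) = deleterious mutation
                           | deep deletion (GISTIC -2)
                           | standardized expression z <= -2

activation(sample, gene)   = high-level amplification (GISTIC +2)
                           | standardized expression z >= +2

The mutation layer is never consulted for activation because computational
prediction of gain-of-function point mutations is unreliable. A *deleterious*
mutation is any frameshift / stopgain / startloss / stoploss, or a missense
variant whose damage probability (PolyPhen2-style score, supplied as input)
exceeds 0.5 strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsCohort",
    "StatusMatrix",
    "zscore_expression",
    "is_deleterious",
    "call_inactivation",
    "call_activation",
    "build_status_matrix",
]

LOF_CLASSES = frozenset({"frameshift", "stopgain", "startloss", "stoploss"})


@dataclass
class OmicsCohort:
    """Expression, mutation, CNV and annotations for one sample cohort.

    expr: genes x samples, log scale. cnv: genes x samples, GISTIC codes in
    {-2..2}. mutations: records (sample, gene, consequence, damage_prob).
    annotations: per-sample frame indexed by sample id with at least
    ``cancer_type``; optionally immune_subtype, age, os_time, os_event,
    response. ``expr_z`` is standardized expression, computed lazily within
    the configured stratum (default: per cancer type).
    """

    expr: pd.DataFrame
    mutations: pd.DataFrame
    cnv: pd.DataFrame
    annotations: pd.DataFrame
    stratify_z: str | None = "cancer_type"
    _expr_z: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        samples = set(self.expr.columns)
        if set(self.cnv.columns) and set(self.cnv.columns) != samples:
            raise ValueError("expr and cnv sample sets disagree")
        if set(self.annotations.index) != samples:
            raise ValueError("expr and annotation sample sets disagree")

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def expr_z(self) -> pd.DataFrame:
        if self._expr_z is None:
            strata = (
                self.annotations[self.stratify_z]
                if self.stratify_z is not None
                else None
            )
            self._expr_z = zscore_expression(self.expr, strata)
        return self._expr_z


@dataclass
class StatusMatrix:
    """Binary genes x samples event matrix with per-event provenance.

    ``provenance[gene][sample]`` is the set of omics layers (subset of
    {"mutation", "cnv", "expression"}) whose clause fired for that event.
    Activation matrices never carry mutation provenance.
    """

    values: pd.DataFrame
    event_kind: str
    provenance: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    skipped_genes: list[str] = field(default_factory=list)

    def event_counts(self) -> pd.Series:
        return self.values.sum(axis=1).astype(int)


def zscore_expression(expr: pd.DataFrame, strata: pd.Series | None = None) -> pd.DataFrame:
    """Standardize each gene to mean 0, sd 1, within strata if given.

    Strata (e.g. cancer type) prevent tissue-of-origin expression differences
    from dominating the tails. Genes constant within a stratum get z = 0
    there. Uses the unbiased (ddof=1) standard deviation.
    """
    if strata is None:
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1)
        z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        return z.fillna(0.0)
    z = pd.DataFrame(np.nan, index=expr.index, columns=expr.columns)
    for _, cols in expr.columns.to_series().groupby(strata.reindex(expr.columns)):
        block = expr[cols.index]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zb = block.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        z.loc[:, cols.index] = zb.fillna(0.0)
    return z


def is_deleterious(consequence: str, damage_prob: float | None = None) -> bool:
    """True for loss-of-function classes, or damaging missense (prob > 0.5).

    Missense with a missing damage probability is conservatively not
    deleterious. Total function: unknown consequence classes return False.
    """
    if consequence in LOF_CLASSES:
        return True
    if consequence == "missense":
        if damage_prob is None or (isinstance(damage_prob, float) and np.isnan(damage_prob)):
            return False
        return damage_prob > 0.5
    return False


def _deleterious_lookup(mutations: pd.DataFrame) -> set[tuple[str, str]]:
    """(sample, gene) pairs carrying at least one deleterious mutation."""
    if len(mutations) == 0:
        return set()
    mask = [
        is_deleterious(c, d)
        for c, d in zip(mutations["consequence"], mutations["damage_prob"])
    ]
    hit = mutations.loc[mask]
    return set(zip(hit["sample"], hit["gene"]))


def _gene_layers(cohort: OmicsCohort, gene: str) -> tuple[bool, bool, bool]:
    in_expr = gene in cohort.expr.index
    in_cnv = gene in cohort.cnv.index
    in_mut = len(cohort.mutations) > 0 and (cohort.mutations["gene"] == gene).any()
    return in_mut, in_cnv, in_expr


def call_inactivation(
    cohort: OmicsCohort, gene: str, sample: str, z_cut: float = -2.0
) -> tuple[bool, frozenset[str]]:
    """Call one (gene, sample) inactivation event; returns (flag, provenance).

    Provenance lists every satisfied clause. A gene absent from a layer
    contributes False for that clause; a gene absent from all layers raises.
    """
    in_mut, in_cnv, in_expr = _gene_layers(cohort, gene)
    if not (in_mut or in_cnv or in_expr):
        raise KeyError(f"gene {gene!r} absent from expression, CNV and mutation layers")
    prov = set()
    if in_mut:
        sub = cohort.mutations
        sub = sub[(sub["gene"] == gene) & (sub["sample"] == sample)]
        if any(is_deleterious(c, d) for c, d in zip(sub["consequence"], sub["damage_prob"])):
            prov.add("mutation")
    if in_cnv and cohort.cnv.at[gene, sample] == -2:
        prov.add("cnv")
    if in_expr and cohort.expr_z.at[gene, sample] <= z_cut:
        prov.add("expression")
    return bool(prov), frozenset(prov)


def call_activation(
    cohort: OmicsCohort, gene: str, sample: str, z_cut: float = 2.0
) -> tuple[bool, frozenset[str]]:
    """Call one (gene, sample) activation event; the mutation layer is ignored."""
    _, in_cnv, in_expr = _gene_layers(cohort, gene)
    if not (in_cnv or in_expr):
        raise KeyError(f"gene {gene!r} absent from expression and CNV layers")
    prov = set()
    if in_cnv and cohort.cnv.at[gene, sample] == 2:
        prov.add("cnv")
    if in_expr and cohort.expr_z.at[gene, sample] >= z_cut:
        prov.add("expression")
    return bool(prov), frozenset(prov)


def build_status_matrix(
    cohort: OmicsCohort,
    genes: list[str],
    kind: str = "inactivation",
    z_cut: float | None = None,
    with_provenance: bool = False,
) -> StatusMatrix:
    """Vectorized event calling for a gene list over the whole cohort.

    Row order follows the input gene list; column order the cohort samples.
    Genes absent from every relevant layer are skipped (with a summary count)
    rather than aborting the run. ``with_provenance`` additionally records the
    satisfied clauses per event (slower; per-event dict).
    """
    if kind not in ("inactivation", "activation"):
        raise ValueError(f"kind must be 'inactivation' or 'activation', got {kind!r}")
    if not genes:
        raise ValueError("genes must be non-empty")
    if z_cut is None:
        z_cut = -2.0 if kind == "inactivation" else 2.0

    samples = cohort.samples
    kept: list[str] = []
    skipped: list[str] = []
    rows = []
    prov_all: dict[str, dict[str, frozenset[str]]] = {}

    del_pairs = _deleterious_lookup(cohort.mutations) if kind == "inactivation" else set()
    zmat = cohort.expr_z

    for gene in genes:
        in_mut, in_cnv, in_expr = _gene_layers(cohort, gene)
        relevant = (in_mut or in_cnv or in_expr) if kind == "inactivation" else (in_cnv or in_expr)
        if not relevant:
            skipped.append(gene)
            continue
        mut_clause = np.zeros(len(samples), dtype=bool)
        if kind == "inactivation" and in_mut:
            mut_clause = np.array([(s, gene) in del_pairs for s in samples])
        cnv_clause = np.zeros(len(samples), dtype=bool)
        if in_cnv:
            cnv_row = cohort.cnv.loc[gene].reindex(samples)
            cnv_clause = (cnv_row == (-2 if kind == "inactivation" else 2)).to_numpy()
        expr_clause = np.zeros(len(samples), dtype=bool)
        if in_expr:
            zrow = zmat.loc[gene].reindex(samples).to_numpy()
            expr_clause = (zrow <= z_cut) if kind == "inactivation" else (zrow >= z_cut)
        flags = mut_clause | cnv_clause | expr_clause
        kept.append(gene)
        rows.append(flags.astype(np.int8))
        if with_provenance:
            gp: dict[str, frozenset[str]] = {}
            for i, s in enumerate(samples):
                if flags[i]:
                    p = set()
                    if mut_clause[i]:
                        p.add("mutation")
                    if cnv_clause[i]:
                        p.add("cnv")
                    if expr_clause[i]:
                        p.add("expression")
                    gp[s] = frozenset(p)
            prov_all[gene] = gp

    if skipped:
        logger.warning(
            "build_status_matrix(%s): skipped %d gene(s) absent from all layers",
            kind, len(skipped))
    values = pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8),
        index=kept, columns=samples)
    return StatusMatrix(values=values, event_kind=kind, provenance=prov_all,
                        skipped_genes=skipped)
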