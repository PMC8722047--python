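"""Integration of per-screen CRISPR hit tables into a recurrent regulator catalog.

Screens performed in tumor/immune co-culture (or in vivo immune-competent)
settings are all loss-of-function, so hits read the same way in every screen:
sgRNAs of genes whose product sensitizes tumor cells to immune killing become
*enriched* in surviving cells (sensitizer candidates), while sgRNAs of genes
that drive immune escape are *depleted* (resistor candidates). Recurrence
across independent screens is the primary noise filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RegulatorCatalog", "classify_hits", "map_orthologs", "build_catalog"]

ENRICHED = "enriched"
DEPLETED = "depleted"
NEUTRAL = "neutral"


@dataclass
class RegulatorCatalog:
    """Genes recurrently hit across screens, labeled sensitizer or resistor.

    ``table`` has one row per gene with columns ``role`` ("sensitizer" or
    "resistor"), ``support`` (list of screen ids) and ``n_screens``.
    """

    table: pd.DataFrame
    dropped_ties: list[str] = field(default_factory=list)

    @property
    def sensitizers(self) -> list[str]:
        return self.table.index[self.table["role"] == "sensitizer"].tolist()

    @property
    def resistors(self) -> list[str]:
        return self.table.index[self.table["role"] == "resistor"].tolist()

    def roles(self) -> dict[str, str]:
        return self.table["role"].to_dict()

    def __len__(self) -> int:
        return len(self.table)


def classify_hits(hits: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Label each gene of one screen enriched / depleted / neutral.

    enriched iff adj_p_pos < alpha and lfc > 0; depleted iff adj_p_neg < alpha
    and lfc < 0 (strict inequalities). Records with a missing log-fold change
    are neutral and counted in a single warning.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lfc = pd.to_numeric(hits["lfc"])
    p_pos = pd.to_numeric(hits["adj_p_pos"])
    p_neg = pd.to_numeric(hits["adj_p_neg"])
    enriched = (p_pos < alpha) & (lfc > 0)
    depleted = (p_neg < alpha) & (lfc < 0)
    labels = pd.Series(NEUTRAL, index=hits.index, dtype=object)
    labels[enriched.fillna(False)] = ENRICHED
    labels[depleted.fillna(False)] = DEPLETED
    n_missing = int(lfc.isna().sum())
    if n_missing:
        logger.warning("classify_hits: %d record(s) with missing lfc set to neutral", n_missing)
        labels[lfc.isna()] = NEUTRAL
    out = pd.Series(labels.values, index=hits["gene"].values, name="class")
    return out


def map_orthologs(genes: list[str], mapping: pd.DataFrame) -> list[str]:
    """Map (e.g. mouse) symbols to human symbols via a two-column table.

    ``mapping`` columns: ``source``, ``human``. Genes without a mapping are
    dropped (count logged); a source symbol with several human targets expands
    to all of them (logged). Output order follows input order.
    """
    lut: dict[str, list[str]] = {}
    for src, hum in zip(mapping["source"], mapping["human"]):
        lut.setdefault(src, []).append(hum)
    out: list[str] = []
    n_dropped = 0
    n_expanded = 0
    for g in genes:
        targets = lut.get(g)
        if targets is None:
            n_dropped += 1
            continue
        if len(targets) > 1:
            n_expanded += 1
        out.extend(targets)
    if n_dropped:
        logger.info("map_orthologs: dropped %d gene(s) without a human ortholog", n_dropped)
    if n_expanded:
        logger.info("map_orthologs: %d gene(s) expanded one-to-many", n_expanded)
    return out


def build_catalog(
    classified: dict[str, pd.Series],
    min_screens: int = 2,
) -> RegulatorCatalog:
    """Aggregate per-screen classifications into a recurrent regulator catalog.

    Parameters
    ----------
    classified
        Mapping screen_id -> per-gene labels as returned by
        :func:`classify_hits`.
    min_screens
        Recurrence threshold: a gene enters the catalog as sensitizer iff it is
        enriched in at least this many screens (resistor: depleted). A gene
        qualifying for both roles keeps the role with more supporting screens;
        exact ties are excluded and recorded in ``dropped_ties``.
    """
    if min_screens < 1:
        raise ValueError("min_screens must be >= 1")
    if len(classified) < min_screens:
        raise ValueError(
            f"need at least min_screens={min_screens} screens, got {len(classified)}"
        )
    enriched_in: dict[str, list[str]] = {}
    depleted_in: dict[str, list[str]] = {}
    for screen_id, labels in classified.items():
        for gene, lab in labels.items():
            if lab == ENRICHED:
                enriched_in.setdefault(gene, []).append(screen_id)
            elif lab == DEPLETED:
                depleted_in.setdefault(gene, []).append(screen_id)

    rows = []
    dropped: list[str] = []
    for gene in sorted(set(enriched_in) | set(depleted_in)):
        e = enriched_in.get(gene, [])
        d = depleted_in.get(gene, [])
        sens_ok = len(e) >= min_screens
        res_ok = len(d) >= min_screens
        if sens_ok and res_ok:
            if len(e) == len(d):
                dropped.append(gene)
                logger.warning(
                    "build_catalog: %s enriched and depleted with equal support "
                    "(%d screens each); excluded", gene, len(e))
                continue
            role, support = ("sensitizer", e) if len(e) > len(d) else ("resistor", d)
        elif sens_ok:
            role, support = "sensitizer", e
        elif res_ok:
            role, support = "resistor", d
        else:
            continue
        rows.append((gene, role, sorted(support), len(support)))

    table = pd.DataFrame(rows, columns=["gene", "role", "support", "n_screens"]).set_index("gene")
    return RegulatorCatalog(table=table, dropped_ties=dropped)
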