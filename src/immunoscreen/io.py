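"""Readers, writers, and summaries for the tabular formats the pipeline touches.

Conventions used across the package:

* every matrix is a TSV with a header row; the first column holds the row
  identifier (gene symbols for expression / CNV / dependency / drug matrices);
  genes are rows, samples or drugs are columns;
* missing numeric values are written and read as ``NA`` and preserved as NaN,
  never imputed;
* reported percentages use half-up rounding to two decimals.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ScreenMetadata",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_screen_hits",
    "read_screen_metadata",
    "read_matrix",
    "write_matrix",
    "read_mutations",
    "read_annotations",
    "read_feature_catalog",
    "summarize_metadata",
    "load_default_signatures",
    "load_default_features",
    "load_default_screen_metadata",
]

CANCER_TYPES = ("skin", "breast", "colon", "pancreas", "lung")
SETTINGS = ("in_vitro", "in_vivo")
LIBRARY_SCALES = ("genome_scale", "focused")
ORGANISMS = ("mouse", "human")

HIT_COLUMNS = ("gene", "lfc", "adj_p_pos", "adj_p_neg")
MUTATION_COLUMNS = ("sample", "gene", "consequence", "damage_prob")


@dataclass(frozen=True)
class ScreenMetadata:
    """Study-design descriptors for one CRISPR screen."""

    screen_id: str
    study_id: str
    cancer_type: str
    setting: str
    library_scale: str
    organism: str
    algorithm: str
    icb_treated: bool = False

    def __post_init__(self) -> None:
        for value, vocab, name in (
            (self.setting, SETTINGS, "setting"),
            (self.library_scale, LIBRARY_SCALES, "library_scale"),
            (self.organism, ORGANISMS, "organism"),
        ):
            if value not in vocab:
                raise ValueError(f"{name}={value!r} not in {vocab}")


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. the immune / CYT / MHC signature lists."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...; tab-separated).

    Within-set duplicate genes are removed, first occurrence kept. Lines with
    fewer than three fields raise a ``ValueError`` naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_screen_hits(path: str | Path) -> pd.DataFrame:
    """Read a MAGeCK-style per-gene hit table.

    Requires columns ``gene, lfc, adj_p_pos, adj_p_neg``; numeric fields are
    parsed with ``NA`` preserved as missing. A missing required column raises
    ``ValueError``; a non-numeric cell raises ``ValueError`` with the row index.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}, na_values=["NA"], keep_default_na=False)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    for col in ("lfc", "adj_p_pos", "adj_p_neg"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad[bad.isna() & df[col].notna()].index[0])
            raise ValueError(f"{path}: non-numeric value in column {col!r} at row {row}") from None
    for col in ("adj_p_pos", "adj_p_neg"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    return df[list(HIT_COLUMNS)]


def read_screen_metadata(path: str | Path) -> list[ScreenMetadata]:
    """Read a screen-metadata TSV into a list of :class:`ScreenMetadata`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    screens = []
    for _, row in df.iterrows():
        screens.append(
            ScreenMetadata(
                screen_id=row["screen_id"],
                study_id=row["study_id"],
                cancer_type=row["cancer_type"],
                setting=row["setting"],
                library_scale=row["library_scale"],
                organism=row["organism"],
                algorithm=row["algorithm"],
                icb_treated=str(row["icb_treated"]).strip().lower() in ("true", "1", "yes"),
            )
        )
    ids = [s.screen_id for s in screens]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate screen_id values")
    return screens


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples (or genes-x-drugs) TSV matrix, first column = row id."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix TSV; floats at 12 significant digits, NaN as NA."""
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read MAF-lite mutation records (sample, gene, consequence, damage_prob)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"sample": str, "gene": str, "consequence": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df["damage_prob"] = pd.to_numeric(df["damage_prob"])
    return df[list(MUTATION_COLUMNS)]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-sample annotations, indexed by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    return df


def read_feature_catalog(path: str | Path) -> pd.DataFrame:
    """Read the immune-feature catalog (feature, category, polarity, genes).

    ``genes`` is comma-separated in the file and split into a list. Every
    feature must declare a polarity in {anti_tumor, pro_tumor}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature", "category", "polarity", "genes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s): {sorted(missing)}")
    bad = ~df["polarity"].isin(["anti_tumor", "pro_tumor"])
    if bad.any():
        raise ValueError(f"{path}: invalid polarity values: {df.loc[bad, 'polarity'].tolist()}")
    df = df.copy()
    df["genes"] = df["genes"].map(lambda s: [g for g in s.split(",") if g])
    return df.set_index("feature")


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(decimal.Decimal(str(x)).quantize(
        decimal.Decimal("1." + "0" * ndigits), rounding=decimal.ROUND_HALF_UP))


def summarize_metadata(screens: list[ScreenMetadata], field_name: str) -> pd.DataFrame:
    """Tabulate one metadata field across screens as (category, count, percentage).

    Percentages are 100*count/total, half-up rounded to 2 decimals; categories
    sorted by descending count then lexicographically. With 17 screens of which
    7 are skin-cancer models this reports ("skin", 7, 41.18).
    """
    if not screens:
        raise ValueError("summarize_metadata: empty screen list")
    values = [getattr(s, field_name) for s in screens]
    counts: dict[str, int] = {}
    for v in values:
        key = str(v)
        counts[key] = counts.get(key, 0) + 1
    total = len(values)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(cat, n, _round_half_up(100.0 * n / total)) for cat, n in rows],
        columns=["category", "count", "percentage"],
    )


def _data_path(name: str):
    return resources.files("immunoscreen.data").joinpath(name)


def load_default_signatures() -> GeneSetCollection:
    """Packaged stand-in immune / CYT / MHC signature gene sets."""
    with resources.as_file(_data_path("signatures.gmt")) as p:
        return read_gmt(p)


def load_default_features() -> pd.DataFrame:
    """Packaged stand-in immune-feature catalog with anti-/pro-tumor polarity."""
    with resources.as_file(_data_path("immune_features.tsv")) as p:
        return read_feature_catalog(p)


def load_default_screen_metadata() -> list[ScreenMetadata]:
    """Packaged screen-design summary table (17 immune-killing screens).

    The table is a synthetic stand-in reproducing the marginal composition of
    the screen collection (7 skin / 4 breast / 4 colon / 1 pancreas / 1 lung;
    13 in vitro; 15 genome-scale; 16 mouse).
    """
    with resources.as_file(_data_path("screen_metadata.tsv")) as p:
        return read_screen_metadata(p)
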