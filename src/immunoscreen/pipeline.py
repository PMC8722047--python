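"""End-to-end orchestration with a validated config and a threshold manifest.

The analysis hinges on many small cutoffs (alpha = 0.05, recurrence >= 2
screens, |z| >= 2 event calls, log2 OR > 1.5, |lfc| > 0.25, CERES in
[-0.25, 0.25], >= 100 related features, 500 extreme genes), so every run
records all of them — plus SHA-256 checksums of every input and output — in
``manifest.json``. Re-running an identical config over identical inputs is
byte-identical.

Stages run in dependency order::

    integrate -> status -> score -> associate -> features -> network
              -> depfilter -> ctis -> drugs

Each stage only communicates through the files it writes under the run
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("integrate", "status", "score", "associate", "features", "network",
          "depfilter", "ctis", "drugs")


@dataclass
class PipelineConfig:
    indir: str = "."
    outdir: str = "run"
    alpha: float = 0.05
    min_screens: int = 2
    z_cut: float = 2.0
    lor_cut: float = 1.5
    lfc_cut: float = 0.25
    ceres_low: float = -0.25
    ceres_high: float = 0.25
    min_related_features: int = 100
    n_extreme: int = 500
    min_events: int = 5
    feature_min_events: int = 3
    min_phase: str = "phase3"
    ctis_sensitizers: tuple[str, ...] = ("JAK1", "NFKB2", "PPP6C", "TNFRSF1B")
    ctis_resistors: tuple[str, ...] = ("PIGM", "TPR")
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("ctis_sensitizers", "ctis_resistors", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ctis_sensitizers", "ctis_resistors", "stages"):
            d[key] = list(d[key])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages over the inputs in ``config.indir``.

    Expects the input layout emitted by :func:`immunoscreen.simulate.write_inputs`
    (expr.tsv, mutations.tsv, cnv.tsv, annotations.tsv, screens/,
    signatures.gmt, features.tsv, drivers.tsv, dependency.tsv, drugs.tsv,
    drug_phases.tsv). Returns the run directory; writes ``manifest.json``.
    """
    from . import associations as assoc_mod
    from . import connectivity as conn
    from . import scoring, screens, status, survival
    from .io import (read_annotations, read_feature_catalog, read_gmt,
                     read_matrix, read_mutations, read_screen_hits)

    indir = Path(config.indir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    def track_in(name: str) -> Path:
        p = indir / name
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
        inputs[name] = _sha256(p)
        return p

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", na_rep="NA", float_format="%.12g", **kw)
        outputs[name] = _sha256(p)

    expr = read_matrix(track_in("expr.tsv"))
    anno = read_annotations(track_in("annotations.tsv"))
    cohort = status.OmicsCohort(
        expr=expr,
        mutations=read_mutations(track_in("mutations.tsv")),
        cnv=read_matrix(track_in("cnv.tsv")).astype(int),
        annotations=anno,
    )
    catalog = None
    if "integrate" in config.stages:
        classified = {}
        for p in sorted((indir / "screens").glob("*.tsv")):
            inputs[f"screens/{p.name}"] = _sha256(p)
            classified[p.stem] = screens.classify_hits(read_screen_hits(p),
                                                       alpha=config.alpha)
        catalog = screens.build_catalog(classified, min_screens=config.min_screens)
        cat_out = catalog.table.copy()
        cat_out["support"] = cat_out["support"].map(";".join)
        emit(cat_out, "catalog.tsv", index_label="gene")

    status_matrix = None
    if "status" in config.stages:
        status_matrix = status.build_status_matrix(
            cohort, list(catalog.table.index), kind="inactivation",
            z_cut=-abs(config.z_cut))
        emit(status_matrix.values, "status.tsv", index_label="gene")

    scores = None
    if "score" in config.stages:
        sets = read_gmt(track_in("signatures.gmt"))
        scores = scoring.signature_scores(expr, sets)
        emit(scores, "scores.tsv", index_label="sample")

    functional = None
    if "associate" in config.stages:
        assoc = assoc_mod.associate_signatures(scores, status_matrix, anno,
                                               min_events=config.min_events)
        emit(assoc, "associations.tsv", index=False)
        functional = assoc_mod.filter_functional_regulators(
            assoc, catalog, alpha=config.alpha)
        fun_out = functional.table.copy()
        fun_out["support"] = fun_out["support"].map(
            lambda s: ";".join(s) if isinstance(s, list) else s)
        emit(fun_out, "functional_catalog.tsv", index_label="gene")

    feature_counts = None
    if "features" in config.stages:
        feat_catalog = read_feature_catalog(track_in("features.tsv"))
        fscores = scoring.feature_abundance(expr, feat_catalog)
        fassoc = assoc_mod.associate_features(
            fscores, status_matrix, anno, min_events=config.feature_min_events)
        polarity = feat_catalog["polarity"]
        feature_counts = assoc_mod.count_related_features(
            fassoc, functional.roles(), polarity, alpha=config.alpha)
        emit(feature_counts, "feature_counts.tsv", index=False)

    if "network" in config.stages:
        drivers = pd.read_csv(track_in("drivers.tsv"), sep="\t")
        classes = dict(zip(drivers["gene"], drivers["driver_class"]))
        ogs = [g for g, c in classes.items() if c == "OG" and g in expr.index]
        tsgs = [g for g, c in classes.items() if c == "TSG" and g in expr.index]
        frames = []
        if ogs:
            frames.append(status.build_status_matrix(cohort, ogs, "activation",
                                                     z_cut=abs(config.z_cut)).values)
        if tsgs:
            frames.append(status.build_status_matrix(cohort, tsgs, "inactivation",
                                                     z_cut=-abs(config.z_cut)).values)
        driver_status = pd.concat(frames) if frames else pd.DataFrame()
        net = assoc_mod.og_tsg_network(
            expr, driver_status, classes, functional.roles(),
            alpha=config.alpha, lfc_cut=config.lfc_cut,
            min_events=config.min_events)
        emit(net, "network.tsv", index=False)

    if "depfilter" in config.stages:
        dep = read_matrix(track_in("dependency.tsv"))
        keep = assoc_mod.proliferation_independent(
            dep, low=config.ceres_low, high=config.ceres_high)
        emit(pd.DataFrame({"gene": keep}), "proliferation_independent.tsv",
             index=False)

    if "ctis" in config.stages:
        panel = survival.CTISPanel(sensitizers=tuple(config.ctis_sensitizers),
                                   resistors=tuple(config.ctis_resistors))
        ctis = survival.ctis_score(expr, panel)
        emit(ctis.to_frame(), "ctis.tsv", index_label="sample")
        evaluation: dict[str, float] = {}
        if {"os_time", "os_event"} <= set(anno.columns):
            surv = anno.rename(columns={"os_time": "time", "os_event": "event"})
            cox = survival.cox_screen(ctis, surv, covariate_cols=("cancer_type", "age"),
                                      min_events=config.min_events)
            evaluation.update({f"cox_{k}": cox[k] for k in
                               ("hr", "ci_low", "ci_high", "p")})
            evaluation["c_index"] = survival.concordance_index(
                ctis.to_numpy(), surv["time"].to_numpy(), surv["event"].to_numpy())
            high = (ctis > ctis.median()).map({True: "high", False: "low"})
            chi2, p = survival.logrank_test(surv["time"], surv["event"], high)
            evaluation["logrank_chi2"] = chi2
            evaluation["logrank_p"] = p
        _write_json(evaluation, outdir / "ctis_eval.json")
        outputs["ctis_eval.json"] = _sha256(outdir / "ctis_eval.json")

    if "drugs" in config.stages:
        matrix = read_matrix(track_in("drugs.tsv"))
        phases_df = pd.read_csv(track_in("drug_phases.tsv"), sep="\t")
        phases = pd.Series(phases_df["clinical_phase"].values,
                           index=phases_df["drug"])
        matrix = conn.filter_drugs_by_phase(matrix, phases,
                                            min_phase=config.min_phase)
        query = conn.build_query_signature(
            sensitizers=functional.sensitizers, resistors=functional.resistors)
        raw = conn.score_drugs(query, matrix, n_extreme=config.n_extreme)
        result = conn.rank_aggregate(raw)
        emit(result.table, "drugs_ranked.tsv", index_label="drug")

    manifest = {"config": config.to_dict(), "inputs": inputs, "outputs": outputs}
    _write_json(manifest, outdir / "manifest.json")
    return outdir
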