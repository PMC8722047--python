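"""Synthetic cohorts, screens, drug matrices and survival with planted truth.

Every generator is a pure function of (spec, seed): the spec's single integer
seed drives an independent substream per generator (``default_rng([seed, k])``
with a fixed stream index k), so adding a generator never perturbs another's
draws.

The cohort emulates the statistical structure the analysis assumes, not any
real data set's marginals: log-normal expression with cancer-type offsets,
planted sensitizer/resistor inactivation events injected consistently into
the mutation / CNV / expression layers, immune-signature genes shifted by
-delta per sensitizer event (+delta per resistor event), driver (OG/TSG)
events that shift regulator expression, exponential survival whose hazard
depends on CTIS, and a drug matrix containing planted reversers whose
profiles anti-correlate with the query signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import QuerySignature
from .io import GeneSetCollection
from .status import OmicsCohort

__all__ = ["SyntheticSpec", "make_cohort", "make_screens", "make_drug_matrix",
           "make_survival", "write_inputs"]

_STREAMS = {"cohort": 0, "screens": 1, "drugs": 2, "survival": 3, "deps": 4}

LOF = ("frameshift", "stopgain", "startloss", "stoploss")


@dataclass
class SyntheticSpec:
    """Stated world for the synthetic pipeline inputs."""

    n_samples: int = 600
    n_genes: int = 2000
    cancer_types: dict = field(default_factory=lambda: {
        "skin": 0.3, "breast": 0.25, "colon": 0.25, "lung": 0.2})
    n_sensitizers: int = 8
    n_resistors: int = 8
    n_decoys: int = 8          # pass the recurrence filter but delta = 0
    n_singletons: int = 6      # significant in exactly one screen
    n_ogs: int = 4
    n_tsgs: int = 4
    event_rate: float = 0.15           # pi: per-sample planted event probability
    effect_size: float = 1.0           # delta: log2 shift of immune genes per event
    driver_effect: float = 0.6         # expression shift of regulators per driver event
    mutation_background: float = 0.01
    cnv_background: float = 0.05       # rate of background +/-1 GISTIC codes
    n_screens: int = 4
    n_drugs: int = 200
    n_reversers: int = 3
    reversal_strength: float = 1.0     # rho in [0, 1]
    baseline_hazard: float = 0.1       # lambda of the exponential survival model
    log_hr: float = 0.7                # beta: hazard multiplier exp(-beta * CTIS)
    censoring: float = 0.3             # target censoring fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cancer_types.values()) - 1.0) > 1e-9:
            raise ValueError("cancer-type proportions must sum to 1")
        if not 0.0 <= self.reversal_strength <= 1.0:
            raise ValueError("reversal_strength must lie in [0, 1]")
        for name in ("event_rate", "mutation_background", "cnv_background", "censoring"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        planted = self.n_sensitizers + self.n_resistors + self.n_decoys
        if planted > 0 and self.event_rate == 0.0:
            raise ValueError("event_rate = 0 with planted genes is infeasible")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _gene_universe(spec: SyntheticSpec) -> dict[str, list[str]]:
    sens = [f"SEN{i:02d}" for i in range(1, spec.n_sensitizers + 1)]
    res = [f"RES{i:02d}" for i in range(1, spec.n_resistors + 1)]
    dec = [f"DEC{i:02d}" for i in range(1, spec.n_decoys + 1)]
    sgl = [f"SGL{i:02d}" for i in range(1, spec.n_singletons + 1)]
    ogs = [f"OG{i:02d}" for i in range(1, spec.n_ogs + 1)]
    tsgs = [f"TSG{i:02d}" for i in range(1, spec.n_tsgs + 1)]
    imm = [f"IMM{i:02d}" for i in range(1, 21)]
    cyt = ["GZMA", "PRF1"]
    mhc = ["HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2", "NLRC5", "PSMB8", "PSMB9"]
    anti_ft = [f"AFT{i:02d}" for i in range(1, 13)]
    pro_ft = [f"PFT{i:02d}" for i in range(1, 13)]
    special = sens + res + dec + sgl + ogs + tsgs + imm + cyt + mhc + anti_ft + pro_ft
    n_bg = spec.n_genes - len(special)
    if n_bg < 0:
        raise ValueError("n_genes too small for the planted gene layout")
    bg = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    return {"sensitizers": sens, "resistors": res, "decoys": dec,
            "singletons": sgl, "ogs": ogs, "tsgs": tsgs, "immune": imm,
            "cyt": cyt, "mhc": mhc, "anti_features": anti_ft,
            "pro_features": pro_ft, "background": bg,
            "all": special + bg}


def _gene_sets(universe: dict) -> GeneSetCollection:
    return GeneSetCollection({
        "immune": list(universe["immune"]),
        "CYT": list(universe["cyt"]),
        "MHC": list(universe["mhc"]),
    })


def _feature_catalog(universe: dict) -> pd.DataFrame:
    rows = []
    anti, pro = universe["anti_features"], universe["pro_features"]
    for i in range(0, len(anti), 2):
        rows.append((f"anti_feat_{i // 2 + 1}", "immune_cell", "anti_tumor", anti[i:i + 2]))
    for i in range(0, len(pro), 2):
        rows.append((f"pro_feat_{i // 2 + 1}", "immune_cell", "pro_tumor", pro[i:i + 2]))
    return pd.DataFrame(rows, columns=["feature", "category", "polarity", "genes"]
                        ).set_index("feature")


def make_cohort(spec: SyntheticSpec) -> tuple[OmicsCohort, dict]:
    """Generate a multi-omics cohort with planted regulator/driver events.

    Returns (cohort, truth). ``truth`` holds the planted gene lists, the
    planted per-sample event matrix (mechanism-injected), the full event
    matrix implied by the calling rules on the realized layers (computed here
    with an independent inline evaluation), the simulator's signature gene
    sets and feature catalog, and the planted network edges.
    """
    rng = spec.rng("cohort")
    uni = _gene_universe(spec)
    genes = uni["all"]
    samples = [f"S{i:04d}" for i in range(1, spec.n_samples + 1)]

    cts = list(spec.cancer_types)
    probs = np.array([spec.cancer_types[c] for c in cts])
    cancer = rng.choice(cts, size=spec.n_samples, p=probs)
    subtype = rng.choice(["C1", "C2", "C3", "C4", "C5", "C6"], size=spec.n_samples)
    age = np.clip(rng.normal(60, 10, size=spec.n_samples), 25, 90)
    annotations = pd.DataFrame({
        "cancer_type": cancer, "immune_subtype": subtype, "age": np.round(age, 1),
    }, index=samples)

    baseline = rng.normal(8.0, 1.0, size=len(genes))
    ct_offset = {c: rng.normal(0.0, 0.5, size=len(genes)) for c in cts}
    noise = rng.normal(0.0, 1.0, size=(len(genes), spec.n_samples))
    expr = np.empty_like(noise)
    for j, s in enumerate(samples):
        expr[:, j] = baseline + ct_offset[cancer[j]] + noise[:, j]
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    cnv_arr = np.zeros((len(genes), spec.n_samples), dtype=int)
    bg_mask = rng.random(cnv_arr.shape) < spec.cnv_background
    cnv_vals = rng.choice([-1, 1], size=cnv_arr.shape)
    cnv_arr[bg_mask] = cnv_vals[bg_mask]
    cnv = pd.DataFrame(cnv_arr, index=genes, columns=samples)

    mut_rows: list[tuple[str, str, str, float]] = []
    # background mutations, mostly benign
    bg_mut = rng.random((len(genes), spec.n_samples)) < spec.mutation_background
    gidx, sidx = np.nonzero(bg_mut)
    for g, s in zip(gidx, sidx):
        if rng.random() < 0.3:
            cons = str(rng.choice(LOF))
            dp = np.nan
        else:
            cons = "missense"
            dp = float(np.round(rng.random(), 3))
        mut_rows.append((samples[s], genes[g], cons, dp))

    # planted regulator events: injected into a randomly chosen omics layer
    # such that the corresponding calling clause holds by construction
    planted_genes = uni["sensitizers"] + uni["resistors"] + uni["decoys"]
    driver_genes = uni["ogs"] + uni["tsgs"]
    events = pd.DataFrame(0, index=planted_genes + driver_genes, columns=samples,
                          dtype=np.int8)

    stratum_mean = {}
    for c in cts:
        stratum_mean[c] = baseline + ct_offset[c]
    gene_pos = {g: i for i, g in enumerate(genes)}

    def inject_low_expression(gene: str, sample_j: int) -> None:
        mu = stratum_mean[cancer[sample_j]][gene_pos[gene]]
        expr.iloc[gene_pos[gene], sample_j] = mu - 6.0

    def inject_high_expression(gene: str, sample_j: int) -> None:
        mu = stratum_mean[cancer[sample_j]][gene_pos[gene]]
        expr.iloc[gene_pos[gene], sample_j] = mu + 6.0

    for gene in planted_genes + uni["tsgs"]:
        flags = rng.random(spec.n_samples) < spec.event_rate
        for j in np.nonzero(flags)[0]:
            events.loc[gene, samples[j]] = 1
            mech = rng.choice(["mutation", "cnv", "expression"], p=[0.5, 0.3, 0.2])
            if mech == "mutation":
                if rng.random() < 0.5:
                    mut_rows.append((samples[j], gene, str(rng.choice(LOF)), np.nan))
                else:
                    mut_rows.append((samples[j], gene, "missense",
                                     float(np.round(rng.uniform(0.51, 1.0), 3))))
            elif mech == "cnv":
                cnv.loc[gene, samples[j]] = -2
            else:
                inject_low_expression(gene, j)

    for gene in uni["ogs"]:
        flags = rng.random(spec.n_samples) < spec.event_rate
        for j in np.nonzero(flags)[0]:
            events.loc[gene, samples[j]] = 1
            if rng.random() < 0.6:
                cnv.loc[gene, samples[j]] = 2
            else:
                inject_high_expression(gene, j)

    # immune-signature shifts: -delta per sensitizer event, +delta per resistor
    # event on immune-oriented genes; opposite sign on pro-tumor feature genes
    sens_counts = events.loc[uni["sensitizers"]].sum(axis=0).to_numpy() \
        if uni["sensitizers"] else np.zeros(spec.n_samples)
    res_counts = events.loc[uni["resistors"]].sum(axis=0).to_numpy() \
        if uni["resistors"] else np.zeros(spec.n_samples)
    immune_shift = spec.effect_size * (res_counts - sens_counts)
    immune_oriented = uni["immune"] + uni["cyt"] + uni["mhc"] + uni["anti_features"]
    expr.loc[immune_oriented] += immune_shift
    expr.loc[uni["pro_features"]] -= immune_shift

    # driver events depress sensitizer expression and raise resistor expression
    driver_counts = events.loc[driver_genes].sum(axis=0).to_numpy() \
        if driver_genes else np.zeros(spec.n_samples)
    expr.loc[uni["sensitizers"]] -= spec.driver_effect * driver_counts
    expr.loc[uni["resistors"]] += spec.driver_effect * driver_counts

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "consequence",
                                                "damage_prob"])
    cohort = OmicsCohort(expr=expr, mutations=mutations, cnv=cnv,
                         annotations=annotations)

    truth = {
        "sensitizers": uni["sensitizers"],
        "resistors": uni["resistors"],
        "decoys": uni["decoys"],
        "singletons": uni["singletons"],
        "ogs": uni["ogs"],
        "tsgs": uni["tsgs"],
        "planted_events": events,
        "gene_sets": _gene_sets(uni),
        "feature_catalog": _feature_catalog(uni),
        "network_edges": [(r, d) for d in driver_genes
                          for r in uni["sensitizers"] + uni["resistors"]],
        "inactivation_truth": _expected_inactivation(
            expr, mutations, cnv, annotations,
            planted_genes + uni["tsgs"]),
    }
    return cohort, truth


def _expected_inactivation(expr, mutations, cnv, annotations, genes) -> pd.DataFrame:
    """Inline, loop-based re-evaluation of the inactivation rules.

    Kept deliberately separate from :mod:`immunoscreen.status` so the tests
    can compare the pipeline callers against what the generated layers imply.
    """
    samples = list(expr.columns)
    cancer = annotations["cancer_type"]
    z = pd.DataFrame(index=genes, columns=samples, dtype=float)
    for ct in cancer.unique():
        cols = [s for s in samples if cancer[s] == ct]
        block = expr.loc[genes, cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        z.loc[:, cols] = block.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    deleterious = set()
    for _, row in mutations.iterrows():
        cons, dp = row["consequence"], row["damage_prob"]
        if cons in LOF or (cons == "missense" and not pd.isna(dp) and dp > 0.5):
            deleterious.add((row["sample"], row["gene"]))
    out = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for g in genes:
        for s in samples:
            if ((s, g) in deleterious or cnv.at[g, s] == -2
                    or z.at[g, s] <= -2.0):
                out.at[g, s] = 1
    return out


def make_screens(spec: SyntheticSpec) -> tuple[dict[str, pd.DataFrame], list]:
    """Per-screen hit tables with planted recurrent hits.

    Planted sensitizers (and sensitizer-like decoys) are enriched in >= 2
    screens; resistors (and resistor-like decoys) depleted in >= 2; singleton
    genes are significant in exactly one screen; everything else is neutral
    (adjusted p >= 0.2). Returns ({screen_id: hit table}, [ScreenMetadata]).
    """
    from .io import ScreenMetadata

    if spec.n_screens < 2:
        raise ValueError("need at least 2 screens")
    rng = spec.rng("screens")
    uni = _gene_universe(spec)
    genes = uni["all"]
    screen_ids = [f"SIMSCR{i:02d}" for i in range(1, spec.n_screens + 1)]

    half = spec.n_decoys // 2
    enriched_planted = uni["sensitizers"] + uni["decoys"][:half]
    depleted_planted = uni["resistors"] + uni["decoys"][half:]

    tables = {}
    for sid in screen_ids:
        lfc = rng.normal(0.0, 0.3, size=len(genes))
        p_pos = rng.uniform(0.2, 1.0, size=len(genes))
        p_neg = rng.uniform(0.2, 1.0, size=len(genes))
        tables[sid] = pd.DataFrame({"gene": genes, "lfc": lfc,
                                    "adj_p_pos": p_pos, "adj_p_neg": p_neg})

    def plant(gene: str, sids: list[str], direction: int) -> None:
        for sid in sids:
            tab = tables[sid]
            i = tab.index[tab["gene"] == gene][0]
            tab.at[i, "lfc"] = direction * rng.uniform(1.0, 3.0)
            col = "adj_p_pos" if direction > 0 else "adj_p_neg"
            tab.at[i, col] = rng.uniform(1e-5, 0.01)

    for gene in enriched_planted:
        k = int(rng.integers(2, spec.n_screens + 1))
        plant(gene, list(rng.choice(screen_ids, size=k, replace=False)), +1)
    for gene in depleted_planted:
        k = int(rng.integers(2, spec.n_screens + 1))
        plant(gene, list(rng.choice(screen_ids, size=k, replace=False)), -1)
    for i, gene in enumerate(uni["singletons"]):
        sid = screen_ids[int(rng.integers(0, spec.n_screens))]
        plant(gene, [sid], +1 if i % 2 == 0 else -1)

    meta = [
        ScreenMetadata(
            screen_id=sid, study_id=f"SIMSTUDY{i // 2 + 1:02d}",
            cancer_type=str(rng.choice(list(spec.cancer_types))),
            setting=str(rng.choice(["in_vitro", "in_vivo"], p=[0.75, 0.25])),
            library_scale=str(rng.choice(["genome_scale", "focused"], p=[0.85, 0.15])),
            organism=str(rng.choice(["mouse", "human"], p=[0.9, 0.1])),
            algorithm=str(rng.choice(["MAGeCK", "DrugZ"])),
            icb_treated=False,
        )
        for i, sid in enumerate(screen_ids)
    ]
    return tables, meta


def make_drug_matrix(
    spec: SyntheticSpec, query: QuerySignature, genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Drug-induced expression-change matrix with planted reversal drugs.

    Background drugs carry iid standard-normal profiles; each of the
    ``n_reversers`` planted drugs draws query-up genes from N(-3*rho, 1) and
    query-down genes from N(+3*rho, 1), i.e. it reverses the query with
    strength rho. Returns (matrix, clinical-phase annotations [all
    "launched"], truth dict with the planted drug ids).
    """
    if not query.up and not query.down:
        raise ValueError("query signature is empty")
    rng = spec.rng("drugs")
    if genes is None:
        genes = _gene_universe(spec)["all"]
    drugs = [f"DRUG{i:03d}" for i in range(1, spec.n_drugs + 1)]
    mat = rng.normal(0.0, 1.0, size=(len(genes), spec.n_drugs))
    matrix = pd.DataFrame(mat, index=genes, columns=drugs)
    reversers = sorted(str(d) for d in
                       rng.choice(drugs, size=spec.n_reversers, replace=False))
    shift = 3.0 * spec.reversal_strength
    up = [g for g in query.up if g in matrix.index]
    down = [g for g in query.down if g in matrix.index]
    for d in reversers:
        matrix.loc[up, d] = rng.normal(-shift, 1.0, size=len(up))
        matrix.loc[down, d] = rng.normal(+shift, 1.0, size=len(down))
    phases = pd.Series("launched", index=drugs, name="clinical_phase")
    return matrix, phases, {"reversers": reversers}


def make_survival(
    spec: SyntheticSpec, ctis: pd.Series, annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Exponential survival whose hazard decreases with CTIS, plus censoring.

    T ~ Exponential(rate = lambda * exp(-beta * CTIS)); censoring times are
    c * Uniform(0, 1) with c calibrated by bisection so the realized censoring
    fraction matches the spec's target. Returns a frame indexed by sample with
    columns time, event (plus any annotation columns passed in).
    """
    if spec.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = spec.rng("survival")
    x = ctis.to_numpy(dtype=float)
    rate = spec.baseline_hazard * np.exp(-spec.log_hr * x)
    t = rng.exponential(1.0 / rate)
    u = rng.uniform(0.0, 1.0, size=t.size)
    target = spec.censoring

    def censored_fraction(c: float) -> float:
        return float(np.mean(c * u < t))

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
    c = np.sqrt(lo * hi)
    cens = c * u
    time = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    time = np.maximum(time, 1e-6)
    out = pd.DataFrame({"time": time, "event": event}, index=ctis.index)
    if annotations is not None:
        out = out.join(annotations)
    return out


def write_inputs(spec: SyntheticSpec, outdir) -> dict:
    """Materialize every pipeline input under ``outdir`` in the repo formats.

    Emits expr/cnv/dependency/drug TSV matrices, MAF-lite mutations, sample
    annotations + survival, per-screen hit TSVs, screen metadata, signature
    GMT, feature catalog TSV, drug-phase TSV and ``truth.json``. Returns the
    truth dictionary (with frames converted to serializable form).
    """
    import json
    from pathlib import Path

    from .io import write_gmt, write_matrix
    from .survival import DEFAULT_PANEL, CTISPanel, ctis_score

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "screens").mkdir(exist_ok=True)

    cohort, truth = make_cohort(spec)
    tables, meta = make_screens(spec)

    write_matrix(cohort.expr, outdir / "expr.tsv")
    write_matrix(cohort.cnv, outdir / "cnv.tsv")
    cohort.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False,
                            na_rep="NA", float_format="%.12g")

    panel = CTISPanel(sensitizers=tuple(truth["sensitizers"][:4]),
                      resistors=tuple(truth["resistors"][:2]))
    ctis = ctis_score(cohort.expr, panel)
    surv = make_survival(spec, ctis, cohort.annotations)
    anno = cohort.annotations.join(surv[["time", "event"]]).rename(
        columns={"time": "os_time", "event": "os_event"})
    anno.to_csv(outdir / "annotations.tsv", sep="\t", na_rep="NA",
                float_format="%.12g", index_label="sample")

    for sid, tab in tables.items():
        tab.to_csv(outdir / "screens" / f"{sid}.tsv", sep="\t", index=False,
                   na_rep="NA", float_format="%.12g")
    meta_df = pd.DataFrame([{
        "screen_id": m.screen_id, "study_id": m.study_id,
        "cancer_type": m.cancer_type, "setting": m.setting,
        "library_scale": m.library_scale, "organism": m.organism,
        "algorithm": m.algorithm, "icb_treated": str(m.icb_treated).lower(),
    } for m in meta])
    meta_df.to_csv(outdir / "screen_metadata.tsv", sep="\t", index=False)

    write_gmt(truth["gene_sets"], outdir / "signatures.gmt")
    feats = truth["feature_catalog"].copy()
    feats["genes"] = feats["genes"].map(",".join)
    feats.to_csv(outdir / "features.tsv", sep="\t", index_label="feature")

    # dependency scores: planted regulators proliferation-independent by design
    rng = spec.rng("deps")
    dep_genes = truth["sensitizers"] + truth["resistors"] + truth["decoys"]
    dep = pd.DataFrame(rng.uniform(-0.2, 0.2, size=(len(dep_genes), 20)),
                       index=dep_genes,
                       columns=[f"CELL{i:02d}" for i in range(1, 21)])
    write_matrix(dep, outdir / "dependency.tsv")

    drivers = pd.DataFrame(
        [(g, "OG") for g in truth["ogs"]] + [(g, "TSG") for g in truth["tsgs"]],
        columns=["gene", "driver_class"])
    drivers.to_csv(outdir / "drivers.tsv", sep="\t", index=False)

    query = QuerySignature(up=list(truth["sensitizers"]),
                           down=list(truth["resistors"]))
    drug_matrix, phases, drug_truth = make_drug_matrix(spec, query)
    write_matrix(drug_matrix, outdir / "drugs.tsv")
    phases.rename_axis("drug").reset_index().to_csv(
        outdir / "drug_phases.tsv", sep="\t", index=False)

    serializable = {
        k: truth[k] for k in ("sensitizers", "resistors", "decoys",
                              "singletons", "ogs", "tsgs")
    }
    serializable["reversers"] = drug_truth["reversers"]
    serializable["network_edges"] = truth["network_edges"]
    serializable["ctis_panel"] = {"sensitizers": list(panel.sensitizers),
                                  "resistors": list(panel.resistors)}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1, sort_keys=True)
    return serializable
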