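"""Shared fixtures: one synthetic world generated once per session."""

import numpy as np
import pandas as pd
import pytest

from immunoscreen.simulate import SyntheticSpec, make_cohort, make_screens


@pytest.fixture(scope="session")
def world():
    """Default-parameter synthetic cohort with ground truth (seed 1)."""
    spec = SyntheticSpec(seed=1)
    cohort, truth = make_cohort(spec)
    return {"spec": spec, "cohort": cohort, "truth": truth}


@pytest.fixture(scope="session")
def screen_world():
    spec = SyntheticSpec(seed=1)
    tables, meta = make_screens(spec)
    return {"spec": spec, "tables": tables, "meta": meta}


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Materialized pipeline inputs + truth.json for end-to-end tests."""
    from immunoscreen.simulate import write_inputs

    out = tmp_path_factory.mktemp("sim")
    spec = SyntheticSpec(seed=7)
    truth = write_inputs(spec, out)
    return {"dir": out, "truth": truth, "spec": spec}


@pytest.fixture()
def toy_cohort():
    """Tiny 3-gene x 4-sample cohort with hand-checkable omics layers."""
    from immunoscreen.status import OmicsCohort

    samples = ["s1", "s2", "s3", "s4"]
    expr = pd.DataFrame(
        [[5.0, 5.1, 4.9, 5.0],
         [2.0, 8.0, 5.0, 5.0],
         [1.0, 1.1, 0.9, 1.0]],
        index=["G1", "G2", "G3"], columns=samples)
    cnv = pd.DataFrame(
        [[0, -2, 0, 1],
         [2, 0, -1, 0],
         [0, 0, 0, -2]],
        index=["G1", "G2", "G3"], columns=samples)
    mutations = pd.DataFrame({
        "sample": ["s1", "s3", "s4"],
        "gene": ["G1", "G2", "G3"],
        "consequence": ["frameshift", "missense", "missense"],
        "damage_prob": [np.nan, 0.9, 0.2],
    })
    annotations = pd.DataFrame({"cancer_type": ["a", "a", "a", "a"]}, index=samples)
    return OmicsCohort(expr=expr, mutations=mutations, cnv=cnv,
                       annotations=annotations, stratify_z=None)
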