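"""Run every stage end-to-end on generated inputs and inspect the manifest.

The pipeline reads only files, writes only files, and records every threshold
plus SHA-256 checksums of all inputs and outputs; re-running the same config
is byte-identical.
"""

import json
import tempfile
from pathlib import Path

from immunoscreen.pipeline import PipelineConfig, run_pipeline
from immunoscreen.simulate import SyntheticSpec, write_inputs

with tempfile.TemporaryDirectory() as tmp:
    indir, outdir = Path(tmp) / "inputs", Path(tmp) / "run"
    truth = write_inputs(SyntheticSpec(seed=7), indir)
    cfg = PipelineConfig(
        indir=str(indir), outdir=str(outdir),
        ctis_sensitizers=tuple(truth["ctis_panel"]["sensitizers"]),
        ctis_resistors=tuple(truth["ctis_panel"]["resistors"]))
    run_pipeline(cfg)

    manifest = json.loads((outdir / "manifest.json").read_text())
    print("stages wrote:", sorted(manifest["outputs"]))
    print("alpha:", manifest["config"]["alpha"],
          "| min_screens:", manifest["config"]["min_screens"],
          "| lfc_cut:", manifest["config"]["lfc_cut"])
    import pandas as pd
    drugs = pd.read_csv(outdir / "drugs_ranked.tsv", sep="\t", index_col=0)
    print("top-3 drugs:", list(drugs.index[:3]), "| planted:", truth["reversers"])
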