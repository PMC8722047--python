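"""Three-signature association filter: keep functionally consistent regulators.

A sensitizer is kept iff its inactivation associates negatively (adj. p <
0.05) with ALL of immune, CYT and MHC scores after adjusting for cancer type;
resistors need positive associations with all three.
"""

from immunoscreen.associations import (associate_signatures,
                                       filter_functional_regulators)
from immunoscreen.scoring import signature_scores
from immunoscreen.screens import build_catalog, classify_hits
from immunoscreen.simulate import SyntheticSpec, make_cohort, make_screens
from immunoscreen.status import build_status_matrix

spec = SyntheticSpec(seed=1)
cohort, truth = make_cohort(spec)
tables, _ = make_screens(spec)
catalog = build_catalog({s: classify_hits(t) for s, t in tables.items()})
status = build_status_matrix(cohort, list(catalog.table.index))
scores = signature_scores(cohort.expr, truth["gene_sets"])
assoc = associate_signatures(scores, status, cohort.annotations)
functional = filter_functional_regulators(assoc, catalog, alpha=0.05)

true = set(truth["sensitizers"]) | set(truth["resistors"])
kept = set(functional.table.index)
print(f"catalog {len(catalog)} -> functional {len(kept)}")
print(f"recall {len(kept & true) / len(true):.2f}, "
      f"precision {len(kept & true) / len(kept):.2f}")
# The filter removes the planted null-effect decoys (recurrent in the screens
# but with no immune-signature effect) while keeping the true regulators.
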