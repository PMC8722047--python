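"""Rank drugs by immune-signature reversal with XSum, KS and RGES + Stuart Q.

The query asks for drugs that push sensitizer expression up and resistor
expression down; three scoring methods are fused by the Stuart order
statistic, so only drugs consistently near the top of every method get a
small Q.
"""

from immunoscreen.connectivity import (QuerySignature, rank_aggregate,
                                       score_drugs)
from immunoscreen.simulate import SyntheticSpec, make_drug_matrix

spec = SyntheticSpec(seed=1)
query = QuerySignature(up=[f"SEN{i:02d}" for i in range(1, 9)],
                       down=[f"RES{i:02d}" for i in range(1, 9)])
matrix, phases, truth = make_drug_matrix(spec, query)

raw = score_drugs(query, matrix, methods=("xsum", "ks", "rges"), n_extreme=500)
result = rank_aggregate(raw)
cols = ["xsum", "ks", "rges", "q", "final_rank"]
print(result.table[cols].head(5).to_string(float_format=lambda v: f"{v:.3g}"))
print("\nplanted reversers:", truth["reversers"])
# The three planted reversal drugs occupy the top of the fused ranking: every
# method scores them strongly negative (reversal), so their rank ratios are
# tiny and the joint uniform-order-statistic probability Q is smallest.
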