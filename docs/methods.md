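# Methods

## Scope and model

The package implements the integrative layer that sits downstream of
published screen-analysis tools (MAGeCK, DrugZ): it consumes per-gene hit
tables and never touches sgRNA counts. All analyses share one statistical
template — regress a per-sample readout on a binary functional status,
adjust for cancer type, BH-correct one declared family of tests per run, and
apply a sign-plus-significance rule.

## Event calling

A sample carries an **inactivation** event for a gene iff any of three
clauses holds: (i) a deleterious mutation — one of frameshift, stopgain,
startloss, stoploss, or a missense variant with damage probability strictly
greater than 0.5 (missense with a missing probability is conservatively
benign); (ii) deep deletion, GISTIC code exactly −2; (iii) standardized
expression z ≤ −2 (inclusive). **Activation** uses GISTIC +2 or z ≥ +2 and
never consults mutations, because gain-of-function point-mutation prediction
is unreliable. Damage probabilities are inputs (PolyPhen2-style); no variant
effect prediction is performed.

Expression is standardized per gene *within cancer type* by default
(configurable to cohort-wide via `OmicsCohort(stratify_z=None)`): without
stratification, tissue-of-origin expression differences dominate the ±2
tails and the z clause degenerates into a tissue classifier. Genes constant
within a stratum get z = 0. Genes absent from one omics layer contribute
`False` for that clause rather than aborting; genes absent from all layers
are skipped with a logged count.

## Immune scores

* **immune** — an ssGSEA-style statistic: rank all genes by descending
  expression (ties broken lexicographically by symbol, for determinism);
  walking down the list, score = Σ_i [P_in(i) − P_out(i)] where P_in is the
  weighted fraction of set genes seen so far (weight = descending-rank
  value^α, α = 0.25) and P_out the unweighted fraction of non-set genes.
* **CYT** — geometric mean of GZMA and PRF1 on the linear scale with a 0.01
  pseudocount. `signature_scores` reports it on the log scale by default
  (`cyt_log=True`): the geometric mean of log-normal expression is itself
  log-normal, and OLS on the raw value is dominated by the right tail; on
  the log scale the status coefficient reads as a log-fold effect on
  cytolytic activity. The `cyt_score` primitive itself stays linear.
* **MHC** — mean per-gene z-scored expression over the antigen-presentation
  set (HLA-A/B/C, B2M, TAP1/2, NLRC5, PSMB8/9 by default).

All three are oriented higher = stronger anti-tumor immunity. The packaged
immune/MHC gene sets and the immune-feature catalog are structural stand-ins
(the source supplementary lists are not distributed); every set is
replaceable via GMT/TSV.

## Association engine

Continuous readouts use OLS with dummy-coded covariates (reference = most
frequent level); binary outcomes use logistic regression (statsmodels,
maximum 50 iterations, tolerance 1e−8). Perfect separation and
non-convergence yield flagged records with missing p — never ±∞ odds ratios.
Status vectors with fewer than `min_events` (default 5) members in either
class are flagged "insufficient events"; a constant response returns
coefficient 0, p = 1 by contract. BH adjustment is a hand-rolled step-up
(cross-checked against statsmodels in the tests) that passes missing values
through without counting them in the family size.

Decision rules, with their defaults:

| filter | rule |
|---|---|
| functional regulator | all three signatures: adj. p < 0.05 and role-consistent sign |
| subtype-specific | one-vs-rest logistic: adj. p < 0.05 and log2 OR > 1.5 |
| S-/R-related feature | significant, polarity × role direction match; counts summed over cancer types |
| OG/TSG edge | Wilcoxon adj. p < 0.05 and lfc beyond ∓0.25 (sign by role) |
| proliferation-independent | mean dependency in [−0.25, 0.25], endpoints inclusive |

Feature associations are computed stratified within each cancer type (no
covariates) because the counting rule is defined per cancer type; the
signature filter instead pools samples with cancer-type dummies.

## CTIS and survival

CTIS = mean(sensitizer panel) − mean(resistor panel) on per-gene z-scored
log expression by default (raw log scale via `scale="raw"`); z-scoring makes
the two panel halves commensurable across cohorts. Cox regression uses
lifelines (Efron ties, CI from the observed information); the log-rank test
is Mantel–Cox. Harrell's C counts a pair comparable when the shorter
observed time is an event, with score ties at 0.5; ROC AUC is the
Mann–Whitney statistic with the same tie convention. KM dichotomization uses
the cohort median.

The greedy panel selector (`select_panel_greedy`) is a documented,
non-equivalent substitute for minimal-depth random-survival-forest gene
selection: forward selection maximizing mean cross-validated C-index of the
CTIS-form score, deterministic given the seed (fold assignment) and
candidate order. The published six-gene panel ships as the default
configuration so downstream stages never depend on the substitute.

## Connectivity scoring

KS enrichment of tag positions V(1..t) among n genes: a = max_j [j/t −
V(j)/n], b = max_j [V(j)/n − (j−1)/t], ES = a if a ≥ b else −b. The KS
connectivity score is ES_up − ES_down zeroed when both share a sign, then
scaled across the drug cohort (positives by the max, negatives by |min| —
rank-preserving within sign, so aggregation is unaffected). RGES is the same
difference without the zeroing; XSum sums drug change values over query
genes restricted to the union of the 500 most extreme genes per tail
(truncated for small matrices). All three are natively negative-for-reversal,
so ranks are taken ascending without negation; the orientation map is
explicit in `METHOD_ORIENTATION`. Ties get average ranks; the rank-ratio
denominator is the number of drugs after phase filtering (default: phase 3
or launched, i.e. past phase II trials). Drugs with no query overlap are
excluded with a logged reason, not silently ranked. Stuart's Q uses the
exact factorial recursion V_k = Σ_i (−1)^(i−1) V_{k−i} r_(N−k+1)^i / i!,
Q = N!·V_N; final ordering is ascending Q with ties broken by mean rank
ratio then drug id.

## Synthetic world

The generator emulates the statistical structure the analysis assumes, not
any real dataset's marginals. Defaults (all fixed before the recovery tests
were run): 600 samples, 2000 genes, four cancer types (30/25/25/20%), 8
planted sensitizers, 8 resistors, 8 null-effect decoys (recurrent in screens
but δ = 0), 6 single-screen singletons, 4 OGs + 4 TSGs; event rate π = 0.15;
immune effect δ = 1.0 (log2 shift of immune-oriented genes per event, sign
by role; pro-tumor feature genes shift opposite); driver effect 0.6 on
regulator expression; mutation background 1%, CNV background 5% (±1 codes);
200 drugs with 3 planted reversers at strength ρ = 1 (query-up genes drawn
from N(−3ρ, 1), down from N(+3ρ, 1)); exponential survival with baseline
rate 0.1 and hazard multiplier exp(−0.7·CTIS); 30% target censoring via
uniform censoring times calibrated by bisection. One integer seed drives an
independent substream per generator, so adding a generator never perturbs
the others.

Planted regulator events are injected into a randomly chosen omics layer
(mutation 50%, deep deletion 30%, expression outlier at stratum mean − 6
log2 units 20%) so each satisfies the calling rules by construction; the
truth object also records the event matrix the realized layers imply
(including chance expression tails), computed by an inline evaluator kept
separate from the pipeline callers.

What a green test does establish: the boolean rules, scoring statistics and
rank fusion are implemented exactly (oracle tests), and the pipeline
recovers planted effects of realistic size at cohort scale (recovery tests).
What it does not: robustness to real-data pathologies absent from the
generator — batch effects, correlated gene modules, subclonal mutations,
copy-number/expression dosage coupling, or CMap replicate structure.

## Numerical choices

Strict inequalities at p-value thresholds and lfc cutoffs; inclusive z and
CERES interval endpoints — exactly as the rules are stated. Expression-rank
and drug-profile ties break lexicographically; stable (mergesort) sorts
throughout so reruns are byte-identical; TSV floats at 12 significant
digits. The censoring calibration bisects the scale of the uniform censoring
distribution over [1e−9, 1e9] (200 geometric steps). Catalog role conflicts
(a gene enriched in some screens, depleted in others) resolve by majority
support; exact ties are dropped and recorded.

## Known limitations

No sgRNA-level statistics or read-count normalization; no ortholog lookup
service (a two-column mapping table is an input); no GO similarity, MSI or
tumor-vs-normal side analyses; no time-dependent ROC; one profile per drug
(no CMap instance collapsing); the normalized resistor-sensitizer ratio
statistic has no recoverable definition and is not computed. The published
six-gene CTIS panel is configuration, not something the package can re-derive
from public data.
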