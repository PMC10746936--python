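# Methods

This note documents the statistical procedures implemented in `dicoexnet`,
the choices made where the methodology was genuinely open, the synthetic
data model used to exercise them, and the known limitations.

## Differential expression meta-analysis

Each cohort is analysed independently: per gene, a Welch two-sample
*t*-test of disease versus control on log2-scale expression (a
pooled-variance Student *t* is available via `equal_var=True`), with
Benjamini–Hochberg step-up adjustment across all genes of the cohort.  A
gene is a DEG when `adj_p < alpha` (default 0.05) **and**
`|log2FC| ≥ log2(fc_threshold)` (default fc_threshold = 2; on log2 data a
two-fold linear change and |log2FC| ≥ 1 coincide, which is why matrices
are required to be log2-scale).  `log2FC` is the difference of group
means; `direction` is its sign, and genes with log2FC exactly 0 are
excluded from the up/down dichotomy.  The meta-analysis is the
intersection of the per-cohort DEG symbol sets — deliberately
conservative: a gene must survive testing in *every* cohort.  Direction
disagreements across cohorts are reported (logged) but not enforced;
downstream signature construction uses the majority direction.

Over-representation uses the one-sided hypergeometric tail
P(X ≥ overlap) with each collection set first intersected with the
universe, and BH adjustment across sets.  The universe defaults to the
genes present in the expression data, since an assay-independent universe
would overstate enrichment.

## Condition-wise correlation and the differential network

Cohorts are z-scored per gene *within each study* (sample n−1 standard
deviation; constant genes are dropped with a warning) before pooling, so
that between-cohort location/scale differences — batch effects — cannot
masquerade as correlation.  Duplicate gene symbols are collapsed to their
mean profile *before* z-scoring, because averaging standardized rows would
no longer have unit variance.  Samples of each condition are then
concatenated across cohorts and the Spearman rank correlation (average
ranks for ties) is computed for every unordered pair of the common-DEG
panel, once per condition: SCCd in disease, SCCh in control.  Pooling
before correlating (rather than averaging per-cohort correlation
matrices) uses every sample in a single estimate; it assumes the z-scoring
has removed cohort-level differences, which is exactly what it is for.

Two thresholds define the differential network:

* **p-critic** (per condition): `mean(SCC) + 1.96 · std(SCC)` over all
  off-diagonal pair values (each unordered pair once, sample standard
  deviation).  The default input distribution is the *signed* SCC values;
  significance of a pair means `|SCC| > p_critic`, covering both tails
  with the single cut-off.  An `absolute=True` variant feeds |SCC| into
  the statistic instead.  Note the statistic is adaptive: with ~125k
  mostly-null pairs it sits near the 2-sigma point of the null correlation
  spread (≈ 0.17 at 150 pooled samples), while in small panels dominated
  by correlated pairs it rises accordingly.
* **ε**: a pair is differentially co-expressed when
  `ε = |SCCd − SCCh| > 0.5`.  The absolute value is used (rather than the
  signed difference) so that disease-gained and disease-lost correlation
  are treated symmetrically; a pair must additionally be significantly
  linked in disease (`|SCCd| > p_critic(disease)`).

An optional pre-filter on the per-pair Spearman p-value (t-approximation,
p < 0.05) is available but off by default, since the p-critic rule
supersedes it.

### Module detection

The retained pairs form a simple undirected graph (edge attributes SCCd,
SCCh, ε).  Modules are found per connected component:

* a component that already has ≥ `min_size` nodes (default 5) and density
  `2E/(N(N−1)) ≥ density_threshold` (default 0.5) **is** a module as it
  stands;
* a sparser component is partitioned by deterministic greedy modularity
  maximization (Clauset–Newman–Moore, as implemented in networkx), and
  each resulting community is kept if it meets the same size/density
  criteria.

The first rule exists because greedy modularity, applied unconditionally,
will split a near-complete component: with ~10 % of edges missing at
random, a two-way split of a 20-node near-clique can carry modularity
≈ 0.02 > 0, and the partition then tracks the noise pattern of the missing
edges rather than any real structure.  A dense component already satisfies
the "highly clustered" criterion, so subdividing it serves no purpose.
Detection is deterministic given the node set (components and communities
are processed in sorted node order).

Density is always `2E/(N(N−1))`.  For a reported 21-node/45-edge module
this gives ≈ 21.4 %, not the 69 % sometimes quoted for such modules in the
applied literature; no alternative "density" metric reproducing such
figures is defined anywhere, so the standard formula is implemented and
the discrepancy is simply noted.  Correlation-pattern summaries (counts of
module pairs with SCC above `p_critic` / below `−p_critic` per condition)
report percentages against two denominators — all module pairs and the
per-condition significant-pair count — because published percentages of
this kind are frequently ambiguous about their denominator.

## Prognostic evaluation

The per-patient module score is the mean of the z-scored expression of the
module genes (genes absent from the validation matrix are logged and
skipped).  Patients are split at the median score (ties to "low"); the
high/low groups are compared with the Kaplan–Meier product-limit estimator
and the log-rank test (lifelines).  Events precede censorings at tied
times.  A module is flagged prognostic when the two-group log-rank
p < alpha (default 0.05).

Because tumour stage dominates cancer prognosis, two further analyses are
available when a stage column exists: a k-group log-rank across stages,
and a stage-stratified log-rank of the score split (observed−expected
vectors and hypergeometric covariance matrices accumulated per stratum and
summed before forming the chi-square; this one is computed directly rather
than through lifelines, whose k-group test does not expose strata).
Unknown-stage samples are excluded from the stage-involving analyses only.
Which combination of stage and module score an applied study "considered"
is usually under-specified; providing both readings avoids guessing.

## Drug repurposing and text mining

The module signature takes `up`/`down` membership and log2FC weights from
the DEG table (majority direction across cohorts in the pipeline).  A
drug library maps each drug to signed per-gene weights (positive =
induced).  The reversal score of a drug is the *negative* cosine
similarity between signature and drug weight vectors on their gene
intersection — +1 for a perfect reverser — and drugs are ranked by
descending score (ties by name), top-k (default 50) returned.  Cosine
reversal on a user-supplied library replaces proprietary
characteristic-direction services while preserving the "inverse effect"
semantics.  Caveat: on a one-gene intersection the cosine is ±1 by
construction, so with sparse libraries a `min_overlap` above the default 1
is advisable.

TF-IDF novelty: for each of four query contexts — the drug name alone, and
the name restricted to documents containing "thyroid cancer", "thyroid
carcinoma" or "cancer" — the sub-corpus is the matching documents, `tf` is
the total case-insensitive whole-phrase occurrence count of the name
across the sub-corpus, `idf = ln(N/df)` with N the sub-corpus size and df
the number of documents containing the name, and `tfidf = tf · idf` with
df = 0 defining tfidf = 0.  A drug is *novel* when tfidf = 0 under every
context.  Raw-count tf and ln-idf are fixed here because "TF-IDF" alone
does not pin down a variant; drug names are matched as exact phrases
without stemming since they are proper nouns.  Note the definition makes a
term mentioned in *every* document also score 0 (idf = 0); novelty is
therefore "no discriminating literature trace", not strictly "never
mentioned".

## Synthetic data model

`SimulationConfig` defaults describe the emulated study design: 5 cohorts
× 30+30 samples (150+150 pooled), 2000 genes with 500 planted DEGs (half
up, half down, log2 shift 1.5 ≈ 2.8-fold, comfortably past the two-fold
filter at n = 30+30 and noise sd 0.5), and a 20-gene module among the
DEGs.  Gene baselines are U(4, 12) on the log2 scale, shared across
cohorts, plus a N(0, 0.25) per-cohort batch offset; all noise is Gaussian.
Module genes load on a per-sample latent factor with loading a = 0.8 in
disease and 0 in control (unit total variance before the noise_sd scale),
giving population Pearson correlation a² = 0.64 between module genes in
disease — Spearman ≈ 0.62 — and ≈ 0 in control, i.e. exactly the
SCCd/SCCh separation the ε rule targets.  Loadings are all positive by
default (mean pairwise SCCd ≈ +0.62); `module_down_fraction` plants
negative loadings to produce mixed-sign correlation patterns.

Survival: event times are exponential with rate
`baseline · exp(beta · score)` (baseline 0.02 per month, beta 1 per unit
module score); censoring is independent U(0, u) with u calibrated by
bisection so the expected censored fraction matches `censoring_rate`
(default 20 %).  Stage is the score quartile — a deliberately strong
stage–module link.  Consequence: within each stage stratum the median
split is (nearly) constant, so the stage-stratified log-rank is degenerate
(statistic ≈ 0) on synthetic data; on real data, where stage is only
correlated with any module, the stratified test is informative.  The
validation cohort generator produces an independent tumour-only cohort of
module genes (n = 300) with survival driven by the *measured* module
score.

The corpus/library generator plants one exact reverser (negated signature
weights), decoys whose gene sets either miss the module or overlap it
substantially (a one-gene overlap would trivially score ±1), known drugs
mentioned a fixed number of times inside cancer-context abstracts, and
designated novel drug names that never occur.

What passing tests on these data do **not** show: robustness to heavy-
tailed or count-distributed expression (microarray/RNA-seq artefacts, RMA
preprocessing), probe-level effects, non-Gaussian correlation structure,
informative censoring, proportional-hazards violations, or stage measured
with error.  The generators are deliberately clean so that failures
indicate implementation defects rather than modelling mismatch.

## Numerical conventions and edge cases

* Sample (n−1) standard deviations throughout (z-scoring, p-critic).
* Welch *t* p-values that are NaN (zero variance in both groups with
  equal means) are set to 1: no evidence of change.
* BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`;
  inputs outside [0, 1] raise.
* Spearman via `scipy.stats.spearmanr` (average ranks); correlation
  requires ≥ 3 pooled samples; the 2-gene case is reshaped from scipy's
  scalar return.
* p-critic requires ≥ 2 pair values; with zero variance it degenerates to
  the common correlation value.
* Pair records are canonicalized with `gene_a < gene_b`; duplicate pairs
  collapse onto one network edge; self-loops are ignored.
* Median-split ties go to "low"; all-identical scores raise (no
  stratification is possible).
* Risk-set counts treat `time ≥ t` as at risk; log-rank variance terms
  with risk-set size ≤ 1 contribute nothing.
* The stratified chi-square uses the pseudo-inverse on the (k−1)-dim
  covariance block, so fully degenerate strata yield statistic 0, p = 1
  rather than an error.
* All generators draw from `numpy.random.default_rng(seed)` and are
  bit-reproducible under a fixed seed; the pipeline manifest records
  relative output paths so re-runs are byte-identical.

## Problem sizes used in the test suite

The suite exercises the full design at its default scale (5 × 60-sample
cohorts, 2000 genes) for module recovery (20 seeds) and prognostic
power/null rates (50 + 50 seeds at n = 300), 1000 null replicates for
log-rank calibration, and exhaustive small-universe enumeration (≤ 25)
for the hypergeometric test; unit tests use smaller configurations of the
same generators.  These sizes were chosen so the whole suite completes in
about a minute while keeping Monte-Carlo error well inside the asserted
bounds.
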