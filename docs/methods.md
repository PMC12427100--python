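# Methods

## Scope and model

`lipidprog` implements a lipidome-first prognosis analysis for a
~100-patient tumor cohort: species-level preprocessing and differential
abundance, over-representation of lipid characteristics, unsupervised
lipidome subtyping, per-lipid survival screening, and lipid–gene
correlation rollups. The analysis treats each lipid species as a
feature; all category-level statements (class, ether linkage, chain
length, unsaturation) are obtained by 2×2 over-representation against
the set of species that survived preprocessing — never against "all
species ever detected", since the tested universe is what defines
expectation under the null.

## Nomenclature

Shorthand grammar `CLASS[ O-] C:D[;H][/C:D[;H]…]` over a fixed
23-class vocabulary (19 ester classes + PC O-, PE O-, LPC O-, LPE O-).
`O-` and the typographic en-dash `O–` are both accepted and normalized,
because vendor exports differ. A single C:D token is a sum composition
(empty chain list); multiple tokens give per-chain resolution whose
sums must equal the stored totals (enforced invariant). The hydroxyl
count after `;` is parsed and stored although no downstream analysis
uses it. Unparseable names are dropped with a warning by default; a
strict mode raises. Chain-length and double-bond bins are half-open
`[lo, hi)` starting at 0 with an open-ended final bin; the default is
one bin per observed integer value, since no canonical binning exists —
callers doing coarse binning pass explicit boundaries.

## Preprocessing

Order is fixed: filter → impute → log₁₀, enforced through the matrix's
`scale` and missingness state (a second log transform or a transform of
an incomplete matrix raises).

* **Filter**: drop species whose missing fraction across *all* samples
  strictly exceeds 0.70 ("exceeding" read as strict, so a species
  missing in exactly 70 % is retained).
* **Impute**: each missing cell ← half the species' observed minimum.
  Zeros are converted to missing on ingest (below-detection-limit
  readout), which both motivates half-minimum imputation and makes the
  log transform total. Imputed values never exceed the observed
  minimum, and imputation is idempotent.
* **Transform**: element-wise log₁₀.

## Differential lipids

Two-tailed Student's (pooled-variance) *t*-tests on log₁₀ values —
`scipy.stats.ttest_ind` / `ttest_rel`, vectorized across species — with
Benjamini–Hochberg adjustment (`statsmodels`). The fold-change threshold
is stated in log₂ while tests run in log₁₀; the reconciliation is to
compute log₂ FC on the imputed *raw* group means
(`log2(mean_raw_A / mean_raw_B)`), avoiding a double transform.
Significance: adjusted *p* < 0.05 **and** |log₂ FC| ≥ 1. Zero-variance
species get *p* = 1 with a warning rather than NaN, so degenerate
synthetic fixtures behave deterministically. Tumor/adjacent-normal
designs are matched, but whether the original tests were paired is not
documented; the default is unpaired with a `paired` option.

## Fisher over-representation

Two-sided *p* by the point-probability (minimum-likelihood) method: sum
hypergeometric probabilities of all fixed-margin tables whose point
probability is ≤ the observed one (with the conventional 1 + 10⁻⁷
relative tolerance). The tail is accumulated with `logsumexp` over
`hypergeom.logpmf`, so a finite log₁₀ *p* is always available; values
below 2.2 × 10⁻¹⁶ additionally render as the display string
`"< 2.2e-16"`. The reported odds ratio is the sample cross-product
`ad/bc` (∞ when `bc = 0 < ad`), not the conditional MLE — simpler,
deterministic, and what printed 2×2 summaries use. Two-sided is the
default because depletion ("fewer than expected") is as meaningful as
enrichment; one-sided variants were deliberately not exposed to keep
the decision rule single.

## Subtyping

t-SNE (scikit-learn, PCA initialization) with output dimensionality 2,
perplexity 15 and 3000 gradient iterations on the log₁₀ matrix, all
retained species, Euclidean distances, no feature selection. Perplexity
is lowered with a warning when n ≤ 3·perplexity; fewer than 5 samples
is an error. K-means (k = 2, 10 restarts) runs on the 2-D embedding,
not the original matrix. Cluster → subtype labelling is the package's
own rule: the cluster with the higher mean log₁₀ abundance over
ether-linked species is "A" (the ether-high, poor-prognosis analogue).
A clinical labelling (by aggressiveness) is impossible for synthetic
data and would couple the subtyper to the survival table. The t-SNE
seed is a required parameter (default 42); identical matrix + seed
gives identical assignments.

## Survival screen

Per lipid: median dichotomization (high = strictly above the median,
ties to low, so "high" always strictly exceeds the median; constant
features are skipped with a reason), then

* **log-rank**: observed − expected events of the high group summed
  over distinct event times, scaled by the hypergeometric variance sum,
  χ² with 1 df;
* **Cox**: univariate proportional-hazards fit of the high/low
  indicator, Efron tie handling, safeguarded Newton iteration on the
  scalar partial likelihood, SE from the observed information,
  95 % CI = exp(β ± 1.96·SE). The scalar solver exists because the
  screen fits one model per species (~800 per cohort); the risk-set
  sums are vectorized over tied-time groups. `lifelines` (Cox and
  log-rank) and a brute-force partial-likelihood maximizer serve as
  independent oracles in the tests; Kaplan–Meier curves use lifelines
  directly. When one group has no events the likelihood is monotone;
  the result is flagged (`separation`) with HR 0/∞ instead of failing.

Selection uses the **raw** log-rank *p* < 0.05 (no multiplicity
correction), matching the screen's decision rule; a BH-adjusted column
is available and documented as a deviation. Whether the HR should come
from the dichotomized or the continuous covariate is ambiguous in this
design; the dichotomized reading is implemented (the solver accepts
numeric covariates, so the continuous variant is one call away).

## Trans-omics

Spearman ρ = Pearson on mid-ranks, computed for the full lipid × gene
grid by rank transformation and a single matrix product. *p* from the
*t*-approximation with n − 2 df; for n ≤ 9 an exact permutation
*p* (full n! enumeration) replaces it. Significance is joint:
|ρ| > 0.4 and *p* < 0.05, raw — no grid-wide correction, because the
rule is a screening heuristic, not an inference claim. Correlations are
species-level; a gene belongs to a class's set when significantly
correlated with ≥ 1 species of that class (a class-aggregate mode —
correlate log₁₀ of per-class summed raw abundances — is available via
`class_aggregate`). Gene matrices that look like raw counts/TPM
(max > 50) are log₂(x+1)-transformed on ingest; ranks make this
irrelevant for ρ but it keeps any downstream use of the matrix sane.

## Synthetic cohorts

Defaults emulate the study conditions: n = 100 samples, 800 species
across the full vocabulary with 160 (20 %) ether-linked, two planted
subtypes at a 50/50 split, +1.0 log₁₀ on every ether species in
subtype A, per-species log₁₀ baselines uniform on (−1, 2), Gaussian
noise sd 0.25 (log₁₀), logistic MNAR missingness (midpoint −1.0,
slope 4 on log₁₀ abundance, giving ~6 % missing cells concentrated in
low-abundance species), a 50-gene module driven by the per-sample mean
ether log-abundance (noise sd 0.3) among 1000 genes, and exponential
survival with baseline hazard 1/1000 days and log HR = log 2.5 for
subtype A. Censoring: uniform on (0, c) with c solved numerically so
the expected censoring fraction equals `censor_rate` (0.2) — genuinely
independent censoring, which matters for unbiased HR recovery — plus
administrative censoring at 2000 days. Species names are emitted in
shorthand so the parser sits in every tested path.

What the generator does **not** emulate: paired tumor/normal structure,
batch or drift effects, internal-standard normalization residue,
realistic class-specific abundance distributions, clinical covariates
beyond time/event, or correlated noise between species of the same
pathway. Passing tests therefore demonstrate statistical correctness of
the machinery under the planted model, not robustness to those real
data features.

## Numerical choices and simulation sizes

* Fisher tail sums in log space; BH via statsmodels; *t*-tests via
  scipy, NaN→(0, 1) only for zero-variance degeneracy.
* Cox Newton: step clipped to |Δβ| ≤ 2 with step-halving on likelihood
  decrease, convergence at |Δβ| < 10⁻¹⁰, 50 iterations max.
* Median ties to "low"; K-means label permutation resolved by the
  ether-mean rule; all seeds explicit.
* Test-suite simulation sizes: 100 replicates for null calibration, Cox
  recovery and end-to-end planted-structure recovery at the full
  default cohort size (n = 100, 800 species, 1000 genes);
  `scripts/acceptance.py` uses 20/50/10 replicates for the same three
  studies, sized for a few minutes on one CPU.

## Known limitations

* The per-grid-cell Spearman *p* is approximate for moderate n with
  heavy ties (exact only for n ≤ 9).
* t-SNE determinism holds for a fixed seed and library version, not
  across library versions; sample-order permutation can change
  coordinates at floating-point level (cluster assignments are stable).
* The Cox solver is single-covariate by design; no multivariable
  models, PH diagnostics, or competing risks.
* Gene-set enrichment runs only against user-supplied GMT files; no
  live pathway-database queries.
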