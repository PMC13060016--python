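# Methods

This note documents the statistical model behind `dimorphprot`, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Experimental structure assumed

Two sperm morphs (apyrene **A**, eupyrene **E**), each sampled as
independent, unpaired biological replicates; each biological replicate
measured in several technical MS injections. Technical replicates carry no
biological information, so the first step averages them — over *detected*
injections only, because an injection that missed a protein is a technical
dropout, not evidence of absence — and all inference afterwards is at the
biological-replicate level. Pairwise technical correlations (Pearson, on
log2 values over jointly detected proteins; pairs sharing fewer than 10
proteins are reported as undefined) justify the collapse; at the default
generator noise they sit above 0.99, matching the regime in which averaging
is appropriate. Whether such correlations are better computed on raw or log
abundances is a judgment call; they are computed on log2 here and the scale
is recorded in the QC report.

Outlier replicates (detection count below `count_frac = 0.6` of the median
count, or median log2 abundance more than `abundance_z = 3` robust SDs —
1.4826 × MAD — from the median of sample medians) are *flagged, never
auto-dropped*: exclusion of a replicate is an analysis decision that must be
recorded in the configuration (`exclude_samples`), mirroring how such
exclusions are justified by inspection in practice.

## Missingness model

LFQ missingness mixes two mechanisms, and the package treats the
distinction operationally, via per-morph observation counts over biological
replicates:

| rule | condition |
|---|---|
| filtered out | > `max_missing` (2) missing in **both** morphs |
| COMPLETE | no missing values |
| MAR | ≥ 2 observations in both morphs |
| MNAR | ≤ 1 observation in one morph and ≥ 3 in the other |
| UNCLASSIFIED | anything else (impossible in 5-vs-6 designs; falls back to MAR) |

For the 5-apyrene/6-eupyrene design these rules provably cover every
retained incomplete protein (the test suite enumerates all (obs_A, obs_E)
pairs). The UNCLASSIFIED→MAR fallback exists only for other designs; MAR's
conditional-mean imputation is the less aggressive assumption.

Imputation operates on log2 abundances, after filtering and classification:

* **MinDet** (MNAR): every missing cell of a target protein in sample *s*
  is replaced by the `mindet_quantile` (default 0.01) quantile of sample
  *s*'s observed log2 values. Deterministic; the fill sits at the left tail,
  where censored values must lie. The quantile is computed over the whole
  retained matrix, not only the targets.
* **MLE** (MAR): samples are the variables of a joint Gaussian, proteins
  its i.i.d. cases. EM iterates conditional-expectation E-steps (with the
  conditional-covariance correction in the sufficient statistics) and
  closed-form M-steps until no parameter moves by more than `em_tol = 1e-4`
  or `em_max_iter = 100` is hit (warning; last iterate kept). The fit uses
  the fully observed proteins together with the MAR targets; initialisation
  is the complete-case mean/covariance (falling back to a diagonal moment
  start in degenerate fixtures); numerically singular covariances get a
  `1e-6` ridge on the diagonal. The observed-data log-likelihood is tracked
  per iteration and is non-decreasing (a standard EM self-check exercised in
  the tests). E-steps are grouped by missingness pattern, which keeps a
  1,700 × 12 matrix at a few milliseconds per iteration.

Both imputers never alter an observed value, and the MinDet/MLE target sets
are disjoint by construction.

## Differential abundance

The quantitative test is the empirical-Bayes moderated t described in the
README: pooled per-protein residual variance shrunk toward a prior
(*d₀*, *s₀²*) fitted by the method of moments on log *s²*, using the
digamma/trigamma moment equations of the scaled-F marginal; the trigamma
inverse is solved by Newton iteration. Non-positive excess spread of the
log-variances yields *d₀ = ∞* (complete pooling). Calls require
BH-adjusted p < `alpha = 0.05` **and** |log2fc| ≥ log2 `fc_min = 1.5`,
with the fold rule applied to the model coefficient (the log-scale mean
difference) rather than a ratio of raw-scale means, for consistency with
the linear model. The contrast sign convention is apyrene − eupyrene.

Qualitative presence/absence calls run on the *non-imputed* filtered
matrix — their point is to catch proteins whose signal conservative
imputation would erase: detected in ≥ `min_present = 4` replicates of one
morph and ≤ `max_other = 1` of the other. The 4/1 defaults are the
appropriate fixed thresholds for 5–6 replicate designs; `min_present="auto"`
scales as ceil(0.75·n) per morph for other designs. A protein quantitatively
biased one way and qualitatively exclusive the other way is a contradiction
and aborts the merge; otherwise the bias category is the union of the two
call sets.

PCA of samples uses all retained proteins by default (protein-mean
centring, full SVD); `top_n` optionally restricts to the most variable
proteins first.

## Enrichment and homology

Annotation-rate differences across the three bias subsets use Pearson's
chi-square of homogeneity on the 3 × 2 table, no continuity correction,
df = 2, with a warning when any expected cell drops below 5. GO enrichment
is a per-term hypergeometric upper tail against the all-detected-proteins
universe, run separately per namespace and per subset (nine combinations);
the *conditional* variant processes terms children-before-parents and, when
a term's p < `p_cutoff = 0.05`, removes its universe genes from all
ancestors before they are tested. Terms with fewer than `min_size = 3`
universe genes are skipped. Enrichment p-values are reported raw (an
optional BH switch exists, default off), `part_of` edges are treated like
`is_a` for propagation (restrictable by flag), and annotations are
propagated by the true-path rule before testing. Proteins map to genes via
the longest isoform.

Cross-species sharing counts a focal gene as shared when any ortholog group
contains it together with a comparison-species gene *that is itself in that
species' sperm-protein set*; many-to-many groups qualify through any
co-member. One-to-one orthology is deliberately not required — the ortholog
table's groups are taken as given.

## The synthetic generator

The generator emulates: a 2 × 6 biological design with triplicate technical
injections (duplicate for the last replicate of each morph, i.e. 34 runs);
~1,700 proteins with baselines N(20, 3²) on log2; biological noise
σ_bio = 0.5 and technical noise σ_tech = 0.05 (giving technical correlations
> 0.99); 15% morph-biased proteins with |log2fc| ~ N(2, 0.5²), 55% of them
eupyrene-biased (echoing the typical eupyrene excess without asserting it);
left-censoring of each run's lowest 5% of values (MNAR); 2% uniform dropout
(MAR); and optionally one degraded apyrene replicate (+2 log2 shift, 50%
extra dropout). Censor and dropout masks are disjoint per cell and recorded
as ground truth. The outlier replicate is off by default — it models an
unexplained artifact, not a design feature — and is switched on where QC
flagging is exercised.

What it does **not** emulate: peptide-to-protein roll-up, shared peptides,
match-between-runs artifacts, intensity-dependent variance beyond
left-censoring, batch/run-order drift, and cross-protein correlation
(proteins are independent given the design). Passing tests therefore show
the pipeline's statistical behaviour under a clean LFQ-like missingness
model, not robustness to every real acquisition artifact.

## Known limitations

* MinDet is intentionally conservative: because the observed distribution
  is itself truncated at the detection limit, imputed values sit just below
  that limit, and strongly censored effects are attenuated toward zero.
  This is visible in the benchmark — effect-size recovery is unbiased to
  < 0.01 log2 units on complete proteins, while MNAR-imputed proteins are
  attenuated — and is exactly why the qualitative presence/absence route
  exists: merged bias categories recover > 95% of planted effects.
* The MLE imputer's Gaussian is morph-blind (one joint distribution over
  all samples); between-morph effects are preserved only through the
  inter-sample covariance it learns.
* GO enrichment p-values are raw per-term tail probabilities; with many
  terms, significance counts should be read as descriptive.
* Run-to-run normalisation is assumed done upstream (the input is expected
  to be normalised precursor-ion abundances); an optional median-centring
  switch is out of scope here.

## Problem sizes used by the acceptance script

The null false-discovery experiment uses 200 bundles at the full default
size (1,700 proteins, 6 + 6 replicates) — large enough that the Monte-Carlo
standard error of the mean FDP is ~0.01 — and the fold-floor check uses one
default bundle with planted effects. Both together take about a minute on a
single CPU.
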