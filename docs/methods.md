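# Methods

## Overview

`subpathsig` implements a multi-cohort discovery-and-validation procedure for
prognostic *functional* signatures: gene sets (subpathways and pathways)
whose per-sample activity predicts patient survival consistently across
independent expression cohorts. The pipeline has five stages:

1. **Subpathway mining** — decompose pathway graphs into subpathways by the
   distance-similarity rule.
2. **Activity scoring** — convert each sample's transcriptome into per-set
   activity scores by rank-based exponential weighting.
3. **Integrated discovery** — screen every feature by univariate Cox in each
   training cohort, aggregate into an integrated prognostic score (ipScore)
   over all training-cohort combinations, and select candidates by their
   frequency in the combinations' top-30 lists.
4. **Meta-analytic validation** — pool the per-cohort hazard ratios of a
   candidate with inverse-variance weighting, quantify heterogeneity, and run
   subgroup and leave-one-out sensitivity analyses.
5. **Pharmacological association** — correlate activity with drug IC50 in a
   molecular-subtype subset of cell lines (subset-permutation significance)
   and compare activity across ordinal chemotherapy-response groups.

Because the original patient cohorts and cell-line panels are external
resources, the package ships a synthetic-data generator that reproduces the
statistical structure the analysis assumes, with a planted protective
subpathway as ground truth. Every stage is exercised and verified on that
synthetic study.

## Subpathway mining

A pathway is an undirected graph with genes as nodes. A subpathway is a
*maximal* set of genes in which every pair lies within shortest-path distance
`k` (default `k = 3`); this is computed exactly as the maximal cliques of the
graph's k-th power (`networkx.find_cliques`). Nodes in different connected
components are at infinite distance and never share a subpathway; isolated
nodes form singletons. Output order is deterministic (descending size, then
lexicographically smallest member), and subpathway ids are
`<pathway>_<rank>`. On graphs of up to ~12 nodes the implementation is
verified against brute-force enumeration of all distance-bounded subsets.

## Activity scoring

For one sample with `|N|` genes, genes are ranked in descending expression
(rank 1 = highest; ties share the average rank) and weighted

    w(r) = r · exp(sign · r / |N|),     sign = +1 by default.

The raw activity of a gene set S is the in-set/out-of-set contrast

    sPA(S) = mean_{g∈S} w_g − mean_{g∉S} w_g,

and each feature row is z-normalised across samples using the population
(divide-by-n) standard deviation. Gene-level "activity" is the expression
value itself, normalised the same way. Scoring is purely rank-based, so any
strictly monotone per-sample transform of expression (log, quantile,
exponentiation) leaves the activity matrix unchanged.

Two conventions deserve attention:

- **Exponent sign.** The weight formula is implemented as printed, with
  `sign = +1`; a `sign = -1` switch selects the "decreasing" variant
  `r·exp(−r/|N|)`. Note that *both* variants are increasing in the rank
  number over `r ∈ [1, |N|]` (the decreasing variant peaks at `r = |N|`), so
  under either convention the highest-expressed genes carry the smallest
  weights and a set whose genes rise in expression *falls* in sPA. The sign
  of downstream hazard-ratio estimates simply flips with this orientation;
  all survival, pooling and correlation machinery is direction-agnostic.
- **Ties and degeneracy.** Average ranks on ties (deterministic); constant
  activity rows cannot be z-scored and are returned as zeros with a QC flag;
  feature genes absent from the expression matrix are dropped and counted in
  the QC table; missing expression values are rejected (a full ranking is
  required).

## Survival models

- **Univariate Cox** is a hand-written Newton maximisation of the partial
  likelihood with Breslow tie handling, tolerance 1e-8, at most 100
  iterations with step clipping at ±5. It is cross-checked against
  `lifelines` (identical to 1e-6 on tie-free data) and exists because the
  screening stage calls it once per feature × cohort. Wald two-sided
  p-values and 95% CIs (`exp(β ± 1.96·SE)`) are reported. Degenerate inputs
  — fewer than two events, constant covariate, non-convergence — return a
  flagged result with p = 1 instead of raising, so a single bad feature
  cannot abort a screen.
- **Multivariate Cox** delegates to `lifelines.CoxPHFitter`; categorical
  covariates are expanded to indicators against the first sorted level.
- **Two-group stratification** uses 1-d K-means (K = 2) with deterministic
  initialisation at the 25th/75th percentiles; the cluster with greater mean
  activity is labelled `high`. Multi-feature signatures cluster samples with
  K = 2 Euclidean K-means on standardised feature rows, initialised at the
  extreme samples of the mean-activity projection; a single-feature set
  falls back to the univariate split so the two entry points agree.
- **Log-rank test** (two groups, 1 df) comes from `lifelines.statistics`.

## Integrated discovery

With 7 training cohorts, all subsets of sizes {5, 6, 7} give 21 + 7 + 1 = 29
combinations. For each feature and combination,

    ipScore = mean over cohorts of −log10(Cox p),

with p clipped below at 1e-300. Each combination's features are ranked by
descending ipScore (ties broken lexicographically by feature id) and the top
30 kept, separately per level (gene / subpathway / pathway). A feature's
frequency is its membership count over all 29 top-30 lists; candidates
satisfy frequency ≥ 20. The tally counts membership over *all* lists (an
`exclude_self` flag provides the leave-own-combination variant). Serial
cumulative sets — the 28 prefixes of sizes 3…30 of a ranked list — are
assessed on held-out cohorts by the K = 2 split plus log-rank. Candidate
relevance against a reference gene catalogue uses the upper-tail
hypergeometric test.

## Meta-analysis

Per-cohort log hazard ratios of a signature's continuous normalised activity
are pooled on the log scale with inverse-variance weights. Cochran's Q is
computed about the fixed-effect estimate, `I² = max(0, (Q − df)/Q)·100`, and
between-study variance τ² by the DerSimonian–Laird moment estimator floored
at zero. Model choice follows the I² rule: fixed-effect below 50%,
DL random-effects otherwise. Subgroup pooling (by platform tag), leave-one-out
sensitivity (≥ 3 studies), and funnel-plot data (per-study effects plus
pseudo-95% bounds over an SE grid) are exported as tables; funnel symmetry
is left to visual inspection, no Egger/Begg test is computed. The pooling
arithmetic is verified against `statsmodels.stats.meta_analysis`.

## Drug response

Activity is correlated with log10 IC50 by Spearman rank correlation within
cell lines of the "classical" subtype. Significance comes from a subtype
permutation test: B = 10,000 random subsets of the same size are drawn
without replacement from the whole panel, and `p = N/B` where N counts null
correlations *strictly below* the observed one. This left tail is only
meaningful for a negative observed correlation (higher activity, greater
sensitivity); a two-sided summary `P(|ρ_null| ≥ |ρ_obs|)` accompanies it.
Null subsets may coincide with the true classical subset; they are retained.
Subsets as small as 2 are accepted so that the test can be validated against
exhaustive enumeration on tiny panels. Response groups (default CR/PR/SD vs
PD) are compared by a two-sided Wilcoxon rank-sum test — exact when both
groups have ≤ 10 untied observations, tie-corrected normal approximation
otherwise.

## Synthetic study design

The generator draws, per cohort, log2-scale expression
`x_gs = μ_g + δ_c + ε_gs` with gene means `μ_g ~ N(7, 1)` shared across
cohorts, a cohort mean shift `δ_c ~ N(0, 0.2)` (inter-study heterogeneity),
and noise `ε ~ N(0, noise_sd²)`, `noise_sd = 1`. The planted subpathway's
genes additionally receive a per-sample latent factor `z_s ~ N(0,1)` with
unit loading, so the set's rank-contrast activity tracks the factor.

Survival follows an exponential proportional-hazards model:
`λ_i = λ₀ · exp(β · a_i)` with baseline hazard λ₀ = 0.1 per time unit,
`a_i` the planted set's *normalised* activity, and β = `planted_log_hr`
(default −0.5 per SD, i.e. protective). Censoring is an independent
exponential whose rate is solved numerically so the expected censored
fraction equals `censor_rate` (default 0.3). Subtype labels are i.i.d.
classical with probability `classical_fraction` (0.45); age and sex are
neutral covariates for multivariate fits.

Default design: 11 cohorts (7 training, 4 test) of 500 patients — the
training/validation geometry of a multi-cohort discovery study at desk
scale. The last two cohorts are RNA-seq-flavoured: expression is
exponentiated and rounded to counts and the platform tag recorded, which
exercises the platform-subgroup meta-analysis; rank-based scoring is
insensitive to the transform apart from rounding ties. The gene universe is
2,000 genes: large enough that the planted set (10 genes) perturbs the
global ranking negligibly — with a much smaller universe, every decoy set's
activity becomes spuriously coupled to the planted factor through the shared
ranks. Each of 99 decoy pathways contributes a null clique subpathway
(size 7–13) and a 4-gene chain subpathway, giving 200 subpathway features so
that a top-30 list is genuinely selective. The pathway graphs mirror these
definitions (clique component plus disconnected chain component), so mining
them at k = 3 reproduces the feature sets exactly.

Cell-line IC50 values use a Gaussian copula: within classical lines the
log-IC50 latent variable correlates with the normal scores of activity at
`r = 2·sin(π·ρ_s/6)`, targeting Spearman `ρ_s = ic50_rho` (default −0.5);
non-classical lines get independent log-normal IC50. Response labels for the
last cohort threshold `activity + N(0, 0.8²)` at the 30/65/85% quantiles
into PD/SD/PR/CR.

What the generator does **not** emulate: probe-level microarray artefacts,
batch effects, library-size variation, correlated gene-gene structure beyond
the single planted factor, non-proportional hazards, and informative
censoring. Passing tests therefore demonstrate that the pipeline's
statistics behave as designed under its own assumptions, not that those
assumptions hold in any particular real data set.

## Numerical choices and problem sizes

- Cox Newton tolerance 1e-8; p-values floored at 1e-300 inside ipScore.
- Population SD in activity normalisation; average ranks on ties throughout.
- K-means initialisations are deterministic (percentile / extreme-sample),
  so reruns are byte-identical; no stochastic clustering is used anywhere.
- All randomness flows from a single `numpy` Generator seeded by the
  configuration; identical config + seed gives bit-identical studies.
- Verification runs use the default study (11 × 500 patients, 2,000 genes,
  300 features) for end-to-end checks and smaller replicate designs
  (1–3 cohorts, 120–500 patients) for repeated-seed power and calibration
  checks; these sizes give stable Monte-Carlo behaviour at interactive cost.

## Known limitations

- The frequency tally admits ties at the maximum count; the planted set is
  required to attain (possibly share) the top count, which is what a
  selection-by-threshold procedure can guarantee.
- The permutation test's null is contaminated by the signal whenever the
  classical subset is a large fraction of the panel (null subsets then
  contain many classical lines); power at `ρ_s = −0.5` is adequate from
  ~30 classical lines in a panel about three times larger.
- The exclude-self frequency variant and the group-based (high/low) cohort
  estimate for meta-analysis are provided as options but are not the
  defaults.
- Subpathway mining follows the literal pairwise-distance rule; other
  published miners may count intervening non-gene nodes differently.
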