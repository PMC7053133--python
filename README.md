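# subpathsig

Discovery and validation of prognostic **subpathway signatures** from
multi-cohort gene-expression survival data.

Clinical expression cohorts rarely agree on which individual genes predict
outcome, but the *functional modules* those genes belong to replicate far
better. `subpathsig` implements an integrated pipeline for finding such
modules and validating them, aimed at computational biologists working with
several independent cohorts (e.g. pancreatic ductal adenocarcinoma series)
plus cell-line pharmacology panels:

1. **Subpathway mining** — pathway graphs (genes as nodes) are decomposed
   into subpathways: maximal gene sets whose members all lie within
   shortest-path distance *k* of each other (default *k* = 3), computed as
   maximal cliques of the graph's k-th power.
2. **Single-sample activity scoring** — each sample's genes are ranked by
   descending expression and weighted `w = r·exp(r/|N|)`; a set's activity is
   the mean in-set weight minus the mean out-of-set weight
   (`sPA`), z-normalised per feature across samples (`sPA_norm`).
3. **Integrated discovery** — every feature is screened by univariate Cox in
   each training cohort; for each of the 29 combinations of 5/6/7 of the 7
   training cohorts, `ipScore = mean(−log10 p)`; candidates are features in
   the top 30 of ≥ 20 combinations. Serial cumulative sets (sizes 3–30) are
   assessed on held-out cohorts by a K = 2 split plus log-rank test.
4. **Meta-analysis** — per-cohort hazard ratios are pooled on the log scale
   with inverse-variance weights; Cochran's Q and I² quantify heterogeneity,
   with fixed-effect pooling below I² = 50% and DerSimonian–Laird
   random-effects above, plus subgroup, leave-one-out and funnel-data
   exports.
5. **Drug response** — Spearman correlation of activity with log IC50 in
   classical-subtype cell lines, tested by a 10,000-draw subset-permutation
   (`p = N/B`), and Wilcoxon rank-sum comparison of activity across
   CR/PR/SD/PD chemotherapy-response groups.

Because the real cohorts are external resources, the package includes a
first-class synthetic-data generator (`subpathsig.simulate`) that emulates
the full study design — multiple cohorts, a planted protective subpathway
(hazard ratio < 1 per SD of activity), platform tags, IC50 tables, response
labels — so every stage is testable end to end. See `docs/methods.md` for
the model and its assumptions.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic design (7 training + 4 test cohorts × 500 patients, 2,000 genes,
a 10-gene planted subpathway at log HR −0.5; pass a seed as the argument):

```bash
python analysis/01_simulate_cohorts.py 1   # generate + summarise the study
python analysis/04_discover_signature.py 1 # ipScores, top-30, frequency
python analysis/05_meta_analysis.py 1      # pooled HR, I2, sensitivity
python analysis/06_drug_response.py 1      # IC50 correlation + permutation
```

Discovery (seed 1) prints:

```
29 training-set combinations, 200 subpathway features screened
planted set path:90001_1: frequency 29/29, selected = True, top of tally = True
```

— the planted subpathway appears in the top-30 of all 29 combinations and
tops the frequency tally, exactly what the selection rule should do when one
module truly carries prognostic signal. Meta-analysis prints:

```
pooled HR 0.611 [0.590, 0.632] (fixed effects, I2 = 0.0%, Q = 3.55)
```

i.e. the pooled hazard ratio per SD of activity recovers the planted
protective effect (exp(−0.5) ≈ 0.607) with no excess heterogeneity, so the
I² < 50% rule selects the fixed-effect model. Drug response prints:

```
31 classical cell lines of 60; target Spearman rho = -0.5
          rho  p_permutation  n_below      b
drug1 -0.6403         0.0006        6  10000
drug2 -0.5052         0.0468      468  10000
```

— the activity–IC50 correlation inside the classical subtype is stronger
than in 10,000 random same-size subsets for drugs 1 and 2 (p = N/10000).

The same stages are available as subcommands of the `subpathsig` CLI
(`simulate`, `mine`, `score`, `discover`, `meta`, `drugs`) for use on your
own TSV/GMT/edge-list inputs; `subpathsig --help` lists them.

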