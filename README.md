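# heightmeta

Multilevel meta-analysis of assortative mating for human height: do
spouses resemble each other in stature, how strongly, and is the
pattern confined to western populations?

The package re-implements, as a tested and reusable pipeline, the
statistics behind a published synthesis of 154 husband–wife height
correlations from 43 countries: Fisher-z effect sizes with known
sampling variances, sample-size recovery for incompletely reported
studies, a crossed-random-effects REML meta-regression, multilevel
heterogeneity statistics, and a rank-correlation publication-bias
test — plus a generative simulator so every stage is verifiable
without access to the historical study table.

## The model

Each study i reports a Pearson correlation r_i between spousal heights
on N_i couples. On the Fisher scale z = artanh(r), with sampling
variance 1/(N−3), the model is a meta-regression with crossed random
intercepts for author group (research teams publish repeatedly) and
country (studies cluster geographically):

    z_i = β0 + β_w·western_i + β_y·(year_i − ȳ) + u_author(i) + w_country(i) + e_i
    u ~ N(0, σ²_author),  w ~ N(0, σ²_country),  e_i ~ N(0, 1/(N_i−3))

Variance components are estimated by restricted maximum likelihood
(validated against `metafor::rma.mv` to ~1e−6), fixed effects by GLS
at the optimum with Wald-normal inference, and summaries are
back-transformed to the correlation scale. Heterogeneity is
quantified by residual Cochran Q and the multilevel I² =
Σσ²/(Σσ² + ṽ) with the Higgins–Thompson typical sampling variance ṽ;
funnel asymmetry by the Begg–Mazumdar rank correlation. The
western/non-western moderator follows the UN M49 geoscheme: Europe
(150), Northern America (021) and Australia/New Zealand (053) are
western; Japan is non-western by convention.

## Worked example

Simulate a study collection at the design of the published synthesis
(154 studies, 91 author groups, 43 countries, true pooled effect
artanh(0.23)) and run the full analysis:

```sh
$ heightmeta simulate --seed 42 -o demo.csv --truth-out truth.json
wrote demo.csv (154 studies, seed 42)
$ heightmeta report demo.csv -o demo_report --no-figures
      model   k  pooled_r  ci_low  ci_high       Q  df  I2_pct
all_studies 154    0.2542  0.1998   0.3071 2455.45 153    93.9
 full_model 154    0.2241  0.1481   0.2975 2309.54 151    93.8
    western  83    0.2869  0.2022   0.3674 1237.24  82    94.7
 nonwestern  71    0.2235  0.1551   0.2897 1072.53  70    92.5
report written to demo_report/
```

Reading the output: the no-moderator model pools all 154 correlations
to r = 0.25 (95% CI 0.20–0.31) — within sampling error of the
generative truth 0.23. The full model adds the western indicator and
centered publication year, leaving 151 residual degrees of freedom;
Q ≫ df and I² ≈ 94% say that almost all the spread in effect sizes
beyond sampling noise comes from real between-study heterogeneity,
here injected through the author and country variance components.
The western and non-western subgroup rows are separate intercept-only
fits of the two study subsets. `demo_report/report.json` additionally
carries the coefficient table (the western contrast and year slope
with Wald tests), the interaction check, variance components,
likelihood-profile convergence diagnostics, the Begg rank test, and
provenance hashes; `--figures` adds a forest-style SVG grouped by
region and a funnel plot.

The same steps are available as composable verbs — `validate`,
`transform`, `fit`, `heterogeneity`, `bias`, `simulate`, `recover`,
`report`, `all` — and as library functions (`read_studies`,
`compute_effects`, `fit_model`, `heterogeneity_report`,
`begg_rank_test`, `simulate_studies`, `recovery_experiment`,
`run_full_analysis`).

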