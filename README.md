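# adrenosig

Urine-metabolomics signatures of corticosteroid-induced adrenal suppression:
an imbalance-aware association and discrimination pipeline.

Children taking inhaled corticosteroids for asthma can develop tertiary
adrenal suppression (peak plasma cortisol ≤ 350 nmol/L after an ACTH
stimulation test). In a typical pharmaco-metabolomics cohort the outcome is
heavily imbalanced — on the order of 188 adrenal-sufficient vs 12
adrenal-insufficient children with hundreds of urinary metabolites measured —
which makes naive per-metabolite testing fragile. `adrenosig` implements the
full analysis chain for this setting, end to end, with a synthetic cohort
generator so every stage is testable without any patient data:

1. **QC / normalization** — keep metabolites observed in > 70% of samples,
   drop xenobiotics and partially characterized compounds, half-minimum
   imputation, osmolality + per-metabolite median normalization, natural-log
   transform, Pareto scaling.
2. **SMOTE oversampling** (from scratch) — each minority sample spawns
   `replications` synthetic samples `x + u·(x_nb − x)`, `u ~ U(0,1)`, with
   `x_nb` among its `k` nearest minority neighbors (defaults k = 3,
   replications = 3, so 12 minority cases become 48).
3. **Repeated logistic association** — per metabolite *i*,
   `P(y = insufficient) = 1 / (1 + exp(−β₀ − β₁ mᵢ − β₂ g))` with sex
   `g ∈ {0 = female, 1 = male}`, refitted on 1000 independent SMOTE
   resamples; p-values, slopes and CI bounds aggregated by their medians;
   Benjamini–Hochberg FDR across metabolites; fold change = ratio of group
   medians on the untransformed imputed matrix.
4. **OPLS-DA** (from scratch) — one predictive component after removal of
   `n_ortho` y-orthogonal components; VIP scores (Σ VIP² = p), stratified
   7-fold Q2Y = 1 − PRESS/TSS, 1000-iteration label-permutation test, and
   median VIP over SMOTE resamples with a VIP > 1.5 selection rule.
5. **Enrichment** — hypergeometric over-representation over pathway sets
   with relative-betweenness topology impact, and chemical-similarity
   cluster enrichment (Tanimoto ≥ 0.7 connected components, one-sided
   Kolmogorov–Smirnov test of member p-values against U(0,1), up/down
   member counts).
6. **Correlation network** — Pearson |r| ≥ 0.8 on log abundances of the
   significant metabolites (at n = 200 that threshold corresponds to
   p < 2.22 × 10⁻¹⁶), connected components, degree-ranked hubs, GraphML
   export.
7. **Cross-cohort validation** — per-metabolite OLS of continuous cortisol
   outcomes on shared metabolites, adjusted for sex and age.
8. **Simulation study** — type-I error, power and empirical FDR of plain
   logistic regression vs SMOTE-repeated logistic regression vs a
   saddlepoint-approximation (SPA) score test (Lugannani–Rice with a
   second-order correction, from scratch) under severe outcome imbalance.

A word of caution that the simulation module makes quantitative: treating
SMOTE-interpolated minority samples as independent observations shrinks the
slope standard error by roughly √((1/12 + 1/188)/(1/48 + 1/188)) ≈ 1.8× and
is therefore strongly anti-conservative — under a pure global null about 28%
of null metabolites reach median p < 0.05, while plain logistic regression
and the SPA score test stay at the nominal 5%.

## Worked example

The whole pipeline runs from one config on a generated cohort (200 samples,
6% minority, 200 metabolites, a 15-metabolite correlated "steroid" block
planted to decrease in the minority group and 5 metabolites to increase,
log-scale effect 1.5 SD):

```python
from adrenosig.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    synth=dict(n_samples=200, n_metabolites=200, minority_fraction=0.06,
               n_effect_down=15, n_effect_up=5, effect_size=1.5,
               block_specs=[(15, 0.85)], missing_rate=0.0),
    n_resamples=200, n_perm=100, seed=7, outdir="demo_run",
)
run_pipeline(cfg)
```

or equivalently `adrenosig run --seed 7 --out demo_run` with the same
config file. On this seed the run prints/writes:

```
significant metabolites (q<0.05): 67 of 200
top rows of association.tsv:
               or_point  or_ci_low  or_ci_high  q_fdr  fold_change direction
M0016            5.4639     3.4126      8.7549    0.0       8.7144        up
M0015            9.2414     4.8582     17.5538    0.0       7.4928        up
M0001            0.1184     0.0639      0.2201    0.0       0.2375      down
oplsda_summary.json: {'r2y': 0.856, 'q2y': 0.774, 'p_perm': 0.0099}
VIP>1.5 count: 24 | top VIP: 3.59
network: 67 nodes, 105 edges, 53 components; top hub degree 14
chemical enrichment: steroid block, 15 members, 0 up / 15 down, q = 2.3e-118
validation overlap: 33 shared ids, 3 validated at p < 0.05
```

Reading it: the planted steroid-block metabolites come out with odds ratios
far below 1 and fold changes ≈ 0.24 (decreased in the insufficient group),
the planted increases with OR ≫ 1; the OPLS-DA separates the oversampled
classes (Q2Y 0.77, permutation p ≈ 0.01); the block forms the densest
network component and the dominant chemical cluster with all members
decreased — the qualitative picture expected for suppressed adrenal steroid
output. Note the 67 "significant" metabolites against 20 planted effects:
the surplus is the anti-conservatism of SMOTE-based inference noted above,
visible even in a clean synthetic cohort.

The imbalance simulation is available as
`adrenosig simulate --seed 1 --out sim_out` or
`adrenosig.simstudy.run_simulation(SimDesign(...))`.

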