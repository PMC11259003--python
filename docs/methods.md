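# Methods

This note documents the statistical procedures implemented in `adrenosig`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behaviour on real data.

## Outcome and preprocessing

The outcome is adrenal status dichotomized from peak plasma cortisol after
ACTH stimulation: insufficient iff cortisol ≤ 350 nmol/L (the tie goes to
insufficient). Preprocessing applies, in order: a missingness filter keeping
metabolites observed in **strictly more than** `min_present` (default 0.70)
of samples ("over 70%" is read as a strict inequality; configurable);
removal of flagged xenobiotics and partially characterized compounds (a
metabolite carrying both flags is counted once, under xenobiotic);
half-minimum imputation (each missing entry ← min observed value of that
metabolite / 2); normalization by sample osmolality followed by
per-metabolite median scaling (so every metabolite has cohort median 1;
osmolality-first order); natural-log transform (the log base is not
material — all downstream tests are monotone-invariant, Pareto scaling
absorbs the constant); and Pareto scaling, x → (x − mean)/√SD with the
sample SD (ddof = 1), so the scaled column variance equals the SD of the
centered log column. Zero-variance columns cannot be Pareto scaled and are
dropped with a warning rather than aborting a run. IQR is computed with
type-7 (linear-interpolation) quantiles. A state log on the cohort container
enforces the legal order filter → impute → normalize → log → scale and
rejects re-application, so downstream stages can assert the processing state
they require. The imputed, untransformed matrix is retained alongside the
scaled one because fold changes (ratio of minority to majority group
medians) must be computed on positive, untransformed values.

## SMOTE and the repeated association model

SMOTE is implemented classically: for each minority sample, `replications`
synthetic samples are drawn as x + u·(x_nb − x) with u ~ U(0,1) and x_nb
uniform over the k nearest minority neighbours (Euclidean distance on the
full processed metabolite matrix; ties broken by lower sample index;
neighbour search within the minority class only). Binary covariates (sex)
are copied from the seed instance, never interpolated, so the logistic
model's gender term stays in {0,1}. Joint (whole-row) interpolation was
chosen over per-metabolite univariate oversampling to preserve within-sample
coherence. Each of the `n_resamples` datasets is seeded from
(master seed, resample index) via `numpy` SeedSequence, so streams are
reproducible and order-independent.

Per metabolite the logistic model P(y) = 1/(1 + exp(−β₀ − β₁m − β₂g)) is
fitted by Newton/IRLS, vectorized across metabolites (stacked 3×3 solves),
which is what makes 1000 resamples × hundreds of metabolites run in seconds.
Age is not in the discovery model (it is in the validation model). Fits that
fail to converge or show quasi-separation (|β| > 30 on scaled covariates)
are refitted with a small L2 ridge on the slopes (λ = 1e−4, intercept
unpenalized) and flagged — with ~12 cases separation is a live possibility.
p-values (Wald, two-sided), slopes, and 95% CI bounds are aggregated across
resamples by their medians over converged fits; exp(median β₁) equals the
median OR by monotonicity, and the aggregated CI is reported as such (the
aggregation rule is only prescribed for p-values; the CI median is a
labelled convention). BH-FDR runs across all metabolites with at least one
converged fit.

**Calibration warning (quantified by the simulation module).** Treating the
interpolated minority samples as real observations shrinks se(β₁) by about
√((1/12 + 1/188)/(1/48 + 1/188)) ≈ 1.8 and inflates null |z| by the same
factor. Measured on 18,000 null tests at 188/12 imbalance: 33% of null
metabolites reach median p < 0.05 (plain logistic: 4.7%; SPA score test:
4.8%). Median aggregation over resamples does not remove this inflation —
it is systematic, not resampling noise. Consequently the empirical FDR of
the SMOTE-repeated association at q < 0.05 is high (~0.8 in the planted-
effect recovery experiment) even though sensitivity for 1.5-SD effects is
near 1. The package reproduces the procedure faithfully and documents its
operating characteristics rather than altering them; the null-calibration
test of the surrounding machinery (median aggregation + BH) is run with
oversampling disabled, where it is well calibrated (null q < 0.05 fraction
≈ 0.001).

## OPLS-DA, VIP, Q2Y, permutation test

The model centers X and the ±1-coded class vector, then alternates: compute
the PLS weight w ∝ Xᵀu, extract the loading p of the score t = Xw, split
off the component of p orthogonal to w as an orthogonal weight w_o, and
deflate X by the orthogonal component t_o p_oᵀ; after `n_ortho` (default 1)
orthogonal components a single predictive component is fitted on the
deflated matrix. With n_ortho = 0 this is exactly one-component NIPALS PLS,
which the tests use as an oracle. The predictive weight is oriented so the
insufficient class has positive mean score. VIP_j =
√(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) over the predictive plus
orthogonal components with SSY_a the share of class variance explained by
score a; orthogonal components explain ≈ 0 of y, so this reduces in practice
to predictive-component VIP, and Σ_j VIP_j² = p holds exactly. Q2Y is
1 − PRESS/TSS over stratified k-fold CV (default 7 folds, seeded; requires
the minority class to have at least k members). The permutation test refits
Q2Y under label permutation, p = (1 + #{null ≥ observed})/(n_perm + 1).
Model-level validation in the pipeline (R2Y/Q2Y/permutation) is computed on
an oversampled dataset, matching how the discriminant models are fitted;
per-metabolite VIPs are medians over the SMOTE resample stream and the
VIP > 1.5 rule marks candidate predictors.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability of the
observed hit/pathway overlap given the analysis universe, BH-corrected
across pathways; with a pathway compound graph, the topology impact of a
pathway is the sum of betweenness centrality over hit members divided by the
sum over all members (a pathway whose members all have zero centrality gets
impact 1 if fully hit, else 0). Chemical-similarity enrichment clusters
metabolites by Tanimoto similarity of binary substructure fingerprints
(edges at similarity ≥ 0.7, connected components; labels canonicalized by
smallest member id so clustering is input-order invariant; fingerprints are
accepted as precomputed bitstrings — on-the-fly computation from SMILES is
deliberately out of the core path). Each cluster with ≥ 3 members is tested
by a one-sample, one-sided Kolmogorov–Smirnov test of its members' raw
association p-values against U(0,1) (alternative: stochastically smaller),
with exact small-sample KS tails; BH across clusters; members with raw
p < 0.05 are counted as increased/decreased by their fold-change direction
and the key compound is the member with the smallest raw p. A two-sample
variant (members vs non-members) would be a reasonable alternative reference
and can be added behind a flag; the one-sample form was chosen as the
simplest calibrated reading.

## Correlation network

Pearson correlations are computed on log-transformed (pre-Pareto)
abundances of the selected metabolites (default: the FDR-significant set);
edges keep signed r but the threshold applies to |r| (default 0.8 — at
n = 200 the t-transform p-value of r = 0.8 is ≈ 8×10⁻⁴⁶, far below
2.22×10⁻¹⁶). Components are connected components; hubs are degree-ranked
with lexicographic tie-break; zero-variance columns are excluded with a
warning. Exports are GraphML plus a plain weighted edge list for external
viewers.

**Imputation attenuates correlations.** Half-minimum imputation under
missing-completely-at-random dropout places imputed points ~3.4 SD below the
column mean; they inflate marginal variances without contributing
covariance. Measured on the generator: a ρ = 0.85 block drops to mean
pairwise r ≈ 0.7 at 2% dropout and ≈ 0.3 at 10%, emptying a 0.8-threshold
network. In real data missingness is largely left-censored (missing because
low), where half-minimum imputation approximates the truth and the
attenuation is mild — a caveat to keep in mind when choosing the network
threshold on heavily imputed data.

## Saddlepoint-approximation score test and the simulation study

For one metabolite, the score statistic against the null model (intercept +
sex) is S = Σ mᵢ(yᵢ − μ̂ᵢ) with μ̂ from the null logistic fit. Its exact
cumulant generating function under independent Bernoulli(μ̂ᵢ) outcomes,
K(t) = Σ log(1 − μ̂ᵢ + μ̂ᵢ e^{mᵢt}) − t Σ mᵢμ̂ᵢ, is solved for the
saddlepoint K′(ζ) = s by safeguarded (bracketed) Newton; the tail is the
Lugannani–Rice approximation with w = sign(ζ)√(2(ζs − K(ζ))),
v = ζ√K″(ζ), plus the second-order (K‴, K⁗) correction, which is dropped
when it is not a small perturbation of the first-order term; at or beyond
the boundary of the score's support the exact extreme-atom probability is
returned, and within a narrow band of the null mean (|s| < 1e−3 SD) the
normal approximation is used because the saddlepoint expansion is singular
at w = 0. Two-sided p doubles the observed tail (capped at 1). Against
exhaustive 2¹⁰ enumeration the tail is within ~6% where the discrete exact
tail is resolvable; at n = 20 (2²⁰ enumeration) it is within a few percent
essentially everywhere. Note that for a discrete score distribution no
smooth tail approximation can match a tail step whose adjacent atom carries
more than the tolerance — accuracy statements are therefore made at
resolvable evaluation points.

The simulation study draws independent-metabolite cohorts (defaults: n = 200
samples, 6% minority, 500 metabolites, 25 planted 1-SD decreases, 100
replicates; tests and the packaged runs use smaller replicate counts chosen
to keep a desk-scale run in minutes), applies plain logistic, SMOTE-repeated
logistic, and the SPA test to every metabolite, and reports type-I error at
α, power on planted effects, empirical FDR after BH at 0.05, and the mean
absolute deviation of β̂₁ on planted effects from a pseudo-true slope. The
pseudo-true slope is defined operationally — the plain-logistic estimate on
a single very large (n = 20,000) cohort drawn from the same generative
parameters — because the log-normal generator does not induce an exactly
logistic model, so no closed-form true β₁ exists. Measured operating
characteristics at 188/12-style imbalance: plain logistic 0.047 at α = 0.05
(conservative deep in the tail: 1.7×10⁻⁴ at α = 10⁻³), SPA 0.048 at
α = 0.05 and 3.9×10⁻⁴ at 10⁻³, SMOTE-logistic 0.33 at α = 0.05. The often-
cited weakness of the plain Wald test under imbalance is a deep-tail
phenomenon here; at the 5% level its size is close to nominal for these
symmetric covariates.

## Synthetic cohorts

The generator draws per-metabolite baselines μ_j ~ U(1, 3) and latent
Gaussians with unit log-SD; blocks are compound-symmetric (z = √ρ·shared +
√(1−ρ)·own), exponentiated to log-normal abundances. The minority count is
fixed (e.g. exactly 12 of 200), "down" effects are planted inside the first
block (the correlated steroid-like cluster) and "up" effects among unblocked
metabolites, as ∓/± `effect_size` shifts of the minority group's latent
values; a continuous cortisol value is drawn uniformly below the 350 nmol/L
cutoff for minority and above it for majority samples so dichotomization
reproduces the labels exactly; sex is Bernoulli (default 114/200 male) with
no abundance effect by default, so gender adjustment is testable under the
null; osmolality is U(0.5, 1.5); dropout is completely at random at
`missing_rate` (default 0.10). Block fingerprints share a bit template with
3% flips so chemical clustering can rediscover the block. The validation
generator produces a small cohort (default n = 10) with four continuous
cortisol outcomes linearly coupled to the planted-effect metabolites and a
controlled metabolite-id overlap with the discovery cohort.

What passing tests on these cohorts show: the estimators, resampling
machinery, rankings and set statistics behave as specified under a known
truth, at realistic size and imbalance. What they do not show: behaviour
under abundance-dependent (censored) missingness, batch effects, retention-
time artifacts, or non-log-normal abundance distributions — none of which
the generator emulates, deliberately.

## Numerical and structural choices

- Logistic IRLS: convergence at max |Newton step| < 1e−10, 50 iterations;
  linear systems solved in batch; pseudo-inverse fallback for singular
  Hessians; standard errors from the inverse observed information.
- OPLS-DA estimator is a scikit-learn `BaseEstimator` (get/set params,
  fitted attributes with trailing underscore, `fit`/`transform`/`predict`),
  and the SMOTE oversampler follows the `fit_resample` convention, so both
  compose with sklearn tooling; metadata-coupled pipeline stages
  (preprocessing, enrichment, network, validation) are plain functions over
  the cohort container, which is the natural shape for them.
- The command-line interface (`adrenosig synth|qc|smote|assoc|oplsda|
  enrich|network|simulate|run`) is a thin layer over the library; the full
  pipeline writes every intermediate artifact and a manifest with parameter
  echo and SHA-256 checksums, and reruns with the same config are
  byte-identical.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; resample/replicate streams use
  (seed, index) spawning so they are order-independent.

## Known limitations

- SMOTE-based inference is anti-conservative by construction (see above);
  the association table's q-values rank metabolites well but should not be
  read as calibrated FDR. The SPA test is the calibrated alternative offered
  by the simulation module.
- Batch-effect correction is out of scope (upstream of this pipeline).
- The pathway topology score requires a user-supplied pathway graph; the
  bundled annotation-derived pathway sets have no graph, so impact is
  reported as missing there.
- Exact logistic regression, Firth correction, and SMOTE variants
  (borderline-SMOTE, ADASYN, undersampling) are deliberately not included.
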