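# Methods

This note documents the statistical machinery behind `pairhazard`, the
assumptions each stage makes, the defaults and why they were chosen, and
what the synthetic-data experiments do and do not establish.

## Rank-pair scoring

The elementary statistic is the indicator that gene *a* is expressed
strictly above gene *b* within one patient.  Strictness matters: ties score
0, so a pair is "on" only when the ordering is unambiguous.  On continuous
expression data ties have measure zero; on heavily rounded data a
`tie_policy="drop-pair"` option removes any pair that ties in any sample
instead.  Because the score is a within-sample comparison, it is invariant
to every strictly increasing per-sample transform — the formal content of
the claim that the method needs no normalization.  The pipeline therefore
never rescales expression; the declared scale (FPKM/TPM/log) is carried as
metadata only.

Pairs are enumerated once per unordered combination, oriented by candidate-
list order.  The reversed orientation adds no information (off ties,
score(a,b) + score(b,a) = 1), so it is not enumerated.

**Candidate band.**  Pairs whose score-1 frequency falls outside
[0.2, 0.8] in either cohort are dropped: a pair that is almost always 0 or
almost always 1 cannot stratify patients.  The 20–80% band is the common
convention of the relative-ordering literature; both endpoints are
inclusive and configurable.

## Gene filtering

A candidate gene is retained when present in both cohorts and when its
unscaled median absolute deviation, `median(|x − median(x)|)`, reaches 0.5
in *each* cohort.  The MAD is deliberately left without the 1.4826
normal-consistency factor: the threshold is an empirical variability floor,
not a robust σ estimate, and a consistency factor can be folded into the
threshold by the caller.  Single-cohort filtering is the degenerate case of
passing the same matrix twice.

## Survival core

All survival statistics are implemented in the package and cross-checked in
the test suite against lifelines and scikit-survival.

* **Kaplan–Meier** — standard product-limit estimator; censored-only times
  shrink later risk sets without a survival drop.
* **Log-rank** — 1-df chi-square from observed-minus-expected events with
  the hypergeometric variance; zero-variance inputs (no events, one
  effective group) return chi-square 0, p 1 rather than NaN.
* **Cox regression** — Newton–Raphson maximization of the partial
  likelihood.  Efron tie handling is the default (the de-facto standard of
  the survival ecosystem); Breslow is available and agrees exactly on
  tie-free data.  Step-halving keeps the partial likelihood non-decreasing;
  convergence is declared when the largest Newton-step component falls
  below 1e−8, with a 50-iteration cap.  Monotone likelihoods (perfect
  separation, no events, constant or collinear covariates) are *flagged*
  (`converged=False` plus a note), never raised, because screening loops
  must survive degenerate covariates.  Confidence intervals are Wald
  (coef ± 1.96·SE, exponentiated).  The score statistic at β = 0 is
  recorded on every fit; for a single binary covariate on tie-free data it
  equals the log-rank chi-square, which the tests verify to 1e−6 — this is
  why the univariate screen can use Cox fits while remaining faithful to a
  log-rank framing.
* **Time-dependent ROC** — the cumulative/dynamic variant: at horizon *t*,
  cases are events by *t*, controls are subjects observed beyond *t*, and
  both sides are weighted by the inverse Kaplan–Meier estimate of the
  censoring survival (IPCW), with G(t−) for cases and G(t) for controls.
  Thresholds are midpoints between adjacent observed marker values (with
  sentinels outside the range) so that the returned cutoff composes exactly
  with the strict group rule below; placing thresholds at midpoints leaves
  the AUC unchanged.  AUC is the trapezoid over the (FPR, TPR) polyline.
  Among time-dependent ROC variants, cumulative/dynamic matches the
  "survival at 1 year" reading of horizon-based evaluation; the variant is
  recorded in the output.
* **Cutoff** — the threshold maximizing Youden's J = TPR − FPR; ties within
  1e−12 are broken toward the threshold nearest the marker median, so a
  perfectly separating marker yields an interior cutoff rather than an
  arbitrary plateau endpoint.

## Signature training

The univariate screen fits one Cox model per candidate pair and passes
those with Wald p below `alpha` (default 0.05, configurable — the screen
threshold is a free parameter of such studies, not a law).  Constant-score
and non-convergent pairs are flagged degenerate and cannot pass.

The LASSO stage delegates the coordinate-descent path to scikit-survival's
glmnet-style Coxnet (`l1_ratio=1`), then chooses the penalty by n-fold
(default 10) cross-validated partial-likelihood deviance using the
Verweij–Van Houwelingen construction, `dev = −2·(ℓ(all; β) − ℓ(train; β))`
with Breslow ties matching the penalized fit.  Folds are stratified by
event status and derived deterministically from the seed.  The default rule
is the deviance minimum (`lambda.min`); the sparser one-standard-error rule
is available as `lambda_rule="1se"`.  Zero-coefficient pairs at the chosen
penalty are dropped; an empty selection raises a no-signal error rather
than returning a vacuous model.

The risk score is the dot product of a sample's binary pair scores with the
selected coefficients.  Group assignment is strict — score **>** cutoff is
high risk; at-cutoff samples are low.  The choice at the boundary is
arbitrary and configurable in spirit; strictness is recorded here and kept
consistent between calibration and validation.

Validation freezes everything: pair definitions, coefficients, cutoff.  The
external cohort is scored, grouped, and summarized (KM curves, log-rank,
hazard ratio of high vs low with Wald CI, AUCs at 1/3/5 × horizon).  An
empty group under the frozen cutoff is reported with the HR omitted.
Subgroup analyses re-run log-rank/Cox within each stratum of a clinical
covariate, skipping strata with fewer than 2 samples per risk group.
Clinical adjustment codes stage I–IV and grade G1–G4 as 1–4, other
categorical covariates alphabetically, and fits one univariate Cox per
covariate plus a joint multivariate model including the risk score.

## Immune deconvolution

Bulk profiles are modeled as non-negative mixtures of reference cell-type
profiles.  The estimator is non-negative least squares on the genes shared
between bulk and reference, rescaled to the unit simplex; an all-zero NNLS
solution falls back to uniform fractions with a note.  NNLS is the simplest
well-posed estimator satisfying the constrained-regression contract; an
SVR-style estimator can be plugged in behind the same interface.
Significance follows the standard permutation scheme: the statistic is the
Pearson correlation between reconstructed and observed bulk, the p-value an
add-one Monte-Carlo tail over gene-label permutations (default 1000), so
p is never exactly 0 and is exactly reproducible for a fixed seed.

Group comparisons are per-cell-type Welch t-tests with raw p-values
(mirroring the starred-p convention of infiltration reports); a
Benjamini–Hochberg column is emitted alongside for honest reading.
Score–fraction association uses Pearson by default, Spearman optionally;
constant fraction vectors are reported as missing rather than as r = 0.

The packaged reference is a **synthetic** 50-gene × 6-cell-type
marker-block matrix (each cell type over-expresses an exclusive marker
block ~10× over background), generated by
`immune_deconv.synthetic_reference`; it makes mixtures identifiable for
tests and demonstrations and is not derived from any published signature
matrix.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline consumes:

* per-gene log-normal expression laws drawn once and shared by both
  cohorts;
* planted pairs whose two genes share a per-sample center with an
  always-positive log-scale half-gap (floor 0.35 plus half-normal noise,
  `noise_sd` default 0.25) signed by a latent Bernoulli(1/2) state z, so
  the within-patient ordering equals z exactly and the signal lives *only*
  in the ordering;
* survival `Exponential(λ0 · exp(Σ β_k z_k))` with exponential censoring —
  the simplest law satisfying proportional hazards, adequate because no
  stage models baseline shape;
* a per-sample strictly increasing distortion of cohort 2 (positive-slope
  affine, monotone cubic, or rank-preserving random remap) standing in for
  platform effects;
* optional immune-marker rows generated as Dirichlet mixtures of the
  packaged reference with 5% multiplicative noise, with the true fractions
  recorded;
* clinical covariates (stage, grade, gender, age) drawn independently of
  risk, so adjustment stages can be exercised under a null.

Reference conditions, fixed once: 20 genes, 300 samples per cohort, 3
planted pairs with log-hazard β = 1.5 each, baseline hazard 0.05 and
censoring rate 0.15 per year.  The two rates were chosen analytically so
that, averaged over the eight planted-state configurations, the censoring
fraction is ≈30% (computed value 29.7%); the empirical fraction in
simulation matches.  Twenty genes give 190 possible pairs, which puts the
screen and LASSO in the "few dozen candidates per selected pair" regime
while keeping 50-seed replication experiments fast.

What the generator does **not** imitate: gene–gene correlation beyond the
planted pairs, cohort case-mix differences, non-proportional hazards, or
realistic immune-fraction covariance.  Passing tests therefore demonstrate
that the machinery is correct and that rank-pair signatures transfer under
monotone distortion — not that any particular real-data signature is
reproducible.

## Problem sizes in the automated checks

The test suite and acceptance script run the headline recovery at the
reference conditions over 50 seeds, the type-I-error calibration over
100–200 simulated null screens of 10 genes × 100 samples, and the
determinism check on 120-sample cohorts; these sizes are the package's
chosen replication scale and keep a full run in the minutes range on one
CPU.

## Known limitations

* No frailty, stratified, time-varying, or competing-risk survival models.
* The Cox fitter targets the small-to-moderate covariate counts of this
  workflow (screens are univariate; multivariate fits have ≲ 10
  covariates); it is not tuned for wide design matrices.
* Permutation p-values in deconvolution are per-sample Monte Carlo;
  at the default 1000 permutations their resolution is ~1e−3.
* The frequency band, screen alpha, and penalty rule are study-design
  parameters; defaults follow field convention, and changing them changes
  the selected signature.
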