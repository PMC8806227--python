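# pairhazard

Rank-based gene-pair prognostic signatures for survival cohorts.

## The problem

Expression-based prognostic signatures usually require careful normalization
before a model trained on one cohort can be applied to another; platform and
batch effects otherwise dominate. A rank-pair signature sidesteps this: for
an ordered gene pair (a, b) and a patient *s*, define the binary score

```
score(a, b; s) = 1  if  E(a, s) > E(b, s),   else 0
```

which depends only on the *within-patient ordering* of the two genes.  Any
strictly increasing per-sample transform of the expression values — scaling,
log-transforms, monotone batch distortions — leaves every score unchanged,
so a signature built from such scores transfers across platforms with no
normalization step at all.  This package implements the full workflow for
building and validating such signatures in oncology-style two-cohort
studies (a discovery and an independent validation cohort of, e.g.,
hepatocellular-carcinoma patients), plus the customary downstream
immune-infiltration analysis.

## The method

1. **Gene filtering** — candidate genes (a packaged 127-gene autophagy list
   ships as the default) are kept when present in both cohorts with median
   absolute deviation ≥ 0.5 in each.
2. **Pair scoring** — all k(k−1)/2 ordered pairs of the retained genes are
   scored per patient; pairs whose score-1 frequency leaves the [0.2, 0.8]
   band in either cohort are dropped as uninformative.
3. **Univariate screen** — each pair's score enters a single-covariate Cox
   model; pairs with Wald p < 0.05 proceed.  (For a binary covariate the Cox
   score test and the log-rank test coincide.)
4. **LASSO-Cox** — an L1-penalized Cox model over the screened pairs, with
   the penalty chosen by 10-fold cross-validated partial-likelihood
   deviance, yields a sparse signature.  The risk score of a patient is

   ```
   risk(s) = Σ_k  coef_k · score(pair_k; s)
   ```

5. **Cutoff calibration** — the time-dependent (cumulative/dynamic, IPCW)
   ROC of the training risk scores at a fixed horizon gives a Youden-optimal
   cutoff; patients strictly above it are high risk.
6. **Frozen-cutoff validation** — the validation cohort is scored with the
   *same* pairs, coefficients and cutoff (never re-calibrated); Kaplan–Meier
   curves, the log-rank test, the hazard ratio of high vs low risk, and
   ROC AUCs at 1/3/5 × horizon quantify transfer.
7. **Immune deconvolution** — bulk profiles are decomposed into cell-type
   fractions by non-negative least squares against a reference signature
   matrix, with permutation p-values; fractions are compared between risk
   groups (Welch t-tests) and correlated with the risk score.

A synthetic-cohort generator (`pairhazard.synthetic_cohorts`) plants gene
pairs whose within-patient ordering drives an exponential proportional-
hazards survival law, applies monotone platform distortions to the second
cohort, and records the ground truth, so the whole pipeline is testable
without access to any real cohort.

## Worked example

```python
from pairhazard import SimulationConfig, simulate_cohort_pair, GeneList
from pairhazard.pipeline import analyze_cohorts

study = simulate_cohort_pair(SimulationConfig(seed=11))
(expr1, clin1), (expr2, clin2) = study.cohorts
candidates = GeneList.from_iterable(g for g in expr1.gene_ids
                                    if g.startswith("G"))
result = analyze_cohorts(expr1, clin1, expr2, clin2, candidates,
                         horizon=1.0, seed=11)
print(result.counts)
v = result.validation
print(f"validation: HR={v.hazard_ratio:.2f} "
      f"(95% CI {v.hr_ci[0]:.2f}-{v.hr_ci[1]:.2f}), "
      f"log-rank p={v.logrank_p:.2e}")
```

prints

```
{'genes_in': 20, 'genes_retained': 20, 'pairs_total': 190,
 'pairs_candidate': 140, 'pairs_screened': 65, 'pairs_selected': 18}
validation: HR=5.06 (95% CI 3.73-6.86), log-rank p=3.10e-29
```

Of 190 possible pairs from 20 genes, 140 survive the frequency band, 65 the
univariate screen, and the LASSO keeps 18 — including all three planted
pairs (`study.truth.pair_ids()`).  Applied to the *independent* validation
cohort with the frozen training cutoff, the high-risk group has about five
times the death hazard of the low-risk group, and the 1-year ROC AUC is
0.86: the planted prognostic structure transfers across the simulated
platform distortion, as the rank-based construction guarantees.

The same workflow is available from the shell:

```bash
pairhazard simulate --seed 11 --outdir data/
pairhazard run --config config.yaml --outdir results/
```

where `config.yaml` names the four cohort files, the gene list, the ROC
horizon with its time unit, and the seed.  Each run writes a
`manifest.json` with per-stage input/output checksums; identical config and
seed reproduce identical checksums.

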