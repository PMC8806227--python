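"""Training and validation of the gene-pair prognostic signature.

The pipeline stages live here:

1. :func:`univariate_screen` — one Cox fit per candidate pair on its binary
   score; a pair passes when the Wald p-value clears ``alpha``.  For a
   binary covariate the Cox score test coincides with the log-rank test, so
   a single-covariate Cox fit covers both framings of the screen.
2. :func:`lasso_cox` — L1-penalized Cox over a descending lambda grid
   (glmnet-style coordinate descent via scikit-survival), with the penalty
   chosen by n-fold cross-validated partial-likelihood deviance
   (Verweij–Van Houwelingen).  Pairs with zero coefficient at the chosen
   lambda are dropped.
3. :func:`risk_scores` — prognostic score of a sample: the dot product of
   its binary pair scores with the model coefficients.
4. :func:`calibrate_cutoff` — Youden-J cutoff from the time-dependent ROC
   of the training scores at the evaluation horizon.
5. :func:`validate` — frozen-cutoff external validation: groups by the
   *training* cutoff, log-rank test, hazard ratio of high vs low, and ROC
   AUCs at 1/3/5 × horizon.  The validation cohort is never re-calibrated.
6. :func:`subgroup_km` / :func:`clinical_cox` — per-stratum survival checks
   and uni/multivariate adjustment for clinical covariates.

Samples are always joined on the intersection of pair-matrix and clinical
ids, in pair-matrix order.  Risk groups use the strict rule: score strictly
above the cutoff is high risk; at-cutoff samples are low risk.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .data_model_io import ClinicalTable, SignatureModel
from .errors import AlignmentError, DomainError, NoSignalError
from .pair_engine import PairScoreMatrix
from .survival_core import (CoxFit, KMCurve, cox_fit, cox_log_partial_likelihood,
                            km_estimate, logrank_test, optimal_cutoff, td_roc)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alignment helper
# ---------------------------------------------------------------------------

def _align(pairs: PairScoreMatrix, clinical: ClinicalTable):
    """Intersect pair-matrix samples with clinical samples, matrix order first."""
    clin_ids = set(clinical.sample_ids)
    keep = [i for i, s in enumerate(pairs.sample_ids) if s in clin_ids]
    if not keep:
        raise AlignmentError("pair matrix and clinical table share no samples")
    sample_ids = [pairs.sample_ids[i] for i in keep]
    scores = pairs.scores[:, keep]
    clin = clinical.subset(sample_ids)
    return sample_ids, scores, clin.os_time, clin.os_event


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    pair: tuple[str, str]
    hazard_ratio: float
    p_value: float
    passed: bool
    note: str = ""


def univariate_screen(pairs: PairScoreMatrix, clinical: ClinicalTable,
                      alpha: float = 0.05, raise_on_empty: bool = True
                      ) -> list[ScreenResult]:
    """Single-covariate Cox screen of every pair's binary score.

    Pairs with a constant score (or a non-converging fit) are flagged
    degenerate and cannot pass.  Results keep input pair order.  When no
    pair passes, an "empty screen" error is raised unless
    ``raise_on_empty=False`` (useful for null calibration studies where
    zero passes is the expected outcome).
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    _, scores, times, events, = _align(pairs, clinical)
    results: list[ScreenResult] = []
    for pair, row in zip(pairs.pairs, scores):
        x = row.astype(float)
        if x.min() == x.max():
            results.append(ScreenResult((pair.gene_hi, pair.gene_lo),
                                        np.nan, np.nan, False, "degenerate"))
            continue
        fit = cox_fit(times, events, x)
        if not fit.converged:
            results.append(ScreenResult((pair.gene_hi, pair.gene_lo),
                                        np.nan, np.nan, False,
                                        fit.note or "non-convergent"))
            continue
        p = float(fit.p_values[0])
        results.append(ScreenResult((pair.gene_hi, pair.gene_lo),
                                    float(fit.hazard_ratios[0]), p, p < alpha))
    n_passed = sum(r.passed for r in results)
    logger.info("univariate_screen: %d/%d pairs passed at alpha=%g",
                n_passed, len(results), alpha)
    if n_passed == 0 and raise_on_empty:
        raise NoSignalError(f"empty screen: no pair passed at alpha={alpha}")
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f"{hi}|{lo}", r.hazard_ratio, r.p_value, r.passed, r.note)
         for r in results for hi, lo in [r.pair]],
        columns=["pair", "hazard_ratio", "p_value", "passed", "note"])


# ---------------------------------------------------------------------------
# LASSO-Cox
# ---------------------------------------------------------------------------

def lasso_cox(pairs: PairScoreMatrix, clinical: ClinicalTable,
              n_folds: int = 10, seed: int = 0, lambda_rule: str = "min",
              alphas=None) -> SignatureModel:
    """L1-penalized Cox selection of pairs, penalty by cross-validated deviance.

    ``pairs`` should already be restricted to screened pairs.  The lambda
    grid is glmnet's descending path unless ``alphas`` is given explicitly;
    a single explicit alpha skips cross-validation.  ``lambda_rule`` is
    ``"min"`` (minimum mean CV deviance, default) or ``"1se"`` (sparsest
    model within one standard error of the minimum).  Fold assignment is
    stratified by event status and derived deterministically from ``seed``.
    Deviance uses the Verweij–Van Houwelingen cross-validated partial
    likelihood, Breslow ties (matching the coordinate-descent fit).
    """
    if lambda_rule not in ("min", "1se"):
        raise DomainError(f"lambda_rule must be 'min' or '1se', got {lambda_rule!r}")
    if len(pairs.pairs) < 2:
        raise DomainError("lasso_cox needs at least 2 screened pairs")
    sample_ids, scores, times, events = _align(pairs, clinical)
    n = len(sample_ids)
    if events.sum() < n_folds:
        raise DomainError(
            f"lasso_cox needs at least n_folds={n_folds} events, have {int(events.sum())}")

    X = scores.T.astype(float)
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    def coxnet(a):
        return CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=a, n_alphas=50,
                                      alpha_min_ratio=0.01, tol=1e-9)

    import warnings

    with warnings.catch_warnings():
        # the all-zero-coefficients case is handled below as NoSignalError
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        full = coxnet(None if alphas is None else list(alphas)).fit(X, y)
    grid = np.asarray(full.alphas_)
    coefs = np.asarray(full.coef_)  # (n_features, n_alphas)
    if not np.any(coefs != 0):
        raise NoSignalError("no signal: all coefficients are zero at every lambda")

    if len(grid) == 1:
        chosen_idx = 0
        cv_mean = None
    else:
        # stratified deterministic folds
        rng = np.random.default_rng(seed)
        fold_id = np.empty(n, dtype=int)
        for mask in (events == 1, events == 0):
            idx = rng.permutation(np.nonzero(mask)[0])
            fold_id[idx] = np.arange(len(idx)) % n_folds
        fold_dev = np.full((n_folds, len(grid)), np.nan)
        for f in range(n_folds):
            train = fold_id != f
            fit_f = coxnet(list(grid)).fit(X[train], y[train])
            for a_i, beta in enumerate(np.asarray(fit_f.coef_).T):
                ll_all = cox_log_partial_likelihood(beta, times, events, X, ties="breslow")
                ll_train = cox_log_partial_likelihood(
                    beta, times[train], events[train], X[train], ties="breslow")
                fold_dev[f, a_i] = -2.0 * (ll_all - ll_train)
        cv_mean = fold_dev.mean(axis=0)
        cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        i_min = int(np.argmin(cv_mean))
        if lambda_rule == "min":
            chosen_idx = i_min
        else:
            ok = np.nonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])[0]
            chosen_idx = int(ok[0])  # grid descends: first index = largest lambda

    beta = coefs[:, chosen_idx]
    nonzero = np.nonzero(beta)[0]
    if len(nonzero) == 0:
        raise NoSignalError(
            f"no signal: chosen lambda {grid[chosen_idx]:.4g} selects an empty model")
    selected = [(pairs.pairs[i].gene_hi, pairs.pairs[i].gene_lo) for i in nonzero]
    logger.info("lasso_cox: lambda=%.4g selected %d/%d pairs",
                grid[chosen_idx], len(nonzero), len(beta))
    return SignatureModel(
        pairs=selected,
        coefficients=beta[nonzero],
        provenance={
            "seed": int(seed), "n_folds": int(n_folds), "lambda_rule": lambda_rule,
            "lambda": float(grid[chosen_idx]), "n_candidate_pairs": int(len(beta)),
            "n_samples": int(n), "n_events": int(events.sum()),
        })


# ---------------------------------------------------------------------------
# Risk scores and groups
# ---------------------------------------------------------------------------

@dataclass
class RiskProfile:
    sample_id: str
    risk_score: float
    group: str | None = None  # "high" / "low" once a cutoff is applied


def risk_scores(model: SignatureModel, pairs: PairScoreMatrix) -> list[RiskProfile]:
    """Prognostic score per sample: binary pair scores · model coefficients."""
    row_of = {p.pair_id: i for i, p in enumerate(pairs.pairs)}
    missing = [pid for pid in model.pair_ids if pid not in row_of]
    if missing:
        raise AlignmentError(f"model pair(s) absent from score matrix: {missing[:5]}")
    sub = pairs.scores[[row_of[pid] for pid in model.pair_ids]].astype(float)
    values = model.coefficients @ sub
    return [RiskProfile(s, float(v)) for s, v in zip(pairs.sample_ids, values)]


def assign_groups(profiles: list[RiskProfile], cutoff: float) -> list[RiskProfile]:
    """Strict group rule: risk score > cutoff → high; at or below → low."""
    return [dataclasses.replace(p, group="high" if p.risk_score > cutoff else "low")
            for p in profiles]


def profiles_to_frame(profiles: list[RiskProfile]) -> pd.DataFrame:
    return pd.DataFrame([(p.sample_id, p.risk_score, p.group) for p in profiles],
                        columns=["sample_id", "risk_score", "group"])


def calibrate_cutoff(model: SignatureModel, pairs: PairScoreMatrix,
                     clinical: ClinicalTable, horizon: float) -> SignatureModel:
    """Set the model cutoff from the Youden-optimal threshold of the training ROC.

    ``horizon`` must be expressed in the clinical table's time unit.
    """
    profiles = risk_scores(model, pairs)
    score_of = {p.sample_id: p.risk_score for p in profiles}
    sample_ids, _, times, events = _align(pairs, clinical)
    marker = np.array([score_of[s] for s in sample_ids])
    roc = td_roc(times, events, marker, horizon)
    cutoff = optimal_cutoff(roc)
    provenance = dict(model.provenance)
    provenance["cutoff_auc"] = float(roc.auc)
    return dataclasses.replace(model, cutoff=cutoff, horizon=float(horizon),
                               provenance=provenance)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Frozen-cutoff evaluation of a signature on one cohort."""

    n_high: int
    n_low: int
    n_events: int
    profiles: list[RiskProfile] = field(repr=False)
    km_high: KMCurve | None = None
    km_low: KMCurve | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    hazard_ratio: float | None = None
    hr_ci: tuple[float, float] | None = None
    hr_p: float | None = None
    aucs: dict[float, float | None] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def validate(model: SignatureModel, pairs2: PairScoreMatrix,
             clinical2: ClinicalTable, horizons=None) -> ValidationReport:
    """Evaluate the signature on an external cohort with the frozen cutoff.

    The cohort's pair matrix must use the same pair definitions as training;
    the cutoff is applied as-is, never re-calibrated.  ``horizons`` defaults
    to 1, 3 and 5 times the model horizon (the 1/3/5-year convention when
    the horizon is one year).
    """
    if model.cutoff is None:
        raise DomainError("validate requires a calibrated model (cutoff is unset)")
    if horizons is None:
        horizons = [model.horizon * k for k in (1, 3, 5)] if model.horizon else []

    sample_ids, _, times, events = _align(pairs2, clinical2)
    profiles = assign_groups(risk_scores(model, pairs2), model.cutoff)
    score_of = {p.sample_id: p for p in profiles}
    kept = [score_of[s] for s in sample_ids]
    high = np.array([p.group == "high" for p in kept])
    marker = np.array([p.risk_score for p in kept])

    report = ValidationReport(n_high=int(high.sum()), n_low=int((~high).sum()),
                              n_events=int(events.sum()), profiles=kept)
    if report.n_high == 0 or report.n_low == 0:
        report.notes.append(
            f"a group is empty under the frozen cutoff {model.cutoff:g}; "
            "log-rank and HR omitted")
    else:
        report.km_high = km_estimate(times[high], events[high])
        report.km_low = km_estimate(times[~high], events[~high])
        lr = logrank_test(times, events, high.astype(int))
        report.logrank_chi2, report.logrank_p = lr.chi_square, lr.p_value
        fit = cox_fit(times, events, high.astype(float))
        if fit.converged:
            report.hazard_ratio = float(fit.hazard_ratios[0])
            report.hr_ci = (float(fit.ci_lower[0]), float(fit.ci_upper[0]))
            report.hr_p = float(fit.p_values[0])
        else:
            report.notes.append(f"group Cox fit did not converge: {fit.note}")
    for h in horizons:
        try:
            report.aucs[float(h)] = float(td_roc(times, events, marker, h).auc)
        except DomainError as exc:
            report.aucs[float(h)] = None
            report.notes.append(str(exc))
    return report


# ---------------------------------------------------------------------------
# Subgroup analysis and clinical adjustment
# ---------------------------------------------------------------------------

@dataclass
class SubgroupResult:
    stratum: str
    n_high: int
    n_low: int
    n_events: int
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    hazard_ratio: float | None = None
    hr_ci: tuple[float, float] | None = None
    skipped: bool = False
    note: str = ""


def subgroup_km(profiles: list[RiskProfile], clinical: ClinicalTable,
                stratify_by: str) -> list[SubgroupResult]:
    """Log-rank + Cox of high vs low risk within each stratum of a covariate.

    Strata with fewer than 2 samples in either risk group are skipped with a
    note rather than raising.
    """
    if stratify_by not in clinical.data.columns:
        raise DomainError(f"clinical table has no column {stratify_by!r}")
    group_of = {p.sample_id: p.group for p in profiles if p.group is not None}
    results = []
    strata = clinical.data[stratify_by].dropna().unique()
    for stratum in sorted(strata, key=str):
        ids = [s for s in clinical.data.index[clinical.data[stratify_by] == stratum]
               if s in group_of]
        sub = clinical.subset(ids)
        high = np.array([group_of[s] == "high" for s in ids])
        res = SubgroupResult(str(stratum), int(high.sum()), int((~high).sum()),
                             int(sub.os_event.sum()))
        if res.n_high < 2 or res.n_low < 2:
            res.skipped = True
            res.note = "fewer than 2 samples in a risk group"
        else:
            lr = logrank_test(sub.os_time, sub.os_event, high.astype(int))
            res.logrank_chi2, res.logrank_p = lr.chi_square, lr.p_value
            fit = cox_fit(sub.os_time, sub.os_event, high.astype(float))
            if fit.converged:
                res.hazard_ratio = float(fit.hazard_ratios[0])
                res.hr_ci = (float(fit.ci_lower[0]), float(fit.ci_upper[0]))
            else:
                res.note = f"Cox fit did not converge: {fit.note}"
        results.append(res)
    return results


_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4,
            "G1": 1, "G2": 2, "G3": 3, "G4": 4}


def _encode_covariate(series: pd.Series, name: str) -> pd.Series:
    """Numeric coding: ordinal stage/grade tokens → 1..4, other categorical
    columns → alphabetical level codes, numeric columns unchanged."""
    values = [v for v in series.dropna().unique()]
    if values and all(v in _ORDINAL for v in values):
        return series.map(_ORDINAL)
    if series.dtype == object:
        levels = sorted(values, key=str)
        return series.map({lv: i for i, lv in enumerate(levels)})
    return pd.to_numeric(series, errors="coerce")


def clinical_cox(profiles: list[RiskProfile], clinical: ClinicalTable,
                 covariates=("age", "gender", "grade", "stage")
                 ) -> tuple[pd.DataFrame, CoxFit]:
    """Univariate and multivariate Cox of the risk score and clinical covariates.

    Ordinal covariates are coded numerically (stage I–IV → 1–4, grade G1–G4
    → 1–4, gender alphabetically → 0/1); samples missing any requested
    covariate are dropped.  Returns the per-covariate univariate table and
    the joint multivariate fit (collinearity surfaces as a flagged
    non-convergence, per the Cox contract).
    """
    for cov in covariates:
        if cov not in clinical.data.columns:
            raise DomainError(f"clinical table has no column {cov!r}")
    score_of = {p.sample_id: p.risk_score for p in profiles}
    ids = [s for s in clinical.data.index if s in score_of]
    design = pd.DataFrame(index=ids)
    design["risk_score"] = [score_of[s] for s in ids]
    for cov in covariates:
        design[cov] = _encode_covariate(clinical.data.loc[ids, cov], cov)
    complete = design.dropna()
    if len(complete) < len(design):
        logger.info("clinical_cox: dropped %d sample(s) with missing covariates",
                    len(design) - len(complete))
    sub = clinical.subset(list(complete.index))
    times, events = sub.os_time, sub.os_event

    rows = []
    for col in complete.columns:
        fit = cox_fit(times, events, complete[col].to_numpy(dtype=float))
        rows.append((col, float(fit.hazard_ratios[0]), float(fit.ci_lower[0]),
                     float(fit.ci_upper[0]), float(fit.p_values[0]), fit.converged))
    uni = pd.DataFrame(rows, columns=["covariate", "hazard_ratio", "ci_lower",
                                      "ci_upper", "p_value", "converged"])
    # multivariate fit: covariate order is risk_score followed by `covariates`
    multi = cox_fit(times, events, complete.to_numpy(dtype=float))
    return uni, multi
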