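"""Synthetic paired survival cohorts with planted prognostic gene pairs.

The generator emulates the structure a rank-pair signature study needs and
nothing else: two cohorts sharing gene identifiers, a handful of planted
gene pairs whose within-patient ordering drives survival, per-sample
monotone platform distortions in the second cohort, and independent
exponential right-censoring.

Construction, per cohort:

* Each gene g gets a log-normal expression law ``exp(mu_g + sigma_g * Z)``
  with (mu_g, sigma_g) drawn once and shared across cohorts, so both
  cohorts measure "the same genes".
* For each planted pair (a, b) a latent per-sample Bernoulli(1/2) state
  z(s) is drawn; the two genes are given a common per-sample center and an
  always-positive half-gap on the log scale, signed by z, so that
  ``E(a, s) > E(b, s)`` exactly when ``z(s) = 1``.  The signal lives purely
  in the ordering — magnitudes carry nothing — so downstream recovery
  specifically validates the rank-pair mechanism.
* The log hazard is linear in the planted states: survival time is
  ``Exponential(baseline_hazard * exp(sum_k beta_k * z_k(s)))``, censoring
  time is ``Exponential(censor_rate)``; observed time is the minimum with
  the usual event indicator.  The exponential baseline is the simplest law
  satisfying proportional hazards, and no pipeline stage models baseline
  shape.
* Cohort 2's expression columns pass through a per-sample strictly
  increasing distortion (affine with positive slope, monotone cubic, or a
  rank-preserving random remap), emulating cross-platform scale effects
  that rank-based scoring must ignore.

Stage, grade, gender and age covariates are drawn independently of the
planted risk, so clinical-adjustment stages can be exercised under a null.
What this generator does **not** imitate: gene–gene correlation structure,
cohort-specific case mix, or non-proportional hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import ClinicalTable, ExpressionMatrix
from .errors import ConfigError

_DISTORTIONS = ("none", "affine", "monotone-cubic", "rank-preserving-random")

#: floor of the log-scale half-gap between the two genes of a planted pair;
#: keeps the planted ordering strict for every sample.
_GAP_FLOOR = 0.35


@dataclass
class SimulationConfig:
    """Study-design parameters for a paired-cohort simulation.

    Defaults are the package's reference study conditions: 20 genes, 300
    samples per cohort, 3 planted pairs with log-hazard 1.5 each, and
    baseline/censoring rates (0.05 and 0.15 per unit time, time unit
    "years") that yield ≈30% censoring under those effects.
    """

    n_genes: int = 20
    n_samples_per_cohort: int = 300
    n_planted_pairs: int = 3
    planted_log_hazard: float | tuple = 1.5
    baseline_hazard: float = 0.05
    censor_rate: float = 0.15
    noise_sd: float = 0.25
    distortion: str = "affine"
    seed: int = 0
    with_clinical_covariates: bool = True
    #: append the packaged immune-reference marker genes as per-sample
    #: noisy mixtures of the reference profiles, so deconvolution stages
    #: have shared genes to work with
    with_immune_markers: bool = True

    def betas(self) -> np.ndarray:
        b = np.asarray(self.planted_log_hazard, dtype=float)
        if b.ndim == 0:
            b = np.repeat(b, self.n_planted_pairs)
        if b.shape != (self.n_planted_pairs,):
            raise ConfigError("planted_log_hazard must be scalar or one value per pair")
        return b

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError(f"n_genes must be >= 2, got {self.n_genes}")
        if self.n_samples_per_cohort < 2:
            raise ConfigError("n_samples_per_cohort must be >= 2")
        if self.n_planted_pairs < 0 or 2 * self.n_planted_pairs > self.n_genes:
            raise ConfigError(
                f"need 2 * n_planted_pairs <= n_genes "
                f"({self.n_planted_pairs} pairs, {self.n_genes} genes)")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ConfigError("baseline_hazard and censor_rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.distortion not in _DISTORTIONS:
            raise ConfigError(f"distortion must be one of {_DISTORTIONS}")
        self.betas()


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: planted pairs, effects, latent states."""

    planted_pairs: list[tuple[str, str]]
    betas: np.ndarray
    #: latent pair states per cohort: list of (n_planted_pairs × n_samples) frames
    z: list[pd.DataFrame] = field(repr=False)
    #: true immune cell fractions per cohort (cell types × samples), if simulated
    immune_fractions: list[pd.DataFrame] | None = field(repr=False, default=None)

    def pair_ids(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.planted_pairs]


@dataclass
class SimulatedStudy:
    """A discovery/validation cohort pair plus its generating truth."""

    cohorts: list[tuple[ExpressionMatrix, ClinicalTable]]
    truth: PlantedTruth
    config: SimulationConfig


def _distort_columns(X: np.ndarray, kind: str,
                     rng: np.random.Generator) -> np.ndarray:
    """Apply a per-sample strictly increasing map to each column."""
    if kind == "none":
        return X.copy()
    n_genes, n_samples = X.shape
    out = np.empty_like(X)
    for s in range(n_samples):
        col = X[:, s]
        if kind == "affine":
            a, b = rng.uniform(0.5, 2.0), rng.uniform(0.0, 1.0)
            out[:, s] = a * col + b
        elif kind == "monotone-cubic":
            c1, c3 = rng.uniform(0.2, 1.0), rng.uniform(0.01, 0.1)
            out[:, s] = c1 * col + c3 * col ** 3
        else:  # rank-preserving-random
            targets = np.sort(rng.lognormal(mean=1.0, sigma=1.0, size=n_genes))
            ranks = np.argsort(np.argsort(col))
            out[:, s] = targets[ranks]
    return out


def _clinical_frame(n: int, times: np.ndarray, events: np.ndarray,
                    sample_ids: list[str], cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    df = pd.DataFrame({"os_time": times, "os_event": events}, index=sample_ids)
    df.index.name = "sample_id"
    if cfg.with_clinical_covariates:
        df["stage"] = rng.choice(["I", "II", "III", "IV"], size=n,
                                 p=[0.30, 0.30, 0.25, 0.15])
        df["grade"] = rng.choice(["G1", "G2", "G3", "G4"], size=n,
                                 p=[0.20, 0.35, 0.30, 0.15])
        df["gender"] = rng.choice(["M", "F"], size=n)
        df["age"] = np.round(np.clip(rng.normal(60, 10, size=n), 30, 85), 1)
    return df


def simulate_cohort_pair(config: SimulationConfig) -> SimulatedStudy:
    """Generate a discovery and a validation cohort from one planted truth.

    Output is bit-identical for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    betas = config.betas()
    k = config.n_planted_pairs
    n = config.n_samples_per_cohort

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    planted = [(genes[2 * j], genes[2 * j + 1]) for j in range(k)]
    # gene laws shared across cohorts
    mu = rng.normal(2.0, 0.6, size=config.n_genes)
    sigma = rng.uniform(0.3, 0.8, size=config.n_genes)

    cohorts = []
    z_frames = []
    immune_frames: list[pd.DataFrame] = []
    for c in range(2):
        sample_ids = [f"C{c + 1}S{i:04d}" for i in range(n)]
        log_expr = mu[:, None] + sigma[:, None] * rng.standard_normal((config.n_genes, n))
        z = rng.integers(0, 2, size=(k, n))
        for j, (a, b) in enumerate(planted):
            ia, ib = genes.index(a), genes.index(b)
            center = mu[ia] + sigma[ia] * rng.standard_normal(n)
            half_gap = _GAP_FLOOR + np.abs(rng.normal(0.0, config.noise_sd, size=n))
            sign = 2 * z[j] - 1
            log_expr[ia] = center + sign * half_gap
            log_expr[ib] = center - sign * half_gap

        lam = config.baseline_hazard * np.exp(betas @ z)
        surv_t = rng.exponential(1.0 / lam)
        cens_t = rng.exponential(1.0 / config.censor_rate, size=n)
        os_time = np.minimum(surv_t, cens_t)
        os_event = (surv_t <= cens_t).astype(int)

        expr_linear = np.exp(log_expr)
        row_names = list(genes)
        if config.with_immune_markers:
            from .immune_deconv import packaged_reference

            ref = packaged_reference()
            R = ref.data.to_numpy(dtype=float)
            fractions = rng.dirichlet(np.ones(R.shape[1]), size=n)  # (n, types)
            bulk = (R @ fractions.T) * np.exp(rng.normal(0, 0.05, (R.shape[0], n)))
            expr_linear = np.vstack([expr_linear, bulk])
            row_names = row_names + ref.gene_ids
            immune_frames.append(pd.DataFrame(fractions.T, index=ref.cell_types,
                                              columns=sample_ids))
        if c == 1:
            expr_linear = _distort_columns(expr_linear, config.distortion, rng)
        expr = ExpressionMatrix(pd.DataFrame(expr_linear, index=row_names,
                                             columns=sample_ids))
        clinical = ClinicalTable(
            _clinical_frame(n, os_time, os_event, sample_ids, config, rng),
            time_unit="years")
        cohorts.append((expr, clinical))
        z_frames.append(pd.DataFrame(z, index=[f"{a}|{b}" for a, b in planted],
                                     columns=sample_ids))

    truth = PlantedTruth(planted_pairs=planted, betas=betas, z=z_frames,
                         immune_fractions=immune_frames or None)
    return SimulatedStudy(cohorts=cohorts, truth=truth, config=config)
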