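"""Workflow orchestration: wire every stage into one reproducible run.

:func:`run_pipeline` executes the full study workflow in order —
gene filtering → pair scoring → candidate selection → univariate screen →
LASSO-Cox → cutoff calibration → frozen-cutoff validation → immune
deconvolution → group comparison and score correlation — writing each
stage's outputs to the run directory and recording a :class:`RunManifest`
with per-stage input/output checksums and counts.  Re-running with an
identical config and inputs reproduces identical checksums.

Configuration is a YAML (or flat key: value) file naming both cohorts'
expression and clinical files, the candidate gene list, the ROC horizon and
its time unit, and the seed; every tunable stage parameter can be
overridden.  All file paths are validated before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .data_model_io import (read_clinical, read_expression, read_gene_list,
                            packaged_gene_list, write_gene_list, write_signature)
from .errors import ConfigError, NoSignalError
from .gene_filtering import filter_genes
from .immune_deconv import (compare_groups, correlate_with_score, deconvolve,
                            packaged_reference, read_reference, results_to_frame)
from .pair_engine import build_pair_matrix, select_candidate_pairs, write_pair_matrix
from .signature_builder import (assign_groups, calibrate_cutoff, lasso_cox,
                                profiles_to_frame, risk_scores, screen_to_frame,
                                univariate_screen, validate)

logger = logging.getLogger(__name__)

_REQUIRED_KEYS = ("cohort1_expression", "cohort1_clinical",
                  "cohort2_expression", "cohort2_clinical",
                  "horizon", "time_unit", "seed")


@dataclass
class PipelineConfig:
    """Validated run configuration."""

    cohort1_expression: Path
    cohort1_clinical: Path
    cohort2_expression: Path
    cohort2_clinical: Path
    horizon: float
    time_unit: str
    seed: int
    gene_list: Path | None = None      # None → packaged 127-gene list
    reference: Path | None = None      # None → packaged synthetic reference
    horizon_unit: str | None = None    # if given, must equal time_unit
    dialect: str = "tsv"
    mad_threshold: float = 0.5
    min_freq: float = 0.2
    max_freq: float = 0.8
    screen_alpha: float = 0.05
    n_folds: int = 10
    lambda_rule: str = "min"
    n_perm: int = 200

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = [k for k in _REQUIRED_KEYS if k not in raw]
        if missing:
            raise ConfigError(f"config missing required key(s): {missing}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a key-value mapping")
        return cls.from_mapping(raw)

    def validate(self) -> None:
        for name in ("cohort1_expression", "cohort1_clinical",
                     "cohort2_expression", "cohort2_clinical"):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise ConfigError(f"config field {name!r}: file not found: {p}")
            setattr(self, name, p)
        for name in ("gene_list", "reference"):
            val = getattr(self, name)
            if val is not None:
                p = Path(val)
                if not p.is_file():
                    raise ConfigError(f"config field {name!r}: file not found: {p}")
                setattr(self, name, p)
        if self.horizon <= 0:
            raise ConfigError("horizon must be > 0")
        if self.horizon_unit is not None and self.horizon_unit != self.time_unit:
            raise ConfigError(
                f"horizon_unit {self.horizon_unit!r} does not match declared "
                f"time_unit {self.time_unit!r}")
        self.seed = int(self.seed)

    def snapshot(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in out.items()}


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, inputs: dict, outputs: dict, counts: dict) -> None:
        self.stages.append({"stage": name, "inputs": inputs,
                            "outputs": outputs, "counts": counts})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


@dataclass
class StudyResult:
    """In-memory result of the train-and-validate workflow on two cohorts."""

    model: "SignatureModel"
    counts: dict
    train_profiles: list
    validation: "ValidationReport"


def analyze_cohorts(expr1, clin1, expr2, clin2, candidates, horizon: float,
                    seed: int, mad_threshold: float = 0.5,
                    min_freq: float = 0.2, max_freq: float = 0.8,
                    screen_alpha: float = 0.05, n_folds: int = 10,
                    lambda_rule: str = "min") -> StudyResult:
    """Train on cohort 1 and validate frozen on cohort 2, all in memory.

    Runs gene filtering, pair scoring, candidate selection, univariate
    screening, LASSO-Cox, cutoff calibration and frozen-cutoff validation —
    the same stage order as :func:`run_pipeline`, without touching disk.
    """
    report = filter_genes(candidates, expr1, expr2, mad_threshold)
    m1 = build_pair_matrix(report.retained, expr1)
    m2 = build_pair_matrix(report.retained, expr2)
    candidate_pairs = select_candidate_pairs(m1, m2, min_freq, max_freq)
    if not candidate_pairs:
        raise NoSignalError("no candidate pairs survive the frequency band")
    m1c, m2c = m1.subset(candidate_pairs), m2.subset(candidate_pairs)
    screen = univariate_screen(m1c, clin1, alpha=screen_alpha)
    passed = [p for p, r in zip(m1c.pairs, screen) if r.passed]
    m1s = m1c.subset(passed)
    model = lasso_cox(m1s, clin1, n_folds=n_folds, seed=seed,
                      lambda_rule=lambda_rule)
    model = calibrate_cutoff(model, m1s, clin1, horizon=horizon)
    train_profiles = assign_groups(risk_scores(model, m1c), model.cutoff)
    val = validate(model, m2c, clin2)
    counts = {
        "genes_in": report.input_count, "genes_retained": len(report.retained),
        "pairs_total": len(m1.pairs), "pairs_candidate": len(candidate_pairs),
        "pairs_screened": len(passed), "pairs_selected": len(model.pairs),
    }
    return StudyResult(model=model, counts=counts,
                       train_profiles=train_profiles, validation=val)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _checksums(paths: dict) -> dict:
    return {name: _sha256(p) for name, p in paths.items()}


def run_pipeline(config: PipelineConfig | str | Path, outdir) -> RunManifest:
    """Execute the full workflow; any stage failure halts with a partial manifest.

    Returns the manifest, which is also written to ``<outdir>/manifest.json``
    (on success and on stage failure alike).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), seed=config.seed)

    def stage_log(name, counts):
        logger.info("stage %s: %s", name,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    try:
        # --- load inputs -------------------------------------------------
        expr1 = read_expression(config.cohort1_expression, config.dialect)
        clin1 = read_clinical(config.cohort1_clinical, config.dialect,
                              time_unit=config.time_unit)
        expr2 = read_expression(config.cohort2_expression, config.dialect)
        clin2 = read_clinical(config.cohort2_clinical, config.dialect,
                              time_unit=config.time_unit)
        candidates = (read_gene_list(config.gene_list) if config.gene_list
                      else packaged_gene_list())
        reference = (read_reference(config.reference) if config.reference
                     else packaged_reference())

        # --- filter-genes ------------------------------------------------
        report = filter_genes(candidates, expr1, expr2, config.mad_threshold)
        genes_path = outdir / "retained_genes.txt"
        report_path = outdir / "gene_filter_report.tsv"
        write_gene_list(report.retained, genes_path)
        report.to_frame().to_csv(report_path, sep="\t", index=False)
        counts = {"genes_in": report.input_count, "genes_out": len(report.retained)}
        manifest.add_stage(
            "filter-genes",
            _checksums({"cohort1_expression": config.cohort1_expression,
                        "cohort2_expression": config.cohort2_expression}),
            _checksums({"retained_genes": genes_path, "report": report_path}),
            counts)
        stage_log("filter-genes", counts)

        # --- score-pairs -------------------------------------------------
        m1 = build_pair_matrix(report.retained, expr1)
        m2 = build_pair_matrix(report.retained, expr2)
        candidate_pairs = select_candidate_pairs(m1, m2, config.min_freq,
                                                 config.max_freq)
        if not candidate_pairs:
            raise NoSignalError("no candidate pairs survive the frequency band")
        m1c, m2c = m1.subset(candidate_pairs), m2.subset(candidate_pairs)
        p1_path, p2_path = outdir / "pairs_cohort1.tsv", outdir / "pairs_cohort2.tsv"
        write_pair_matrix(m1c, p1_path)
        write_pair_matrix(m2c, p2_path)
        counts = {"pairs_total": len(m1.pairs), "pairs_candidate": len(candidate_pairs)}
        manifest.add_stage("score-pairs", _checksums({"retained_genes": genes_path}),
                           _checksums({"pairs_cohort1": p1_path,
                                       "pairs_cohort2": p2_path}), counts)
        stage_log("score-pairs", counts)

        # --- train -------------------------------------------------------
        screen = univariate_screen(m1c, clin1, alpha=config.screen_alpha)
        screen_path = outdir / "screen_results.tsv"
        screen_to_frame(screen).to_csv(screen_path, sep="\t", index=False)
        passed = [p for p, r in zip(m1c.pairs, screen) if r.passed]
        m1s = m1c.subset(passed)
        model = lasso_cox(m1s, clin1, n_folds=config.n_folds, seed=config.seed,
                          lambda_rule=config.lambda_rule)
        model = calibrate_cutoff(model, m1s, clin1, horizon=config.horizon)
        model.provenance["screen_alpha"] = config.screen_alpha
        sig_path = outdir / "signature.json"
        write_signature(model, sig_path)
        train_profiles = assign_groups(risk_scores(model, m1c), model.cutoff)
        risk1_path = outdir / "risk_cohort1.tsv"
        profiles_to_frame(train_profiles).to_csv(risk1_path, sep="\t", index=False)
        counts = {"pairs_screened": len(passed), "pairs_selected": len(model.pairs),
                  "cutoff": model.cutoff}
        manifest.add_stage("train",
                           _checksums({"pairs_cohort1": p1_path,
                                       "cohort1_clinical": config.cohort1_clinical}),
                           _checksums({"signature": sig_path, "screen": screen_path,
                                       "risk_cohort1": risk1_path}), counts)
        stage_log("train", counts)

        # --- validate ----------------------------------------------------
        val = validate(model, m2c, clin2)
        risk2_path = outdir / "risk_cohort2.tsv"
        profiles_to_frame(val.profiles).to_csv(risk2_path, sep="\t", index=False)
        val_path = outdir / "validation_report.json"
        val_payload = {
            "n_high": val.n_high, "n_low": val.n_low, "n_events": val.n_events,
            "logrank_chi2": val.logrank_chi2, "logrank_p": val.logrank_p,
            "hazard_ratio": val.hazard_ratio, "hr_ci": val.hr_ci, "hr_p": val.hr_p,
            "aucs": {str(k): v for k, v in val.aucs.items()}, "notes": val.notes,
        }
        val_path.write_text(json.dumps(val_payload, indent=2, sort_keys=True) + "\n")
        counts = {"n_high": val.n_high, "n_low": val.n_low}
        manifest.add_stage("validate",
                           _checksums({"signature": sig_path,
                                       "pairs_cohort2": p2_path,
                                       "cohort2_clinical": config.cohort2_clinical}),
                           _checksums({"validation_report": val_path,
                                       "risk_cohort2": risk2_path}), counts)
        stage_log("validate", counts)

        # --- deconv (discovery cohort) ------------------------------------
        deconv = deconvolve(expr1, reference, n_perm=config.n_perm, seed=config.seed)
        frac_path = outdir / "immune_fractions.tsv"
        results_to_frame(deconv).to_csv(frac_path, sep="\t")
        comp = compare_groups(deconv, train_profiles)
        comp_path = outdir / "immune_group_comparison.tsv"
        comp.to_csv(comp_path, sep="\t", index=False)
        counts = {"n_samples": len(deconv), "n_cell_types": len(reference.cell_types)}
        manifest.add_stage("deconv",
                           _checksums({"cohort1_expression": config.cohort1_expression}),
                           _checksums({"fractions": frac_path,
                                       "group_comparison": comp_path}), counts)
        stage_log("deconv", counts)

        # --- correlate -----------------------------------------------------
        corr = correlate_with_score(deconv, train_profiles)
        corr_path = outdir / "immune_score_correlation.tsv"
        corr.to_csv(corr_path, sep="\t", index=False)
        counts = {"n_cell_types": len(corr)}
        manifest.add_stage("correlate", _checksums({"fractions": frac_path}),
                           _checksums({"correlation": corr_path}), counts)
        stage_log("correlate", counts)
    except Exception:
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest
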