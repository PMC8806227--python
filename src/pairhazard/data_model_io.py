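"""Core data types and on-disk artifact IO.

The pipeline operates on four kinds of artifact:

* :class:`ExpressionMatrix` — a genes × samples table of library-normalized
  expression values (FPKM/TPM or a log thereof).  The pipeline never rescales
  these values: every downstream use is a within-sample comparison, which is
  invariant to any per-sample strictly increasing transform.
* :class:`ClinicalTable` — per-sample overall-survival time and event flag,
  plus optional stage/grade/gender/age covariates.
* :class:`GeneList` — an ordered, uppercase-normalized list of gene symbols.
* :class:`SignatureModel` — the trained gene-pair signature: ordered pairs,
  their LASSO coefficients, the ROC-derived risk-score cutoff and the
  evaluation horizon.  Serialized as JSON for frozen-cutoff reuse on
  external cohorts.

Tabular formats are plain TSV/CSV with a header; gene lists are one symbol
per line with ``#`` comments.  Survival-time units are carried as metadata
and never converted — the ROC horizon must be supplied in the same unit.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, DomainError

logger = logging.getLogger(__name__)

_SIGNATURE_SCHEMA_VERSION = 1

#: Roman-numeral stage tokens in ordinal order.
_STAGE_ORDER = ("I", "II", "III", "IV")
_GRADE_ORDER = ("G1", "G2", "G3", "G4")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of expression values.

    Parameters
    ----------
    data:
        DataFrame with unique gene symbols as index and unique sample ids as
        columns; every value finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) == 0:
            raise DataFormatError("expression matrix has no genes")
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate gene ids: {dups[:5]}")
        if any((not isinstance(g, str)) or g == "" for g in idx):
            raise DataFormatError("gene ids must be non-empty strings")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataFormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise DataFormatError("expression values must all be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome and optional clinical covariates.

    ``data`` is indexed by sample id with mandatory columns ``os_time``
    (positive) and ``os_event`` (0 censored / 1 death); optional columns
    ``stage`` (ordinal I–IV), ``grade`` (G1–G4), ``gender``, ``age``.
    ``time_unit`` is free-text metadata ("days", "months", "years", ...)
    recorded but never used for conversion.
    """

    data: pd.DataFrame
    time_unit: str = "unspecified"

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise DataFormatError(f"clinical table missing mandatory column {col!r}")
        if self.data.index.duplicated().any():
            raise DataFormatError("duplicate sample ids in clinical table")
        times = self.data["os_time"].to_numpy(dtype=float)
        if not (np.isfinite(times).all() and (times > 0).all()):
            raise DataFormatError("os_time must be finite and > 0 for every retained record")
        events = self.data["os_event"].to_numpy()
        if not np.isin(events, (0, 1)).all():
            bad = sorted(set(events) - {0, 1})
            raise DataFormatError(f"os_event must be 0 or 1, found {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.data["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.data["os_event"].to_numpy(dtype=int)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)], time_unit=self.time_unit)


@dataclass(frozen=True)
class GeneList:
    """Ordered set of uppercase gene symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise DataFormatError("gene list contains duplicate symbols")
        if any(s != s.upper() or not s for s in self.symbols):
            raise DataFormatError("gene symbols must be non-empty and uppercase-normalized")

    @classmethod
    def from_iterable(cls, symbols) -> "GeneList":
        seen: dict[str, None] = {}
        for s in symbols:
            s = str(s).strip().upper()
            if s:
                seen.setdefault(s, None)
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, item) -> bool:
        return item in self.symbols


@dataclass
class SignatureModel:
    """Trained gene-pair signature.

    ``pairs`` are ordered ``(gene_hi, gene_lo)`` tuples — the pair scores 1
    for a sample when gene_hi is expressed strictly above gene_lo.  The risk
    score of a sample is the dot product of its binary pair scores with
    ``coefficients``.  ``cutoff`` (risk score strictly above → high risk) and
    ``horizon`` (the ROC evaluation time, in the clinical table's time unit)
    are set by cutoff calibration and may be None for an uncalibrated model.
    """

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    cutoff: float | None = None
    horizon: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) == 0:
            raise DataFormatError("signature model must contain at least one pair")
        if len(self.pairs) != len(self.coefficients):
            raise DataFormatError("pairs and coefficients length mismatch")
        if np.any(self.coefficients == 0) or not np.isfinite(self.coefficients).all():
            raise DataFormatError("all coefficients must be nonzero and finite")
        for hi, lo in self.pairs:
            if hi == lo:
                raise DataFormatError(f"degenerate pair {hi}|{lo}")
        if self.cutoff is not None and not np.isfinite(self.cutoff):
            raise DataFormatError("cutoff must be finite")

    @property
    def pair_ids(self) -> list[str]:
        return [f"{hi}|{lo}" for hi, lo in self.pairs]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise DataFormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def read_expression(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes × samples expression table.

    First column holds gene symbols, header row holds sample ids, body is
    numeric.  Duplicate gene symbols are collapsed by keeping the row with
    the largest median absolute deviation (ties → first occurrence).
    Non-numeric cells and duplicate sample ids are format errors.
    """
    sep = _sep(dialect)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen = set()
    for sample in header:  # pandas silently renames duplicate columns
        if sample in seen:
            raise DataFormatError(f"duplicate sample id {sample!r} in {path}")
        seen.add(sample)
    df = pd.read_csv(path, sep=sep, index_col=0, na_filter=False)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        gene, sample = df.index[rows[0]], df.columns[cols[0]]
        raise DataFormatError(
            f"non-numeric value {df.iat[rows[0], cols[0]]!r} at gene {gene!r}, "
            f"sample {sample!r} in {path}"
        )
    numeric.index = numeric.index.astype(str)
    if numeric.index.duplicated().any():
        keep_rows = []
        for gene, block in numeric.groupby(level=0, sort=False):
            if len(block) == 1:
                keep_rows.append(block.iloc[0])
            else:
                mads = [_mad(block.iloc[i].to_numpy(dtype=float)) for i in range(len(block))]
                best = int(np.argmax(mads))  # argmax keeps first occurrence on ties
                keep_rows.append(block.iloc[best])
                logger.info("collapsed %d duplicate rows for gene %s (kept max-MAD row)",
                            len(block), gene)
        numeric = pd.DataFrame(keep_rows)
    return ExpressionMatrix(numeric.astype(float))


def write_expression(matrix: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    matrix.data.to_csv(path, sep=_sep(dialect), index_label="gene")


def normalize_stage(token) -> str | None:
    """Normalize a tumor-stage token to I/II/III/IV; unknown → None.

    Sub-letters are stripped ("Stage IIIA" → "III"); arabic 1–4 accepted.
    """
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip().upper()
    s = re.sub(r"^STAGE\s*", "", s)
    if s in {"1", "2", "3", "4"}:
        return _STAGE_ORDER[int(s) - 1]
    m = re.match(r"^(IV|III|II|I)[A-C]?$", s)
    if m:
        return m.group(1)
    return None


def normalize_grade(token) -> str | None:
    """Normalize a histologic grade token to G1–G4; unknown → None."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip().upper().replace("GRADE", "").replace(" ", "")
    if s in {"1", "2", "3", "4"}:
        return f"G{s}"
    if re.match(r"^G[1-4]$", s):
        return s
    if s in {"I", "II", "III", "IV"}:
        return _GRADE_ORDER[_STAGE_ORDER.index(s)]
    return None


def read_clinical(path, dialect: str = "tsv", time_unit: str = "unspecified") -> ClinicalTable:
    """Read a clinical table with columns sample_id, os_time, os_event.

    Rows with os_time ≤ 0 or missing os_event are dropped with a logged
    count; os_event outside {0, 1} is a format error; stage/grade tokens are
    normalized, unknown tokens becoming missing.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise DataFormatError(f"clinical file {path} missing mandatory column {col!r}")
    df["os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    event = pd.to_numeric(df["os_event"], errors="coerce")
    bad_event = event.dropna()[~event.dropna().isin((0, 1))]
    if len(bad_event):
        raise DataFormatError(
            f"os_event must be 0 or 1; found {bad_event.iloc[0]!r} in {path}")
    keep = df["os_time"].notna() & (df["os_time"] > 0) & event.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_clinical: dropped %d record(s) with os_time <= 0 or missing os_event",
                    dropped)
    df = df.loc[keep].copy()
    df["os_event"] = event[keep].astype(int)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataFormatError(f"duplicate sample id {dup!r} in {path}")
    for col, fn in (("stage", normalize_stage), ("grade", normalize_grade)):
        if col in df.columns:
            norm = df[col].map(fn)
            unknown = int(df[col].notna().sum() - norm.notna().sum())
            if unknown:
                logger.info("read_clinical: %d unrecognized %s token(s) set to missing",
                            unknown, col)
            df[col] = norm
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df, time_unit=time_unit)


def write_clinical(table: ClinicalTable, path, dialect: str = "tsv") -> None:
    table.data.to_csv(path, sep=_sep(dialect), index_label="sample_id")


def read_gene_list(path) -> GeneList:
    """Read a gene list, one symbol per line; ``#`` starts a comment."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if not symbols:
        raise DataFormatError(f"gene list {path} contains no symbols")
    return GeneList.from_iterable(symbols)


def write_gene_list(genes: GeneList, path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in genes.symbols))


def write_signature(model: SignatureModel, path) -> None:
    """Serialize a signature model as JSON (schema-versioned, lossless)."""
    payload = {
        "schema_version": _SIGNATURE_SCHEMA_VERSION,
        "pairs": [[hi, lo] for hi, lo in model.pairs],
        "coefficients": [float(c) for c in model.coefficients],
        "cutoff": None if model.cutoff is None else float(model.cutoff),
        "horizon": None if model.horizon is None else float(model.horizon),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_signature(path) -> SignatureModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"signature file {path} is not valid JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != _SIGNATURE_SCHEMA_VERSION:
        raise DataFormatError(
            f"unknown signature schema version {version!r} in {path} "
            f"(expected {_SIGNATURE_SCHEMA_VERSION})")
    return SignatureModel(
        pairs=[(hi, lo) for hi, lo in payload["pairs"]],
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        cutoff=payload.get("cutoff"),
        horizon=payload.get("horizon"),
        provenance=payload.get("provenance", {}),
    )


def signature_models_equal(a: SignatureModel, b: SignatureModel, sig_digits: int = 12) -> bool:
    """Field-for-field equality with reals compared to ``sig_digits`` significant digits."""
    def close(x, y):
        if x is None or y is None:
            return x is None and y is None
        return np.isclose(x, y, rtol=10 ** (1 - sig_digits), atol=0.0)

    return (
        a.pairs == b.pairs
        and len(a.coefficients) == len(b.coefficients)
        and all(close(x, y) for x, y in zip(a.coefficients, b.coefficients))
        and close(a.cutoff, b.cutoff)
        and close(a.horizon, b.horizon)
        and a.provenance == b.provenance
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_samples(expr: ExpressionMatrix, clinical: ClinicalTable
                  ) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Join an expression matrix and a clinical table on shared samples.

    The intersection is ordered by the expression matrix's sample order.
    """
    clin_ids = set(clinical.sample_ids)
    shared = [s for s in expr.sample_ids if s in clin_ids]
    if not shared:
        raise DomainError("expression matrix and clinical table share no samples")
    return ExpressionMatrix(expr.data[shared]), clinical.subset(shared)


def packaged_gene_list() -> GeneList:
    """The packaged 127-gene autophagy candidate list (human gene symbols)."""
    return read_gene_list(Path(__file__).parent / "data" / "autophagy_genes.txt")
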