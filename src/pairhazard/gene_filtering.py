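"""Candidate-gene filtering: presence in both cohorts and MAD variability.

Genes from the candidate list are retained only if they are measured in both
cohorts and show a median absolute deviation (MAD) at or above the threshold
in each cohort separately; near-constant genes cannot produce informative
within-patient comparisons.  The MAD here is the bare robust spread
``median(|x - median(x)|)`` with no normal-consistency factor (1.4826): the
threshold is an empirical variability floor, not a robust standard-deviation
estimate.  A consistency factor can be folded into ``mad_threshold`` by the
caller if desired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import ExpressionMatrix, GeneList
from .errors import DomainError, NoSignalError


def mad(values) -> float:
    """Unscaled median absolute deviation, ``median(|x - median(x)|)``.

    Even-length medians use the midpoint convention.  Empty input is a
    domain error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("mad of an empty vector is undefined")
    if not np.isfinite(x).all():
        raise DomainError("mad requires finite values")
    return float(np.median(np.abs(x - np.median(x))))


@dataclass
class FilterReport:
    """Outcome of candidate-gene filtering, with per-gene reasons."""

    input_count: int
    absent_in_cohort1: list[str]
    absent_in_cohort2: list[str]
    low_mad_in_cohort1: list[str]
    low_mad_in_cohort2: list[str]
    retained: GeneList
    mad_threshold: float
    #: per-gene MAD values (NaN where the gene is absent from a cohort)
    mad_values: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Per-gene status table (gene, status, mad_cohort1, mad_cohort2)."""
        rows = []
        retained = set(self.retained.symbols)
        for gene in self.mad_values.index:
            if gene in retained:
                status = "retained"
            elif gene in self.absent_in_cohort1 or gene in self.absent_in_cohort2:
                status = "absent"
            else:
                status = "low_mad"
            rows.append((gene, status,
                         self.mad_values.at[gene, "mad_cohort1"],
                         self.mad_values.at[gene, "mad_cohort2"]))
        return pd.DataFrame(rows, columns=["gene", "status", "mad_cohort1", "mad_cohort2"])


def filter_genes(candidates: GeneList, cohort1: ExpressionMatrix,
                 cohort2: ExpressionMatrix, mad_threshold: float = 0.5) -> FilterReport:
    """Retain candidates present in both cohorts with MAD ≥ threshold in each.

    The retained list preserves candidate order.  Genes absent from a cohort
    are reported separately from genes removed for low MAD; a gene can appear
    in both cohorts' low-MAD lists.  An empty retained set raises
    :class:`NoSignalError` since no downstream stage can proceed.

    Single-cohort filtering is the degenerate case of passing the same
    matrix twice.
    """
    if mad_threshold < 0:
        raise DomainError(f"mad_threshold must be >= 0, got {mad_threshold}")
    genes1, genes2 = set(cohort1.gene_ids), set(cohort2.gene_ids)
    absent1 = [g for g in candidates if g not in genes1]
    absent2 = [g for g in candidates if g not in genes2]
    absent = set(absent1) | set(absent2)

    mad_values = pd.DataFrame(
        index=list(candidates.symbols), columns=["mad_cohort1", "mad_cohort2"], dtype=float)
    low1, low2, retained = [], [], []
    for gene in candidates:
        m1 = mad(cohort1.data.loc[gene].to_numpy()) if gene in genes1 else np.nan
        m2 = mad(cohort2.data.loc[gene].to_numpy()) if gene in genes2 else np.nan
        mad_values.loc[gene] = (m1, m2)
        if gene in absent:
            continue
        ok1, ok2 = m1 >= mad_threshold, m2 >= mad_threshold
        if not ok1:
            low1.append(gene)
        if not ok2:
            low2.append(gene)
        if ok1 and ok2:
            retained.append(gene)

    if not retained:
        raise NoSignalError(
            f"no genes survive filtering (threshold {mad_threshold}, "
            f"{len(candidates)} candidates)")
    return FilterReport(
        input_count=len(candidates),
        absent_in_cohort1=absent1, absent_in_cohort2=absent2,
        low_mad_in_cohort1=low1, low_mad_in_cohort2=low2,
        retained=GeneList(tuple(retained)),
        mad_threshold=mad_threshold, mad_values=mad_values)
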