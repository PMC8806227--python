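"""Reference-based immune-cell-fraction estimation and downstream comparisons.

Bulk expression is modeled as a non-negative mixture of cell-type reference
profiles.  Each sample's column is regressed on the reference matrix by
non-negative least squares over the genes shared between bulk and reference,
and the solution is rescaled to the unit simplex.  This is the deconvolution
*contract* — constrained reference regression plus a permutation p-value —
implemented with the simplest well-posed estimator (NNLS); an SVR-style
estimator can be plugged in by replacing :func:`_nnls_fractions`.

Significance follows the standard permutation scheme: the test statistic is
the Pearson correlation between the reconstructed and the observed bulk
vector, and the p-value is the add-one Monte-Carlo tail over gene-label
permutations of the bulk vector, so ``perm_p`` is never exactly zero.

Group comparison uses per-cell-type Welch t-tests with no multiplicity
correction (mirroring the starred-p convention of immune-infiltration
reports); a Benjamini–Hochberg-adjusted column is emitted alongside.
Score–fraction association uses Pearson (default) or Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .data_model_io import ExpressionMatrix
from .errors import AlignmentError, DataFormatError, DomainError
from .signature_builder import RiskProfile


@dataclass
class SignatureMatrix:
    """Genes × cell-types reference expression profiles (non-negative)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise DataFormatError("duplicate genes in reference matrix")
        if self.data.columns.duplicated().any():
            raise DataFormatError("duplicate cell types in reference matrix")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise DataFormatError("reference profiles must be finite and non-negative")
        if (values.sum(axis=0) == 0).any():
            raise DataFormatError("every reference column must be non-zero")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DeconvolutionResult:
    """Cell-type fractions for one sample, with permutation significance."""

    sample_id: str
    fractions: pd.Series  # indexed by cell type; >= 0, sums to 1
    perm_p: float
    fit_correlation: float
    note: str = ""


def read_reference(path, dialect: str = "tsv") -> SignatureMatrix:
    sep = "\t" if dialect == "tsv" else ","
    return SignatureMatrix(pd.read_csv(path, sep=sep, index_col=0).astype(float))


def packaged_reference() -> SignatureMatrix:
    """The packaged synthetic 50-gene × 6-cell-type reference fixture.

    A marker-block toy reference (each cell type over-expresses its own
    marker genes), generated synthetically for tests and demonstrations; it
    is not derived from any published immune signature matrix.
    """
    return read_reference(Path(__file__).parent / "data" / "immune_reference_synthetic.tsv")


def _nnls_fractions(R: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, bool]:
    """NNLS coefficients rescaled to the simplex; flag True when all-zero."""
    x, _ = nnls(R, b)
    total = x.sum()
    if total <= 0:
        return np.full(R.shape[1], 1.0 / R.shape[1]), True
    return x / total, False


def _fit_corr(R: np.ndarray, x_raw: np.ndarray, b: np.ndarray) -> float:
    recon = R @ x_raw
    if np.ptp(recon) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(recon, b)[0, 1])


def deconvolve(bulk: ExpressionMatrix, reference: SignatureMatrix,
               n_perm: int = 1000, seed: int = 0) -> list[DeconvolutionResult]:
    """Estimate cell-type fractions for every bulk sample.

    Restricted to genes shared between bulk and reference (aligned by gene
    id, not position; at least 2 required).  Fractions are NNLS coefficients
    rescaled to sum to one; an all-zero NNLS solution falls back to uniform
    fractions with a note.  ``perm_p`` is the add-one fraction of ``n_perm``
    gene-label permutations whose reconstruction correlation reaches the
    observed one.  Fixed seed → exactly reproducible.
    """
    if n_perm < 0:
        raise DomainError("n_perm must be >= 0")
    shared = [g for g in reference.gene_ids if g in set(bulk.gene_ids)]
    if len(shared) < 2:
        raise AlignmentError(
            f"bulk and reference share only {len(shared)} gene(s); need at least 2")
    R = reference.data.loc[shared].to_numpy(dtype=float)
    B = bulk.data.loc[shared].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    results = []
    for s, sample in enumerate(bulk.sample_ids):
        b = B[:, s]
        x, _ = nnls(R, b)
        fractions, degenerate = _nnls_fractions(R, b)
        observed = _fit_corr(R, x, b)
        exceed = 0
        for _ in range(n_perm):
            bp = rng.permutation(b)
            xp, _ = nnls(R, bp)
            if _fit_corr(R, xp, bp) >= observed:
                exceed += 1
        perm_p = (exceed + 1) / (n_perm + 1)
        results.append(DeconvolutionResult(
            sample_id=sample,
            fractions=pd.Series(fractions, index=reference.cell_types),
            perm_p=float(perm_p),
            fit_correlation=observed,
            note="all-zero NNLS solution; uniform fractions" if degenerate else ""))
    return results


def results_to_frame(results: list[DeconvolutionResult]) -> pd.DataFrame:
    frame = pd.DataFrame({r.sample_id: r.fractions for r in results}).T
    frame.index.name = "sample_id"
    frame["perm_p"] = [r.perm_p for r in results]
    frame["fit_correlation"] = [r.fit_correlation for r in results]
    return frame


def _split_groups(results: list[DeconvolutionResult], profiles: list[RiskProfile]):
    group_of = {p.sample_id: p.group for p in profiles}
    high = [r for r in results if group_of.get(r.sample_id) == "high"]
    low = [r for r in results if group_of.get(r.sample_id) == "low"]
    return high, low


def compare_groups(results: list[DeconvolutionResult],
                   profiles: list[RiskProfile]) -> pd.DataFrame:
    """Welch t-test of each cell type's fractions, high- vs low-risk group.

    Output is sorted by ascending p; raw p-values are reported (the
    ``p_bh`` column carries Benjamini–Hochberg adjustment for reference).
    """
    high, low = _split_groups(results, profiles)
    if len(high) < 2 or len(low) < 2:
        raise DomainError(
            f"compare_groups needs >= 2 samples per group "
            f"(high: {len(high)}, low: {len(low)})")
    H = pd.DataFrame({r.sample_id: r.fractions for r in high}).T
    L = pd.DataFrame({r.sample_id: r.fractions for r in low}).T
    rows = []
    for ct in H.columns:
        t, p = stats.ttest_ind(H[ct], L[ct], equal_var=False)
        rows.append((ct, H[ct].mean(), L[ct].mean(), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["cell_type", "mean_high", "mean_low",
                                      "t_statistic", "p_value"])
    out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def correlate_with_score(results: list[DeconvolutionResult],
                         profiles: list[RiskProfile],
                         method: str = "pearson") -> pd.DataFrame:
    """Correlation of each cell type's fraction with the risk score."""
    if method not in ("pearson", "spearman"):
        raise DomainError(f"method must be 'pearson' or 'spearman', got {method!r}")
    score_of = {p.sample_id: p.risk_score for p in profiles}
    paired = [r for r in results if r.sample_id in score_of]
    if len(paired) < 3:
        raise DomainError("correlate_with_score needs >= 3 paired observations")
    scores = np.array([score_of[r.sample_id] for r in paired])
    F = pd.DataFrame({r.sample_id: r.fractions for r in paired}).T
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for ct in F.columns:
        x = F[ct].to_numpy()
        if np.ptp(x) == 0 or np.ptp(scores) == 0:
            rows.append((ct, np.nan, np.nan, "constant vector; correlation undefined"))
        else:
            r = corr(x, scores)
            rows.append((ct, float(r.statistic), float(r.pvalue), ""))
    return pd.DataFrame(rows, columns=["cell_type", "r", "p_value", "note"])


def synthetic_reference(n_genes: int = 50, n_cell_types: int = 6,
                        seed: int = 7) -> SignatureMatrix:
    """Generate a marker-block synthetic reference matrix.

    Each cell type gets an exclusive block of marker genes expressed ~10×
    above the shared background, making mixtures identifiable.  This is the
    generator behind the packaged fixture.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 2.0, size=(n_genes, n_cell_types))
    block = n_genes // n_cell_types
    for ct in range(n_cell_types):
        rows = slice(ct * block, (ct + 1) * block)
        base[rows, ct] += rng.uniform(8.0, 15.0, size=block)
    genes = [f"MKR{i:03d}" for i in range(n_genes)]
    types = [f"CellType{chr(ord('A') + i)}" for i in range(n_cell_types)]
    return SignatureMatrix(pd.DataFrame(np.round(base, 4), index=genes, columns=types))
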