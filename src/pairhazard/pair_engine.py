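"""Binary within-patient gene-pair scoring.

For an ordered pair (a, b) and a patient s, the pair score is 1 when gene a
is expressed strictly above gene b in that patient, else 0.  The score
depends only on the within-sample ordering of expression values, so it is
invariant to any per-sample strictly increasing transform — platform scale,
library-size and monotone batch effects drop out without normalization.
Ties score 0 ("strictly above" is the rule); on continuous expression data
ties are measure-zero, and a ``tie_policy="drop-pair"`` alternative removes
any pair that ties in any sample.

All unordered combinations of the k filtered genes are enumerated once in
list order (i < j), giving k(k−1)/2 pairs; the reversed orientation carries
no extra information since score(a,b) + score(b,a) = 1 off ties.  Pairs that
are near-constant across patients (score-1 frequency outside a configurable
band in either cohort) are dropped as uninformative candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import ExpressionMatrix, GeneList
from .errors import AlignmentError, DomainError

TiePolicy = str  # {"zero", "drop-pair"}


@dataclass(frozen=True)
class GenePair:
    """Ordered gene pair; scores 1 when ``gene_hi`` > ``gene_lo`` within a patient."""

    gene_hi: str
    gene_lo: str

    def __post_init__(self) -> None:
        if self.gene_hi == self.gene_lo:
            raise DomainError(f"degenerate pair {self.gene_hi}|{self.gene_lo}")

    @property
    def pair_id(self) -> str:
        return f"{self.gene_hi}|{self.gene_lo}"


@dataclass
class PairScoreMatrix:
    """Binary pairs × samples score matrix."""

    pairs: list[GenePair]
    sample_ids: list[str]
    scores: np.ndarray  # uint8, shape (n_pairs, n_samples)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (len(self.pairs), len(self.sample_ids)):
            raise DomainError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples")
        if not np.isin(self.scores, (0, 1)).all():
            raise DomainError("pair scores must be 0 or 1")
        self.scores = self.scores.astype(np.uint8)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.pair_ids, columns=self.sample_ids)

    def frequencies(self) -> np.ndarray:
        """Per-pair score-1 frequency across samples."""
        return self.scores.mean(axis=1)

    def subset(self, pairs: list[GenePair]) -> "PairScoreMatrix":
        index = {p: i for i, p in enumerate(self.pairs)}
        missing = [p.pair_id for p in pairs if p not in index]
        if missing:
            raise AlignmentError(f"pairs not present in score matrix: {missing[:5]}")
        rows = [index[p] for p in pairs]
        return PairScoreMatrix(list(pairs), list(self.sample_ids), self.scores[rows])


def pair_score(expr_hi: float, expr_lo: float) -> int:
    """1 iff ``expr_hi`` strictly exceeds ``expr_lo``; ties score 0."""
    if not (np.isfinite(expr_hi) and np.isfinite(expr_lo)):
        raise DomainError("pair_score requires finite expression values")
    return int(expr_hi > expr_lo)


def build_pair_matrix(genes: GeneList, expr: ExpressionMatrix,
                      tie_policy: TiePolicy = "zero") -> PairScoreMatrix:
    """Score every unordered gene combination in every sample.

    Pairs are enumerated in candidate-list order as (gene_i, gene_j) for
    i < j.  ``tie_policy="drop-pair"`` removes pairs with an expression tie
    in any sample; the default scores ties 0.
    """
    if tie_policy not in ("zero", "drop-pair"):
        raise DomainError(f"unknown tie_policy {tie_policy!r}")
    if len(genes) < 2:
        raise DomainError("at least two genes are required to form pairs")
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise AlignmentError(f"genes missing from expression matrix: {missing[:5]}")

    X = expr.data.loc[list(genes.symbols)].to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(genes), k=1)  # row-major (i<j) order
    scores = (X[ii] > X[jj]).astype(np.uint8)
    pairs = [GenePair(genes.symbols[i], genes.symbols[j]) for i, j in zip(ii, jj)]
    if tie_policy == "drop-pair":
        tied = (X[ii] == X[jj]).any(axis=1)
        pairs = [p for p, t in zip(pairs, tied) if not t]
        scores = scores[~tied]
    return PairScoreMatrix(pairs, list(expr.sample_ids), scores)


def write_pair_matrix(matrix: PairScoreMatrix, path) -> None:
    """Write a pair-score matrix as TSV, pair ids ("A|B") as rows."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="pair")


def read_pair_matrix(path) -> PairScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    pairs = []
    for pid in df.index:
        parts = str(pid).split("|")
        if len(parts) != 2:
            raise DomainError(f"malformed pair id {pid!r} in {path}")
        pairs.append(GenePair(parts[0], parts[1]))
    return PairScoreMatrix(pairs, [str(c) for c in df.columns],
                           df.to_numpy())


def select_candidate_pairs(m1: PairScoreMatrix, m2: PairScoreMatrix,
                           min_freq: float = 0.2, max_freq: float = 0.8) -> list[GenePair]:
    """Keep pairs whose score-1 frequency lies in [min_freq, max_freq] in both cohorts.

    Both endpoints are inclusive; pair order is preserved.  The two matrices
    must be over the identical pair list.
    """
    if not (0 <= min_freq < max_freq <= 1):
        raise DomainError(f"invalid frequency band [{min_freq}, {max_freq}]")
    if m1.pairs != m2.pairs:
        raise AlignmentError("pair lists of the two cohorts differ")
    f1, f2 = m1.frequencies(), m2.frequencies()
    keep = (f1 >= min_freq) & (f1 <= max_freq) & (f2 >= min_freq) & (f2 <= max_freq)
    return [p for p, k in zip(m1.pairs, keep) if k]
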