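"""Module co-expression scoring and significance.

The co-expression of a module is the mean Pearson correlation (PCC)
over all unordered gene pairs.  Significance comes in two flavors:

* a genome permutation test -- draw random gene sets of the same size
  and count how often their mean PCC exceeds the observed one (1000
  draws by default);
* Fisher's combined probability test against an empirical pairwise null
  (10,000 random gene pairs by default), for settings where running the
  permutation test per module is too expensive.

Testing is one-sided in the upper tail throughout: the question asked
is whether module genes are *positively* co-expressed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with no missing entries."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    _zscores: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ExpressionError("value grid does not match gene/sample labels")
        if len(self.samples) < 3:
            raise ExpressionError("need at least 3 samples for correlation")
        if np.isnan(self.values).any():
            raise ExpressionError("missing values are not allowed; filter rows first")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    @classmethod
    def read_tsv(cls, path: str | Path, sep: str | None = None) -> "ExpressionMatrix":
        """Load a genes x samples table with a header row and gene-id column."""
        path = Path(path)
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)]
            raise ExpressionError(
                f"{path}: {len(bad)} gene row(s) contain missing values "
                f"(e.g. {bad[0]!r}); remove or filter them"
            )
        return cls.from_dataframe(df)

    def zscores(self) -> np.ndarray:
        """Rows standardized to zero mean, unit norm (NaN for constant genes)."""
        if self._zscores is None:
            centered = self.values - self.values.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(centered, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                self._zscores = centered / norms
        return self._zscores

    def pcc(self, gene_a: str, gene_b: str) -> float:
        z = self.zscores()
        return float(z[self._index[gene_a]] @ z[self._index[gene_b]])


@dataclass
class CoexpressionResult:
    module_id: int | None
    mean_pcc: float
    p_value: float
    method: str  # "permutation" or "fisher"
    n_pairs: int
    n_genes: int


def _present_genes(expr: ExpressionMatrix, genes) -> list[str]:
    present = [g for g in genes if g in expr._index]
    missing = len(list(genes)) - len(present)
    if missing:
        logger.info("%d module gene(s) absent from the expression matrix", missing)
    return present


def _mean_pairwise_pcc(z: np.ndarray, idx: np.ndarray) -> float:
    """Mean off-diagonal correlation among the (standardized) rows idx."""
    sub = z[idx]
    corr = sub @ sub.T
    k = len(idx)
    return float((corr.sum() - np.trace(corr)) / (k * (k - 1)))


def module_mean_pcc(expr: ExpressionMatrix, genes) -> float:
    """Signed mean Pearson correlation over all unordered gene pairs."""
    present = _present_genes(expr, genes)
    if len(present) < 2:
        raise ExpressionError("fewer than 2 module genes present in the matrix")
    z = expr.zscores()
    idx = np.array([expr._index[g] for g in present])
    constant = np.isnan(z[idx]).any(axis=1)
    if constant.any():
        logger.warning(
            "%d constant expression vector(s) excluded from mean PCC", constant.sum()
        )
        idx = idx[~constant]
        if len(idx) < 2:
            raise ExpressionError("fewer than 2 non-constant module genes")
    return _mean_pairwise_pcc(z, idx)


def permutation_pvalue(
    expr: ExpressionMatrix,
    genes,
    n_perm: int = 1000,
    seed: int | None = None,
    strict_greater: bool = True,
    module_id: int | None = None,
) -> CoexpressionResult:
    """Genome permutation test on the module's mean PCC.

    ``p = #(random mean PCC > observed) / n_perm`` (strict inequality;
    pass ``strict_greater=False`` for the conservative >= variant).
    Random sets are drawn from all non-constant genes in the matrix,
    module genes included.
    """
    present = _present_genes(expr, genes)
    observed = module_mean_pcc(expr, present)
    z = expr.zscores()
    usable = np.flatnonzero(~np.isnan(z).any(axis=1))
    k = len(present)
    if len(usable) <= k:
        raise ExpressionError("matrix must contain more genes than the module")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(usable, size=k, replace=False)
        random_mean = _mean_pairwise_pcc(z, idx)
        if (random_mean > observed) if strict_greater else (random_mean >= observed):
            exceed += 1
    return CoexpressionResult(
        module_id=module_id,
        mean_pcc=observed,
        p_value=exceed / n_perm,
        method="permutation",
        n_pairs=k * (k - 1) // 2,
        n_genes=k,
    )


@dataclass
class EmpiricalPairNull:
    """Sorted sample of pairwise PCCs from random gene pairs."""

    values: np.ndarray  # ascending
    n_draws: int

    def p_value(self, observed_pcc: float) -> float:
        """Guarded upper-tail p: (count >= observed + 1) / (n + 1).

        The +1 guard keeps p strictly positive so downstream logs in
        Fisher's method stay finite.
        """
        count_ge = self.n_draws - int(np.searchsorted(self.values, observed_pcc, "left"))
        return (count_ge + 1) / (self.n_draws + 1)


def empirical_pair_null(
    expr: ExpressionMatrix,
    n_draws: int = 10000,
    seed: int | None = None,
) -> EmpiricalPairNull:
    """Null distribution of the PCC of random gene pairs from the matrix."""
    z = expr.zscores()
    usable = np.flatnonzero(~np.isnan(z).any(axis=1))
    if len(usable) < 2:
        raise ExpressionError("need at least 2 non-constant genes")
    rng = np.random.default_rng(seed)
    first = rng.integers(0, len(usable), size=n_draws)
    second = rng.integers(0, len(usable) - 1, size=n_draws)
    second = np.where(second >= first, second + 1, second)  # distinct partner
    i, j = usable[first], usable[second]
    pccs = np.einsum("ij,ij->i", z[i], z[j])
    return EmpiricalPairNull(np.sort(pccs), n_draws)


def fisher_combined_pvalue(pvalues) -> float:
    """Fisher's method: -2 * sum(ln p) ~ chi-squared with 2k d.o.f."""
    pvalues = list(pvalues)
    if not pvalues:
        raise ValueError("need at least one p-value")
    for p in pvalues:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    statistic = -2.0 * sum(math.log(p) for p in pvalues)
    return float(stats.chi2.sf(statistic, df=2 * len(pvalues)))


def module_fisher_pvalue(
    expr: ExpressionMatrix,
    genes,
    null: EmpiricalPairNull,
    module_id: int | None = None,
) -> CoexpressionResult:
    """Combine per-pair empirical upper-tail p-values by Fisher's method."""
    present = _present_genes(expr, genes)
    if len(present) < 2:
        raise ExpressionError("fewer than 2 module genes present in the matrix")
    z = expr.zscores()
    idx = [expr._index[g] for g in present if not np.isnan(z[expr._index[g]]).any()]
    if len(idx) < 2:
        raise ExpressionError("fewer than 2 non-constant module genes")
    pccs = [float(z[i] @ z[j]) for i, j in itertools.combinations(idx, 2)]
    pvals = [null.p_value(r) for r in pccs]
    return CoexpressionResult(
        module_id=module_id,
        mean_pcc=float(np.mean(pccs)),
        p_value=fisher_combined_pvalue(pvals),
        method="fisher",
        n_pairs=len(pccs),
        n_genes=len(idx),
    )
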