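"""Identification of lncRNA expression-correlated genes (LCGs).

For each lncRNA, every mRNA is regressed on the lncRNA's expression with an
ordinary univariate linear model; genes whose two-sided slope t-test falls
below a fixed significance level (default 1e-10, a Bonferroni-scale cutoff
for transcriptome-wide screens) form the lncRNA's LCG set. The slope t-test
is numerically identical to the Pearson correlation t-test, which is what the
vectorized screen exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger("lfsn")

DEFAULT_ALPHA_LCG = 1e-10


@dataclass(frozen=True)
class RegressionStat:
    lnc_id: str
    gene_id: str
    slope: float
    t_stat: float
    p_value: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass
class LCGSet:
    lnc_id: str
    genes: frozenset[str]
    alpha: float


def regress(x: np.ndarray, y: np.ndarray,
            lnc_id: str = "x", gene_id: str = "y") -> RegressionStat:
    """OLS regression of y on x with a two-sided t-test on the slope.

    A constant x or y admits no association test; by convention the result
    carries p = 1 and is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    sx = x - x.mean()
    sy = y - y.mean()
    ssx = float(sx @ sx)
    ssy = float(sy @ sy)
    if ssx == 0.0 or ssy == 0.0:
        return RegressionStat(lnc_id, gene_id, 0.0, 0.0, 1.0, n, degenerate=True)
    sxy = float(sx @ sy)
    slope = sxy / ssx
    r2 = sxy * sxy / (ssx * ssy)
    df = n - 2
    if r2 >= 1.0:
        return RegressionStat(lnc_id, gene_id, slope, np.inf, 0.0, n)
    t = np.sign(sxy) * np.sqrt(r2 * df / (1.0 - r2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return RegressionStat(lnc_id, gene_id, slope, float(t), min(float(p), 1.0), n)


def _check_samples(lnc_expr: ExpressionMatrix, gene_expr: ExpressionMatrix) -> None:
    if lnc_expr.sample_ids != gene_expr.sample_ids:
        only_lnc = set(lnc_expr.sample_ids) - set(gene_expr.sample_ids)
        only_gene = set(gene_expr.sample_ids) - set(lnc_expr.sample_ids)
        if only_lnc or only_gene:
            raise ValueError(
                "sample sets differ between matrices: "
                f"only in lncRNA matrix {sorted(only_lnc)}; "
                f"only in gene matrix {sorted(only_gene)}"
            )
        raise ValueError("sample ordering differs between lncRNA and gene matrices")


def _pvalue_matrix(lnc_expr: ExpressionMatrix, gene_expr: ExpressionMatrix) -> np.ndarray:
    """Two-sided slope-test p-values for every lncRNA x gene combination.

    Constant rows (zero variance) get p = 1 by the degenerate convention.
    """
    n = lnc_expr.n_samples
    X = lnc_expr.values - lnc_expr.values.mean(axis=1, keepdims=True)
    Y = gene_expr.values - gene_expr.values.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((X * X).sum(axis=1))
    ynorm = np.sqrt((Y * Y).sum(axis=1))
    const_x = xnorm == 0
    const_y = ynorm == 0
    xnorm[const_x] = 1.0
    ynorm[const_y] = 1.0
    r = (X / xnorm[:, None]) @ (Y / ynorm[:, None]).T
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(t, df)
    p = np.minimum(p, 1.0)
    p[np.isnan(p)] = 0.0  # |r| == 1 -> t = inf -> p = 0
    p[const_x, :] = 1.0
    p[:, const_y] = 1.0
    return p


def identify_lcgs(
    lnc_id: str,
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA_LCG,
) -> LCGSet:
    """All genes whose regression on the given lncRNA has p strictly below
    alpha. The two matrices must share identically ordered samples."""
    _check_samples(lnc_expr, gene_expr)
    sub = lnc_expr.subset([lnc_id])
    p = _pvalue_matrix(sub, gene_expr)[0]
    genes = frozenset(g for g, pv in zip(gene_expr.entity_ids, p) if pv < alpha)
    return LCGSet(lnc_id, genes, alpha)


def all_lcgs(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA_LCG,
) -> dict[str, LCGSet]:
    """Vectorized LCG screen over every lncRNA at once."""
    _check_samples(lnc_expr, gene_expr)
    p = _pvalue_matrix(lnc_expr, gene_expr)
    gene_ids = np.asarray(gene_expr.entity_ids, dtype=object)
    out: dict[str, LCGSet] = {}
    for i, lnc in enumerate(lnc_expr.entity_ids):
        hits = gene_ids[p[i] < alpha]
        out[lnc] = LCGSet(lnc, frozenset(hits.tolist()), alpha)
    return out


def apply_confounder_filter(
    lcgs: LCGSet,
    coloc_pairs: set[tuple[str, str]],
    coreg_pairs: set[tuple[str, str]],
) -> LCGSet:
    """Remove genes co-localized with or co-regulated alongside the lncRNA.

    Pair sets are (lnc_id, gene_id) tuples from the coregulation module.
    """
    excluded = {g for (l, g) in coloc_pairs | coreg_pairs if l == lcgs.lnc_id}
    kept = lcgs.genes - excluded
    n_removed = len(lcgs.genes) - len(kept)
    if n_removed:
        logger.info("confounder filter removed %d of %d LCGs for %s",
                    n_removed, len(lcgs.genes), lcgs.lnc_id)
    return LCGSet(lcgs.lnc_id, kept, lcgs.alpha)
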