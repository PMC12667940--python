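"""Per-gene smooth trajectory fits along pseudotime.

Each gene's normalized expression is regressed on pseudotime with a cubic
regression spline (Gaussian response).  Temporal variation is assessed with a
likelihood-ratio test of the spline model against the intercept-only model,
p-values are Benjamini-Hochberg adjusted across genes, and the fitted curves
of significant genes are scaled to mean 0 / sd 1 for switch-point analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .io import CellOrdering, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFit",
    "spline_design_matrix",
    "fit_gene_trajectory",
    "adjust_pvalues",
    "scale_fitted",
    "fit_all_genes",
]


@dataclass
class GeneFit:
    """Fitted trajectory and test results for one gene.

    ``scaled`` is populated only for genes retained after the BH filter
    (adjusted p-value below alpha); for filtered-out genes it stays ``None``.
    """

    gene_id: str
    fitted: np.ndarray
    pvalue: float
    qvalue: float = field(default=np.nan)
    scaled: np.ndarray | None = None
    retained: bool = False


def spline_design_matrix(pseudotime: np.ndarray, df: int = 3) -> np.ndarray:
    """Cubic regression-spline basis with ``df + 1`` columns (constants in span).

    For ``df >= 3`` this is a cubic B-spline basis with ``df - 3`` interior
    knots placed at quantiles of the pseudotime values; for ``df`` of 1 or 2 a
    polynomial basis of that degree is used instead.
    """
    if df < 1:
        raise ValueError("df must be a positive integer")
    t = np.asarray(pseudotime, dtype=float)
    lo, hi = t[0], t[-1]
    if hi <= lo:
        raise ValueError("pseudotime must be strictly increasing")
    x = (t - lo) / (hi - lo)
    if df < 3:
        return np.vander(x, df + 1, increasing=True)
    n_interior = df - 3
    if n_interior:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.empty(0)
    knots = np.concatenate([np.zeros(4), interior, np.ones(4)])
    design = BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
    return design


def fit_gene_trajectory(
    expr: np.ndarray, pseudotime: np.ndarray, df: int = 3
) -> tuple[np.ndarray, float]:
    """Fit one gene's smooth trajectory and test for temporal variation.

    Returns the fitted values at each pseudotime point and the p-value of the
    likelihood-ratio test (chi-square with ``df`` degrees of freedom) of the
    spline model against the intercept-only model.  A constant input yields a
    constant fit with p-value 1.
    """
    y = np.asarray(expr, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if y.shape != t.shape:
        raise ValueError("expr and pseudotime must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("expr contains non-finite values")
    n = y.size
    if n < 2 * (df + 1):
        raise ValueError(
            f"need at least {2 * (df + 1)} cells for df={df}; "
            f"got {n} -- use a smaller df"
        )
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 == 0.0:
        return np.full(n, y[0]), 1.0
    X = spline_design_matrix(t, df)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss1 = float(np.sum((y - fitted) ** 2))
    if rss1 <= rss0 * 1e-14:
        return fitted, 0.0
    stat = n * np.log(rss0 / rss1) if rss1 < rss0 else 0.0
    pvalue = float(stats.chi2.sf(stat, df))
    return fitted, pvalue


def adjust_pvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def scale_fitted(fitted: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample (n-1 denominator) sd 1."""
    v = np.asarray(fitted, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to scale")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale a zero-variance trajectory")
    return (v - v.mean()) / sd


def fit_all_genes(
    m: ExpressionMatrix,
    o: CellOrdering,
    df: int = 3,
    alpha: float = 0.05,
) -> list[GeneFit]:
    """Fit every gene, BH-adjust over all genes, scale the retained ones.

    The matrix must already be aligned to the ordering.  Genes whose fit fails
    numerically are assigned p-value 1 with a warning rather than aborting the
    run.  Retention uses a strict ``qvalue < alpha`` cut.
    """
    if list(m.cell_ids) != list(o.cell_ids):
        raise ValueError("matrix is not aligned to the ordering")
    t = np.asarray(o.pseudotime, dtype=float)
    fits: list[GeneFit] = []
    for i, gene in enumerate(m.gene_ids):
        try:
            fitted, pvalue = fit_gene_trajectory(m.values[i], t, df=df)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            logger.warning("fit failed for gene %s; assigning p-value 1", gene)
            fitted, pvalue = np.full(t.size, float(np.mean(m.values[i]))), 1.0
        fits.append(GeneFit(gene_id=gene, fitted=fitted, pvalue=pvalue))
    qvals = adjust_pvalues([f.pvalue for f in fits])
    n_retained = 0
    for f, q in zip(fits, qvals):
        f.qvalue = float(q)
        if f.qvalue < alpha and f.fitted.std(ddof=1) > 0:
            f.scaled = scale_fitted(f.fitted)
            f.retained = True
            n_retained += 1
    logger.info("retained %d / %d genes at alpha=%g", n_retained, len(fits), alpha)
    return fits
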