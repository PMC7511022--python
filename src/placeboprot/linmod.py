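"""Small linear-model core shared by the protein-level analyses.

The per-protein stages (peptide-level ANCOVA, variance dissection, GO-term
regressions) fit thousands of small ordinary-least-squares models per run, so
the fits are done directly with :func:`numpy.linalg.lstsq` rather than through
a formula interface.  Unit tests cross-check every routine here against
statsmodels (``OLS``/``anova_lm``/``RLM``) on shared inputs.

Conventions
-----------
* A *term* is a tuple of factor names, e.g. ``("das",)`` or ``("das", "grp")``.
  Its design column is the elementwise product of the named columns.
* Two-level factors are expected pre-coded as centered numeric columns
  (−0.5/+0.5); continuous predictors are used as-is.
* Type II sums of squares: the SS for term *T* compares the model of all terms
  whose factor set does not contain *T* against that model plus *T*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

Term = tuple[str, ...]


def design_matrix(
    terms: Sequence[Term], data: Mapping[str, np.ndarray], intercept: bool = True
) -> np.ndarray:
    """Build the design matrix for ``terms`` (product columns), intercept first."""
    n = len(next(iter(data.values())))
    cols = []
    if intercept:
        cols.append(np.ones(n))
    for term in terms:
        col = np.ones(n)
        for name in term:
            col = col * np.asarray(data[name], dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class OlsFit:
    beta: np.ndarray
    rss: float
    tss: float
    df_resid: int

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else np.nan


def ols(X: np.ndarray, y: np.ndarray) -> OlsFit:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return OlsFit(beta=beta, rss=float(resid @ resid), tss=tss, df_resid=len(y) - rank)


def type2_anova(
    terms: Sequence[Term],
    data: Mapping[str, np.ndarray],
    y: np.ndarray,
) -> dict[Term, dict[str, float]]:
    """Type II one-df F tests for every term of a crossed linear model.

    Returns ``{term: {"ss": ..., "F": ..., "p": ...}}``.  Residual df/MS come
    from the full model containing every term.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    X_full = design_matrix(terms, data)
    fit = ols(X_full, y)
    if fit.df_resid <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")
    mse = fit.rss / fit.df_resid
    out: dict[Term, dict[str, float]] = {}
    for term in terms:
        tset = set(term)
        # Type II: exclude every term whose factors contain this term's factors
        reduced = [t for t in terms if not tset <= set(t)]
        rss_reduced = _rss(design_matrix(reduced, data), y)
        rss_with = _rss(design_matrix(reduced + [term], data), y)
        ss = max(rss_reduced - rss_with, 0.0)
        F = ss / mse if mse > 0 else np.inf
        p = float(stats.f.sf(F, 1, fit.df_resid)) if np.isfinite(F) else 0.0
        out[term] = {"ss": ss, "F": float(F), "p": p}
    out[("__resid__",)] = {"ss": fit.rss, "F": np.nan, "p": np.nan}
    out[("__model__",)] = {"ss": fit.tss - fit.rss, "F": np.nan, "p": np.nan}
    return out


# ---------------------------------------------------------------------------
# Tukey bisquare (biweight) IRLS, used to flag and drop outliers before OLS.
# ---------------------------------------------------------------------------

BISQUARE_C = 4.685  # 95% Gaussian efficiency


def bisquare_irls(
    X: np.ndarray,
    y: np.ndarray,
    c: float = BISQUARE_C,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively reweighted least squares with the Tukey biweight.

    Returns ``(beta, weights)`` at convergence.  Scale is re-estimated each
    iteration as the normalized median absolute deviation of the residuals.
    A zero scale (half the points or more on an exact fit) returns weight 1
    for exact-fit points and 0 elsewhere.
    """
    y = np.asarray(y, dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(len(y))
    for _ in range(max_iter):
        resid = y - X @ beta
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= np.finfo(float).tiny:
            w = (np.abs(resid) <= 1e-12 * max(1.0, np.abs(y).max())).astype(float)
            break
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        Xw = X * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)
        beta_new, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    resid = y - X @ beta
    scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
    if scale > np.finfo(float).tiny:
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return beta, w


def bisquare_keep_mask(
    X: np.ndarray, y: np.ndarray, weight_cutoff: float = 0.01
) -> np.ndarray:
    """Boolean mask of observations retained after bisquare outlier flagging.

    An observation is an outlier when its converged robust weight falls below
    ``weight_cutoff``.
    """
    _, w = bisquare_irls(X, y)
    return w >= weight_cutoff
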