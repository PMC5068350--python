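"""Multivariate OLS core: Y = X B + E fit jointly over all genes.

Fitting the n x m outcome matrix against one design gives, per gene,
exactly the coefficients of a univariate multiple regression; the gene-set
estimate is the mean of the per-gene standardized focal coefficients.
The module also exposes the conditional (reduced-model residual)
correlation matrix needed by O'Brien's test and the closed-form 2x2
inverse cross-product geometry that makes coefficients of two correlated
standardized regressors negatively correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import DesignSpec, OrientedExpressionMatrix


def _values(Y) -> np.ndarray:
    return Y.values if isinstance(Y, OrientedExpressionMatrix) else np.asarray(Y, float)


@dataclass
class MultivariateFit:
    """Joint OLS fit of all genes on one design.

    B is p_total x m (p_total = q nuisance incl. intercept + d focal);
    t-values use the per-gene residual variance with df = n - p_total.
    """

    B: np.ndarray
    E: np.ndarray
    tvalues: np.ndarray
    se: np.ndarray
    rss: np.ndarray
    df_resid: int
    names: list[str]
    xtx_inv: np.ndarray

    def row(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown design column {name!r}") from None

    def coef(self, name: str) -> np.ndarray:
        return self.B[self.row(name)]

    def tvals(self, name: str) -> np.ndarray:
        return self.tvalues[self.row(name)]


@dataclass
class MeanEffect:
    """Mean standardized coefficient of a focal predictor over the gene set."""

    betabar: float
    per_gene: np.ndarray
    focal: str
    tvalues: np.ndarray | None = None


@dataclass
class ConditionalCorrelation:
    """Correlation matrix of reduced-model residual columns."""

    R: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, float)
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix is indefinite")
        self.R = R


def fit_mvlm(Y, design: DesignSpec) -> MultivariateFit:
    """Fit the multivariate linear model by QR of the full design.

    QR is used instead of the normal equations so rank deficiency among
    the (possibly many, correlated) covariates is detected rather than
    silently absorbed.
    """
    Yv = _values(Y)
    D = design.full_matrix()
    names = design.full_names()
    n, p = D.shape
    if n <= p:
        raise ValueError(f"need n > p_total, got n={n}, p_total={p}")
    Q, R = np.linalg.qr(D)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * diag.max()
    bad = [names[j] for j in np.nonzero(diag <= tol)[0]]
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    B = np.linalg.solve(R, Q.T @ Yv)
    E = Yv - D @ B
    rss = (E * E).sum(axis=0)
    df = n - p
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv = Rinv @ Rinv.T
    s2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    return MultivariateFit(B=B, E=E, tvalues=t, se=se, rss=rss, df_resid=df,
                           names=names, xtx_inv=xtx_inv)


def mean_effect(fit: MultivariateFit, focal: str) -> MeanEffect:
    """Average the focal row of B over genes (the gene-set effect)."""
    coefs = fit.coef(focal)
    return MeanEffect(betabar=float(coefs.mean()), per_gene=coefs, focal=focal,
                      tvalues=fit.tvals(focal))


def contrast_effects(fit: MultivariateFit, focal_a: str, focal_b: str) -> MeanEffect:
    """Per-gene coefficient differences beta_a - beta_b and their mean.

    t-values use the contrast variance a'(X'X)^{-1} a * s_j^2 with
    a = e_a - e_b.
    """
    if focal_a == focal_b:
        raise ValueError("contrast requires two distinct focal predictors")
    ia, ib = fit.row(focal_a), fit.row(focal_b)
    diff = fit.B[ia] - fit.B[ib]
    a = np.zeros(len(fit.names))
    a[ia], a[ib] = 1.0, -1.0
    var_unscaled = float(a @ fit.xtx_inv @ a)
    s2 = fit.rss / fit.df_resid
    se = np.sqrt(var_unscaled * s2)
    t = diff / se
    return MeanEffect(betabar=float(diff.mean()), per_gene=diff,
                      focal=f"{focal_a}-{focal_b}", tvalues=t)


def conditional_correlation(Y, design_reduced: DesignSpec) -> ConditionalCorrelation:
    """Correlation of residuals from the reduced model (focal excluded)."""
    Yv = _values(Y)
    if design_reduced.d > 0:
        raise ValueError("reduced design must not contain focal predictors")
    X = design_reduced.X
    Q, _ = np.linalg.qr(X)
    E = Yv - Q @ (Q.T @ Yv)
    sd = E.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(f"residual column(s) with zero variance: {zero.tolist()}")
    if E.shape[1] == 1:
        return ConditionalCorrelation(np.ones((1, 1)))
    return ConditionalCorrelation(np.corrcoef(E, rowvar=False))


def coefficient_geometry(r: float, n: int) -> tuple[float, float]:
    """Elements of the 2x2 inverse cross-product of two standardized regressors.

    For two regressors scaled so that x'x = n and with correlation r, the
    inverse of X'X has diagonal 1/(n(1-r^2)) and off-diagonal -r/(n(1-r^2)).
    These are the weights combining x1'y and x2'y into each partial
    coefficient; the negative off-diagonal is why highly correlated
    regressors yield negatively correlated coefficient estimates.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 (X'X singular)")
    denom = n * (1.0 - r * r)
    return 1.0 / denom, -r / denom


def obrien_statistic(tvals: np.ndarray, R: np.ndarray) -> float:
    """O'Brien's combined statistic: sum of t-values over sqrt(j'Rj)."""
    j = np.ones(len(tvals))
    denom = float(j @ R @ j)
    if denom <= 0:
        raise ValueError("j'Rj <= 0: correlation matrix is not usable")
    return float(tvals.sum() / np.sqrt(denom))


def obrien_pvalue(stat: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(stat), df))
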