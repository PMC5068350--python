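"""Gene-set tests with closed-form reference distributions.

O'Brien's OLS t-test combines the m per-gene t-values, accounting for the
conditional correlation of the outcomes; the GEE Wald test estimates the
population-averaged effect in long format with a sandwich (robust)
standard error; the legacy coefficient-bootstrap t-test is retained only
to demonstrate its anti-conservatism; and the fold-change back-transform
converts a mean log2-scale coefficient to a fold change per four
standard deviations of the predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import DesignSpec, OrientedExpressionMatrix
from .mvlm import (conditional_correlation, contrast_effects, fit_mvlm,
                   mean_effect, obrien_pvalue, obrien_statistic)

logger = logging.getLogger(__name__)


@dataclass
class GeneSetTestResult:
    method: str
    estimate: float
    se: float | None
    statistic: float
    p: float
    df: float | None = None
    n_resamples: int = 0
    converged: bool = True
    known_invalid: bool = False
    resampling_p: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if (self.resampling_p and self.n_resamples
                and self.p < 1.0 / self.n_resamples - 1e-12):
            raise ValueError("resampling p below 1/n_resamples")
        if self.se is not None and not self.se > 0:
            raise ValueError("standard error must be positive when defined")


def obrien_test(Y, design: DesignSpec, focal: str) -> GeneSetTestResult:
    """O'Brien's OLS t-test of the mean effect of ``focal`` on the set.

    t_obrien = sum(t_j) / sqrt(j'Rj), with t_j from the full-model fit and
    R the correlation of reduced-model (focal excluded) residuals.  The
    reference is a t distribution with n - p - 1 df, p counting all
    predictors except the intercept — i.e. the full-model residual df.
    """
    fit = fit_mvlm(Y, design)
    eff = mean_effect(fit, focal)
    R = conditional_correlation(Y, design.reduced(focal)).R
    stat = obrien_statistic(eff.tvalues, R)
    df = fit.df_resid  # = n - p - 1 with p predictors excluding intercept
    if stat == 0.0:
        return GeneSetTestResult("obrien", eff.betabar, None, 0.0, 1.0, df=df)
    p = obrien_pvalue(stat, df)
    se = abs(eff.betabar / stat)
    return GeneSetTestResult("obrien", eff.betabar, se if se > 0 else None,
                             stat, max(p, np.finfo(float).tiny), df=df)


def obrien_contrast_test(Y, design: DesignSpec, focal_a: str, focal_b: str
                         ) -> GeneSetTestResult:
    """O'Brien test of the difference of two focal mean effects.

    Uses contrast t-values from the full fit and the residual correlation
    of the reduced model excluding both focal predictors.
    """
    fit = fit_mvlm(Y, design)
    eff = contrast_effects(fit, focal_a, focal_b)
    keep = [j for j in range(design.d) if design.z_names[j] not in (focal_a, focal_b)]
    reduced = DesignSpec(
        X=np.hstack([design.X, design.Z[:, keep]]),
        Z=np.empty((design.n, 0)),
        x_names=list(design.x_names) + [design.z_names[j] for j in keep],
        z_names=[],
    )
    R = conditional_correlation(Y, reduced).R
    stat = obrien_statistic(eff.tvalues, R)
    df = fit.df_resid
    if stat == 0.0:
        return GeneSetTestResult("obrien_contrast", eff.betabar, None, 0.0, 1.0, df=df)
    se = abs(eff.betabar / stat)
    return GeneSetTestResult("obrien_contrast", eff.betabar,
                             se if se > 0 else None, stat,
                             max(obrien_pvalue(stat, df), np.finfo(float).tiny),
                             df=df)


def _long_format(Yv: np.ndarray, design: DesignSpec, focal: str):
    """Stack wide data to one row per (subject, gene).

    Exog columns: m gene indicators (gene-specific intercepts, absorbing
    the global intercept), then nuisance covariates, then the focal
    predictor last.  Covariates are constant within subject across genes.
    """
    n, m = Yv.shape
    k = design.focal_index(focal)
    full = design.full_matrix()
    names = design.full_names()
    covar_idx = [j for j in range(full.shape[1]) if j != k and names[j] != "intercept"]
    C = np.hstack([full[:, covar_idx], full[:, [k]]])
    endog = Yv.reshape(-1)  # subject-major: rows i*m + j
    gene_block = np.tile(np.eye(m), (n, 1))
    exog = np.hstack([gene_block, np.repeat(C, m, axis=0)])
    groups = np.repeat(np.arange(n), m)
    focal_col = exog.shape[1] - 1
    return endog, exog, groups, focal_col


def gee_test(Y, design: DesignSpec, focal: str, maxiter: int = 60
             ) -> GeneSetTestResult:
    """GEE Wald z-test of the focal effect (exchangeable working correlation).

    The identity-link Gaussian GEE on the long-format data estimates the
    same population-averaged effect as the OLS mean effect; the sandwich
    covariance clustered by subject makes the SE robust to misspecification
    of the working correlation.  p is two-sided normal.
    """
    import statsmodels.api as sm

    Yv = Y.values if isinstance(Y, OrientedExpressionMatrix) else np.asarray(Y, float)
    endog, exog, groups, kf = _long_format(Yv, design, focal)
    cov = sm.cov_struct.Exchangeable()
    model = sm.GEE(endog, exog, groups=groups, family=sm.families.Gaussian(),
                   cov_struct=cov)
    try:
        res = model.fit(maxiter=maxiter)
        converged = bool(getattr(res, "converged", True))
    except Exception as exc:  # noqa: BLE001 - surfaced via result flag
        logger.warning("GEE failed: %s", exc)
        return GeneSetTestResult("gee", np.nan, None, np.nan, 1.0,
                                 converged=False, extra={"error": str(exc)})
    est = float(res.params[kf])
    se = float(res.bse[kf])  # robust (sandwich) by default
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return GeneSetTestResult("gee", est, se, z, max(p, np.finfo(float).tiny),
                             converged=converged,
                             extra={"alpha_exch": float(cov.dep_params)})


def fredrickson_t(Y, design: DesignSpec, focal: str, n_boot: int = 10_000,
                  seed: int | np.random.Generator | None = None
                  ) -> GeneSetTestResult:
    """Legacy coefficient-bootstrap t-test (known-invalid; kept for study).

    Resamples the m per-gene coefficients with replacement to form a
    bootstrap SE of their mean, then refers beta_bar/SE to t with m - 1 df.
    Ignoring the correlation of the coefficients makes the SE too small
    (inflated Type I error with correlated genes) and the df ignore n.
    """
    fit = fit_mvlm(Y, design)
    coefs = mean_effect(fit, focal).per_gene
    m = len(coefs)
    if m < 2:
        raise ValueError(
            "if only a single gene expression level is measured, this "
            "coefficient-bootstrap t cannot even be computed (m must be >= 2)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    boot_means = coefs[idx].mean(axis=1)
    se = float(boot_means.std(ddof=1))
    betabar = float(coefs.mean())
    if se == 0:
        return GeneSetTestResult("fredrickson_t", betabar, None, 0.0, 1.0,
                                 df=m - 1, n_resamples=n_boot, known_invalid=True)
    stat = betabar / se
    p = float(2.0 * stats.t.sf(abs(stat), m - 1))
    return GeneSetTestResult("fredrickson_t", betabar, se, stat,
                             max(p, np.finfo(float).tiny), df=m - 1,
                             n_resamples=n_boot, known_invalid=True)


def fold_change(betabar_unstandardized: float) -> float:
    """Fold change per 4 SD of the predictor: FC = 2^(4*beta_bar).

    beta_bar must come from a fit on unstandardized log2 outcomes with a
    standardized predictor.  Decreasing effects (beta_bar < 0) are reported
    as the negated reciprocal so the magnitude is always >= 1.
    """
    fc = float(2.0 ** (4.0 * betabar_unstandardized))
    if betabar_unstandardized < 0:
        return -1.0 / fc
    return fc
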