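"""Fixed-effects linear model with correlated error, fit by ML.

The wide n x m outcome matrix is stacked to long format (one row per
subject x gene) with gene-specific intercepts and covariate effects
shared across genes; the within-subject error is either heterogeneous
compound symmetry (gene-specific SDs, one common correlation) or
unstructured.  Estimation alternates an exact GLS step for the fixed
effects with a guarded maximization of the profile likelihood over the
error parameters, so the log-likelihood never decreases.

The long-format design never needs to be materialized: with covariates
constant within subject, the GLS normal equations collapse to small
m- and q-dimensional blocks, making each fit cheap enough for Monte
Carlo use.

Model-based standard errors from (sum_i X_i' S^-1 X_i)^-1 are exactly the
quantity whose downward bias under misspecified correlation the bootstrap
and permutation wrappers are designed to expose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .data_io import DesignSpec, OrientedExpressionMatrix, standardize_columns
from .resampling import PermutationDraw, freedman_lane_sample, reduced_state

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HetCSParams:
    """Heterogeneous compound symmetry: common rho, gene-specific SDs."""

    rho: float
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, float)
        m = len(self.sigma)
        if not (-1.0 / max(m - 1, 1) < self.rho < 1.0):
            raise ValueError(f"rho={self.rho} outside (-1/(m-1), 1)")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    def covariance(self) -> np.ndarray:
        m = len(self.sigma)
        R = np.full((m, m), self.rho)
        np.fill_diagonal(R, 1.0)
        return R * np.outer(self.sigma, self.sigma)


@dataclass
class GLSFit:
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    params: HetCSParams | np.ndarray
    loglik: float
    loglik_path: list[float]
    converged: bool
    n_iter: int
    n: int
    m: int

    def _idx(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown coefficient {name!r}") from None

    def coef(self, name: str) -> float:
        return float(self.beta[self._idx(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self._idx(name)])

    def wald_p(self, name: str) -> float:
        z = self.coef(name) / self.stderr(name)
        return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class ResampleSummary:
    """Per-iteration focal coefficients/t-values from bootstrap or permutation."""

    coefficients: np.ndarray
    tvalues: np.ndarray
    se: float | None
    p: float | None
    n_iterations: int
    failures: int
    unreliable: bool
    dropped_covariates: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# het-CS likelihood with closed-form inverse / determinant


def _hetcs_ab(rho: float, m: int) -> tuple[float, float]:
    """R(rho)^-1 = a I + b J for the exchangeable correlation matrix."""
    a = 1.0 / (1.0 - rho)
    b = -rho / ((1.0 - rho) * (1.0 + (m - 1) * rho))
    return a, b


def hetcs_loglik(E: np.ndarray, sigma: np.ndarray, rho: float) -> float:
    n, m = E.shape
    a, b = _hetcs_ab(rho, m)
    Z = E / sigma
    q1 = float((Z * Z).sum())
    q2 = float((Z.sum(axis=1) ** 2).sum())
    logdetR = (m - 1) * np.log1p(-rho) + np.log1p((m - 1) * rho)
    return (-0.5 * n * m * _LOG2PI - n * float(np.log(sigma).sum())
            - 0.5 * n * logdetR - 0.5 * (a * q1 + b * q2))


def _hetcs_negll_grad(theta: np.ndarray, E: np.ndarray, lo: float, hi: float):
    """Negative loglik and gradient in (log sigma, logit-scaled rho)."""
    n, m = E.shape
    logsig, phi = theta[:m], theta[m]
    sigma = np.exp(logsig)
    s = expit(phi)
    rho = lo + (hi - lo) * s
    a, b = _hetcs_ab(rho, m)
    Z = E / sigma
    rowsum = Z.sum(axis=1)
    q1 = float((Z * Z).sum())
    q2 = float(rowsum @ rowsum)
    logdetR = (m - 1) * np.log1p(-rho) + np.log1p((m - 1) * rho)
    ll = (-0.5 * n * m * _LOG2PI - n * logsig.sum()
          - 0.5 * n * logdetR - 0.5 * (a * q1 + b * q2))
    # d ll / d log sigma_j
    colsq = (Z * Z).sum(axis=0)
    colcross = Z.T @ rowsum
    g_sig = -n + a * colsq + b * colcross
    # d ll / d rho
    c = 1.0 + (m - 1) * rho
    dlogdet = -(m - 1) / (1.0 - rho) + (m - 1) / c
    da = 1.0 / (1.0 - rho) ** 2
    db = (-(1.0 - rho) * c + rho * (-c + (1.0 - rho) * (m - 1))) / ((1.0 - rho) * c) ** 2
    dll_drho = -0.5 * n * dlogdet - 0.5 * (da * q1 + db * q2)
    g_rho = dll_drho * (hi - lo) * s * (1.0 - s)
    grad = np.concatenate([g_sig, [g_rho]])
    return -ll, -grad


def _hetcs_step(E: np.ndarray, current: HetCSParams | None) -> HetCSParams:
    """Maximize the likelihood over (sigma, rho) for fixed residuals."""
    n, m = E.shape
    lo = -1.0 / max(m - 1, 1) + 1e-6
    hi = 1.0 - 1e-6
    sig0 = np.sqrt(np.maximum((E * E).mean(axis=0), 1e-12))
    if current is None:
        rho0 = float(np.clip(_mean_offdiag_corr(E), lo + 1e-6, hi - 1e-6))
    else:
        sig0 = np.maximum(current.sigma, 1e-8)
        rho0 = float(np.clip(current.rho, lo + 1e-6, hi - 1e-6))
    x0 = np.concatenate([np.log(sig0), [logit((rho0 - lo) / (hi - lo))]])
    res = optimize.minimize(_hetcs_negll_grad, x0, args=(E, lo, hi),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8})
    x = res.x
    cand = HetCSParams(rho=lo + (hi - lo) * float(expit(x[m])),
                       sigma=np.exp(x[:m]))
    if current is not None:
        # guard: never accept a likelihood decrease
        if hetcs_loglik(E, cand.sigma, cand.rho) < hetcs_loglik(
                E, current.sigma, current.rho) - 1e-9:
            return current
    return cand


def _mean_offdiag_corr(E: np.ndarray) -> float:
    m = E.shape[1]
    if m < 2:
        return 0.0
    C = np.corrcoef(E, rowvar=False)
    return float((C.sum() - m) / (m * (m - 1)))


# --------------------------------------------------------------------------
# GLS beta step (block-collapsed normal equations)


def _beta_step(Y: np.ndarray, C: np.ndarray, W: np.ndarray):
    """Exact GLS update of (gene intercepts, shared covariate effects).

    For X_i = [I_m, 1_m c_i'] the normal equations collapse to
    A = [[n W, w sum(c)'], [sum(c) w', (1'W1) C'C]] with w = W 1.
    Returns beta = (mu, gamma), the covariance factor A^-1, and fitted
    residuals.
    """
    n, m = Y.shape
    qc = C.shape[1]
    w = W.sum(axis=1)
    s_w = float(w.sum())
    colsum_c = C.sum(axis=0)
    A = np.empty((m + qc, m + qc))
    A[:m, :m] = n * W
    A[:m, m:] = np.outer(w, colsum_c)
    A[m:, :m] = A[:m, m:].T
    A[m:, m:] = s_w * (C.T @ C)
    rhs = np.concatenate([W @ Y.sum(axis=0), C.T @ (Y @ w)])
    Ainv = np.linalg.inv(A)
    beta = Ainv @ rhs
    mu, gamma = beta[:m], beta[m:]
    E = Y - mu[None, :] - (C @ gamma)[:, None]
    return beta, Ainv, E


def _hetcs_W(params: HetCSParams) -> np.ndarray:
    m = len(params.sigma)
    a, b = _hetcs_ab(params.rho, m)
    Rinv = np.full((m, m), b)
    np.fill_diagonal(Rinv, a + b)
    inv_sig = 1.0 / params.sigma
    return Rinv * np.outer(inv_sig, inv_sig)


def _unstructured_loglik(E: np.ndarray, S: np.ndarray) -> float:
    n, m = E.shape
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    quad = float(np.einsum("ij,jk,ik->", E, np.linalg.inv(S), E))
    return -0.5 * n * m * _LOG2PI - 0.5 * n * logdet - 0.5 * quad


def gls_fit(Y, design: DesignSpec, structure: str = "het_cs",
            tol: float = 1e-6, max_iter: int = 200) -> GLSFit:
    """ML fit of the long-format correlated-error model.

    Alternates (i) exact GLS for the fixed effects given the error
    covariance and (ii) error-covariance update given the residuals:
    het-CS by guarded quasi-Newton on the profile likelihood,
    unstructured by its closed-form ML update.  Both steps are
    non-decreasing in the log-likelihood.  Stops when the fixed effects
    move less than ``tol`` (max abs change); hitting ``max_iter`` leaves
    ``converged=False``.
    """
    if structure not in ("het_cs", "unstructured"):
        raise ValueError(f"unknown structure {structure!r}")
    Yv = Y.values if isinstance(Y, OrientedExpressionMatrix) else np.asarray(Y, float)
    gene_ids = (Y.gene_ids if isinstance(Y, OrientedExpressionMatrix)
                else [f"g{j}" for j in range(Yv.shape[1])])
    n, m = Yv.shape
    if structure == "unstructured" and n <= m:
        raise ValueError(
            f"unstructured error matrix needs n > m (got n={n}, m={m}); "
            "fits in this regime do not converge reliably and are refused")
    full = design.full_matrix()
    names_full = design.full_names()
    covar_idx = [j for j in range(full.shape[1]) if names_full[j] != "intercept"]
    C = full[:, covar_idx]
    names = [f"gene:{g}" for g in gene_ids] + [names_full[j] for j in covar_idx]

    beta, Ainv, E = _beta_step(Yv, C, np.eye(m))
    params: HetCSParams | np.ndarray | None = None
    path: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if structure == "het_cs":
            params = _hetcs_step(E, params if isinstance(params, HetCSParams) else None)
            W = _hetcs_W(params)
            path.append(hetcs_loglik(E, params.sigma, params.rho))
        else:
            S = (E.T @ E) / n
            for jitter in (0.0, 1e-8, 1e-6, 1e-4):
                Sj = S + jitter * np.trace(S) / m * np.eye(m)
                if np.linalg.eigvalsh(Sj).min() > 0:
                    S = Sj
                    break
            else:
                logger.warning("unstructured covariance update not PD; stopping")
                break
            params = S
            W = np.linalg.inv(S)
            path.append(_unstructured_loglik(E, S))
        beta_new, Ainv, E = _beta_step(Yv, C, W)
        if structure == "het_cs":
            path.append(hetcs_loglik(E, params.sigma, params.rho))
        else:
            path.append(_unstructured_loglik(E, params))
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if params is None:  # max_iter == 0 guard; never expected
        raise RuntimeError("no covariance update performed")
    se = np.sqrt(np.diag(Ainv))
    return GLSFit(beta=beta, se=se, names=names, params=params,
                  loglik=path[-1] if path else np.nan, loglik_path=path,
                  converged=converged, n_iter=n_iter, n=n, m=m)


# --------------------------------------------------------------------------
# resampling wrappers (wide-format resample -> rescale -> refit)


def _binary_columns(M: np.ndarray) -> list[int]:
    return [j for j in range(M.shape[1])
            if np.unique(M[:, j]).size <= 2]


def _restandardized_design(Xn: np.ndarray, Z: np.ndarray, x_names, z_names,
                           binary: list[int], threshold: int):
    """Rebuild a DesignSpec after resampling: rescale continuous columns,
    drop binary covariates that became (nearly) constant."""
    keep, dropped = [], []
    cols = []
    for j in range(Xn.shape[1]):
        col = Xn[:, j]
        if j in binary:
            counts = np.unique(col, return_counts=True)[1]
            if counts.size < 2 or counts.min() < threshold:
                dropped.append(x_names[j])
                continue
            cols.append(col)
        else:
            cols.append(standardize_columns(col[:, None])[:, 0])
        keep.append(x_names[j])
    Xs = np.column_stack(cols) if cols else np.empty((len(Xn), 0))
    X = np.hstack([np.ones((len(Xn), 1)), Xs])
    design = DesignSpec(X=X, Z=standardize_columns(Z),
                        x_names=["intercept"] + keep, z_names=list(z_names))
    return design, dropped


def _focal_stats(fit: GLSFit, focal: str) -> tuple[float, float]:
    c = fit.coef(focal)
    return c, c / fit.stderr(focal)


def _wide_blocks(design: DesignSpec):
    full = design.full_matrix()
    names = design.full_names()
    nui = [j for j in range(design.q) if names[j] != "intercept"]
    return full[:, nui], [names[j] for j in nui]


def gls_bootstrap(Y, design: DesignSpec, focal: str, n_boot: int = 200,
                  seed=None, drop_rare_binary_threshold: int = 3,
                  structure: str = "het_cs") -> ResampleSummary:
    """Subject bootstrap of the GLS focal coefficient (SE from the spread).

    Subjects are resampled with replacement in wide format, every column
    re-standardized, and the model refit.  Iteration 0 is the observed
    data; the bootstrap SE is the SD of the focal coefficient over the
    resampled iterations only.  Binary covariates with fewer than
    ``drop_rare_binary_threshold`` minority cases in a resample are
    dropped for that iteration (a resample with a constant dummy is
    unsolvable).
    """
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Yv = Y.values if isinstance(Y, OrientedExpressionMatrix) else np.asarray(Y, float)
    n = Yv.shape[0]
    Xn, x_names = _wide_blocks(design)
    binary = _binary_columns(Xn)
    coefs = np.full(n_boot + 1, np.nan)
    tvals = np.full(n_boot + 1, np.nan)
    dropped_all: list[str] = []
    failures = 0
    for it in range(n_boot + 1):
        idx = np.arange(n) if it == 0 else rng.integers(0, n, size=n)
        try:
            d, dropped = _restandardized_design(
                Xn[idx], design.Z[idx] if design.d else np.empty((n, 0)),
                x_names, design.z_names, binary, drop_rare_binary_threshold)
            dropped_all.extend(d2 for d2 in dropped if d2 not in dropped_all)
            fit = gls_fit(standardize_columns(Yv[idx]), d, structure=structure)
            if not fit.converged:
                raise RuntimeError("GLS did not converge")
            coefs[it], tvals[it] = _focal_stats(fit, focal)
        except Exception as exc:  # noqa: BLE001 - counted, surfaced in summary
            failures += 1
            logger.debug("bootstrap iteration %d failed: %s", it, exc)
    ok = ~np.isnan(coefs[1:])
    se = float(coefs[1:][ok].std(ddof=1)) if ok.sum() >= 2 else None
    return ResampleSummary(coefficients=coefs, tvalues=tvals, se=se, p=None,
                           n_iterations=n_boot + 1, failures=failures,
                           unreliable=failures > 0.2 * n_boot,
                           dropped_covariates=dropped_all)


def gls_permutation(Y, design: DesignSpec, focal: str, n_perm: int = 400,
                    seed=None, structure: str = "het_cs") -> ResampleSummary:
    """Freedman-Lane permutation p-value for the GLS focal t-statistic.

    Residuals under the reduced (focal-excluded) model are permuted in
    wide format, added back to the reduced-model fit, rescaled and refit;
    p is the fraction of |t| at or above the observed |t| (observed
    iteration included).
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Yv = Y.values if isinstance(Y, OrientedExpressionMatrix) else np.asarray(Y, float)
    n = Yv.shape[0]
    state = reduced_state(Yv, design, focal)
    coefs = np.full(n_perm, np.nan)
    tvals = np.full(n_perm, np.nan)
    failures = 0
    for it in range(n_perm):
        draw = PermutationDraw(np.arange(n) if it == 0 else rng.permutation(n),
                               iteration=it, observed=(it == 0))
        Yp = freedman_lane_sample(state, draw)
        try:
            fit = gls_fit(standardize_columns(Yp), design, structure=structure)
            if not fit.converged:
                raise RuntimeError("GLS did not converge")
            coefs[it], tvals[it] = _focal_stats(fit, focal)
        except Exception as exc:  # noqa: BLE001
            failures += 1
            logger.debug("permutation iteration %d failed: %s", it, exc)
    if np.isnan(tvals[0]):
        raise RuntimeError("GLS failed on the observed data")
    ok = ~np.isnan(tvals)
    p = float(np.mean(np.abs(tvals[ok]) >= abs(tvals[0])))
    return ResampleSummary(coefficients=coefs, tvalues=tvals, se=None, p=p,
                           n_iterations=n_perm, failures=failures,
                           unreliable=failures > 0.2 * n_perm)
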