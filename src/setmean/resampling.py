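"""Resampling tests of the gene-set mean effect.

All four tests condition on the nuisance covariates.  The permutation
tests use the Freedman-Lane device ("permutation under the null"):
reduced-model residuals are permuted and added back to the reduced-model
fitted values, preserving the nuisance structure while destroying any
focal association.  The rotation test replaces permutations with random
unit vectors in the residual subspace, which is exact for Gaussian errors.

Every test includes the observed data as iteration 0 and computes
p = #{statistic >= observed} / B, so p >= 1/B by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._moderation import estimate_prior, moderate_variances
from .data_io import DesignSpec, OrientedExpressionMatrix
from .mvlm import fit_mvlm, mean_effect
from .parametric import GeneSetTestResult

_CHUNK = 512  # permutations processed per block to bound memory


@dataclass
class PermutationDraw:
    """A permutation of subject indices; iteration 0 is the identity."""

    indices: np.ndarray
    iteration: int
    observed: bool = False

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        n = len(idx)
        if not np.array_equal(np.sort(idx), np.arange(n)):
            raise ValueError("draw is not a permutation of 0..n-1")
        if self.observed and not np.array_equal(idx, np.arange(n)):
            raise ValueError("observed draw must be the identity")
        self.indices = idx


@dataclass
class RotationDraw:
    """A unit vector in the reduced-model residual subspace."""

    vector: np.ndarray
    iteration: int
    observed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-12:
            raise ValueError("rotation vector must have unit norm")
        self.vector = v


@dataclass
class ReducedModelState:
    """Reduced-model (focal excluded) decomposition used by all tests."""

    Q_X: np.ndarray       # orthonormal basis of the nuisance column space
    Yhat: np.ndarray      # fitted values of Y under the null
    E_YX: np.ndarray      # residuals of Y under the null
    E_ZX: np.ndarray      # residuals of the focal predictor on the nuisance
    Y: np.ndarray
    z: np.ndarray
    n: int
    m: int
    q: int


def _values(Y) -> np.ndarray:
    return Y.values if isinstance(Y, OrientedExpressionMatrix) else np.asarray(Y, float)


def reduced_state(Y, design: DesignSpec, focal: str) -> ReducedModelState:
    """Residualize Y and the focal predictor on the nuisance block.

    The nuisance block is X plus every focal column other than ``focal``
    (the paper-style reduced model when two well-being scores are tested
    one at a time).
    """
    Yv = _values(Y)
    k = design.z_names.index(focal)
    z = design.Z[:, k].copy()
    Xr = design.reduced(focal).X
    Q, _ = np.linalg.qr(Xr)
    Yhat = Q @ (Q.T @ Yv)
    E_YX = Yv - Yhat
    E_ZX = z - Q @ (Q.T @ z)
    return ReducedModelState(Q_X=Q, Yhat=Yhat, E_YX=E_YX, E_ZX=E_ZX,
                             Y=Yv, z=z, n=Yv.shape[0], m=Yv.shape[1],
                             q=Q.shape[1])


def freedman_lane_sample(state: ReducedModelState, draw: PermutationDraw
                         ) -> np.ndarray:
    """Y_pi = Yhat + row-permuted residuals under the null.

    The identity draw returns Y exactly; any draw preserves the column
    means (the intercept lives in the nuisance block).
    """
    if draw.observed or np.array_equal(draw.indices, np.arange(state.n)):
        return state.Y
    return state.Yhat + state.E_YX[draw.indices]


def r2f_statistic(state: ReducedModelState, Y_input: np.ndarray) -> float:
    """Squared partial-correlation statistic between focal and outcomes.

    Numerator: the squared sum over all (subject, gene) entries of the
    product of the Y-on-nuisance residuals with the focal residuals;
    denominator: the product of the two total sums of squares, with the
    focal-residual term replicated per gene (factor m) so the ratio stays
    in [0, 1] and reduces to the squared partial correlation at m = 1.
    """
    E_pf = Y_input - state.Q_X @ (state.Q_X.T @ Y_input)
    e = state.E_ZX
    num = float((E_pf * e[:, None]).sum()) ** 2
    den = float((E_pf * E_pf).sum()) * state.m * float(e @ e)
    if den == 0:
        raise ValueError("zero denominator in r2F (degenerate residuals)")
    return num / den


def _make_permutations(n: int, B: int, seed, permutations) -> np.ndarray:
    """B x n index array; row 0 is always the identity (observed data)."""
    if permutations is not None:
        perms = np.asarray(permutations)
        if perms.ndim != 2 or perms.shape[1] != n:
            raise ValueError("permutations must be B x n")
        if not np.array_equal(perms[0], np.arange(n)):
            raise ValueError("permutations[0] must be the identity (observed)")
        return perms
    if B < 1:
        raise ValueError("need at least one iteration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.empty((B, n), dtype=np.intp)
    perms[0] = np.arange(n)
    for b in range(1, B):
        perms[b] = rng.permutation(n)
    return perms


def _null_projection_terms(state: ReducedModelState, perms: np.ndarray):
    """Per-permutation pieces shared by the r2F and F_pun statistics.

    For permuted residuals Ep = E[perm], returns
    rss_reduced = ||M_X Ep||_F^2, cross = e'Ep per gene (m-vector), and
    the scalar e'(row sums of Ep); all computed without forming M_X.
    """
    E, e, Q = state.E_YX, state.E_ZX, state.Q_X
    B = perms.shape[0]
    normE2 = float((E * E).sum())
    rowsum = E.sum(axis=1)
    num_scalar = np.empty(B)
    rss_reduced = np.empty(B)
    cross = np.empty((B, state.m))
    for lo in range(0, B, _CHUNK):
        hi = min(lo + _CHUNK, B)
        Ep = E[perms[lo:hi]]                      # (chunk, n, m)
        QtEp = np.einsum("nq,bnm->bqm", Q, Ep, optimize=True)
        rss_reduced[lo:hi] = normE2 - (QtEp * QtEp).sum(axis=(1, 2))
        cross[lo:hi] = np.einsum("n,bnm->bm", e, Ep, optimize=True)
        num_scalar[lo:hi] = rowsum[perms[lo:hi]] @ e
    return rss_reduced, cross, num_scalar


def _resample_p(statistics: np.ndarray) -> float:
    """Fraction of iterations (observed included) at or above the observed."""
    return float(np.mean(statistics >= statistics[0]))


def anderson_r2f_test(Y, design: DesignSpec, focal: str, n_perm: int = 10_000,
                      seed=None, permutations: np.ndarray | None = None
                      ) -> GeneSetTestResult:
    """Freedman-Lane permutation test of the squared partial correlation."""
    state = reduced_state(Y, design, focal)
    perms = _make_permutations(state.n, n_perm, seed, permutations)
    rss_red, _, num_scalar = _null_projection_terms(state, perms)
    e2 = float(state.E_ZX @ state.E_ZX)
    if e2 == 0:
        raise ValueError("focal predictor fully explained by the nuisance block")
    stat = num_scalar**2 / (rss_red * state.m * e2)
    p = _resample_p(stat)
    betabar = mean_effect(fit_mvlm(state.Y, design), focal).betabar
    return GeneSetTestResult("r2f", betabar, None, float(stat[0]), p,
                             n_resamples=len(perms), resampling_p=True)


def fpun_test(Y, design: DesignSpec, focal: str, n_perm: int = 10_000,
              seed=None, permutations: np.ndarray | None = None
              ) -> GeneSetTestResult:
    """Permutation-under-the-null F-test.

    Each iteration refits both the full and the reduced model to the
    Freedman-Lane outcome Y_pi; the statistic is
    (RSS_reduced - RSS_full) / RSS_full with RSS summed over all genes.
    """
    state = reduced_state(Y, design, focal)
    perms = _make_permutations(state.n, n_perm, seed, permutations)
    rss_red, cross, _ = _null_projection_terms(state, perms)
    e2 = float(state.E_ZX @ state.E_ZX)
    if e2 == 0:
        raise ValueError("focal predictor fully explained by the nuisance block")
    explained = (cross**2).sum(axis=1) / e2
    rss_full = rss_red - explained
    if np.any(rss_full <= 0):
        raise ValueError("perfect full-model fit (RSS_full = 0)")
    stat = explained / rss_full
    p = _resample_p(stat)
    betabar = mean_effect(fit_mvlm(state.Y, design), focal).betabar
    return GeneSetTestResult("fpun", betabar, None, float(stat[0]), p,
                             n_resamples=len(perms), resampling_p=True)


def fga_test(Y, design: DesignSpec, focal: str, n_perm: int = 10_000,
             seed=None, permutations: np.ndarray | None = None
             ) -> GeneSetTestResult:
    """GlobalAncova-style permutation F-test.

    The outcome is the observed reduced-model residual matrix (computed
    once); each iteration permutes the rows of the focal predictor,
    refits the full model, and compares to the fixed reduced-model RSS.
    Permuting Z rather than the residuals ignores the covariance between
    focal and nuisance (exchangeability violation), which the simulations
    show to be mild.
    """
    state = reduced_state(Y, design, focal)
    perms = _make_permutations(state.n, n_perm, seed, permutations)
    E, z, Q = state.E_YX, state.z, state.Q_X
    rss_red = float((E * E).sum())
    if rss_red == 0:
        raise ValueError("reduced model fits perfectly")
    zp = z[perms]                                   # (B, n)
    zt = zp - (zp @ Q) @ Q.T                        # residualize each permuted z on X
    norms2 = (zt * zt).sum(axis=1)
    if np.any(norms2 == 0):
        raise ValueError("a permuted focal vector lies in the nuisance span")
    cross = zt @ E                                  # (B, m)
    explained = (cross**2).sum(axis=1) / norms2
    rss_full = rss_red - explained
    if np.any(rss_full <= 0):
        raise ValueError("perfect full-model fit (RSS_full = 0)")
    stat = explained / rss_full
    p = _resample_p(stat)
    betabar = mean_effect(fit_mvlm(state.Y, design), focal).betabar
    return GeneSetTestResult("fga", betabar, None, float(stat[0]), p,
                             n_resamples=len(perms), resampling_p=True)


def _t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t-values to standard-normal scores through matched tail areas."""
    t = np.asarray(t, float)
    if np.isinf(df):
        return t
    return np.sign(t) * sps.norm.isf(sps.t.sf(np.abs(t), df))


def rotation_test(Y, design: DesignSpec, focal: str, n_rot: int = 10_000,
                  seed=None, moderate: bool = True, d0: float | None = None
                  ) -> GeneSetTestResult:
    """Rotation z-test of the directional (up-or-down) mean effect.

    Y and the focal predictor are projected onto the orthocomplement of
    the nuisance space (dimension n - q).  Per gene, the effect along the
    unit focal direction and the residual variance on the remaining
    n - q - 1 dimensions give a moderated t (empirical-Bayes shrinkage of
    the variances toward a common prior), mapped to a z-score; the
    statistic is the mean z.  Null draws replace the focal direction with
    random unit vectors — the Gaussian null is rotation invariant.
    """
    state = reduced_state(Y, design, focal)
    n, q, m = state.n, state.q, state.m
    if n - q < 2:
        raise ValueError("need n - q >= 2 for the rotation subspace")
    Qfull, _ = np.linalg.qr(np.hstack([state.Q_X,
                                       np.eye(n)]))  # complete the basis
    Q2 = Qfull[:, q:n]
    Ytil = Q2.T @ state.Y                           # (n-q, m)
    ztil = Q2.T @ state.z
    znorm = np.linalg.norm(ztil)
    if znorm == 0:
        raise ValueError("focal predictor fully explained by the nuisance block")
    u0 = ztil / znorm
    df_g = n - q - 1
    ss = (Ytil * Ytil).sum(axis=0)                  # per-gene total SS in subspace

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = rng.standard_normal(size=(n_rot, n - q))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    R[0] = u0                                       # iteration 0: observed direction
    effects = R @ Ytil                              # (B, m)
    s2 = np.maximum(ss[None, :] - effects**2, np.finfo(float).tiny) / df_g

    if moderate:
        if d0 is None:
            d0_est, s02 = estimate_prior(s2[0], df_g)
        else:
            d0_est = d0
            _, s02 = estimate_prior(s2[0], df_g)
        s2post = moderate_variances(s2, df_g, d0_est, s02)
        df_total = df_g + d0_est
    else:
        s2post, df_total = s2, float(df_g)
    tmat = effects / np.sqrt(s2post)
    zbar = _t_to_z(tmat, df_total).mean(axis=1)
    p = float(np.mean(np.abs(zbar) >= abs(zbar[0])))
    betabar = mean_effect(fit_mvlm(state.Y, design), focal).betabar
    return GeneSetTestResult("rotation", betabar, None, float(zbar[0]), p,
                             n_resamples=n_rot, resampling_p=True,
                             extra={"d0": float(df_total - df_g) if moderate else 0.0})
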