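"""Monte Carlo evaluation of gene-set tests on study-structured data.

Datasets are drawn to mimic a bulk-expression well-being study: n
subjects, a block of correlated continuous regressors containing a pair
of highly correlated focal scores, and a set of correlated gene outcomes.
Covariance matrices can be supplied (e.g. computed from the real study)
or generated from a compact synthetic specification.  For each gene-set
size and each test, null (beta = 0) and power (beta = beta_true) loops
record the estimate and p-value, from which Type I error, power, Type S
(sign) error, the exaggeration ratio (Type M), relative bias and
adjusted power are summarized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import DesignSpec, standardize_columns
from .gls import gls_fit
from .mvlm import fit_mvlm, mean_effect
from .parametric import gee_test, obrien_test
from .resampling import (_make_permutations, _null_projection_terms,
                         _resample_p, reduced_state, rotation_test)

logger = logging.getLogger(__name__)

OLS_METHODS = ("obrien", "r2f", "fpun", "fga", "rotation")


@dataclass
class SyntheticCovarianceSpec:
    """Compact description of the synthetic S_X / S_Y pair.

    The regressor block has ``n_regressors`` standardized covariates whose
    focal pair (indices ``focal_index``, ``partner_index``) correlates at
    ``r_focal`` exactly; remaining correlations have typical magnitude
    ``nuisance_scale``.  The gene covariance is low-rank-plus-diagonal
    with unit diagonal, a dominant positive factor and ``n_factors - 1``
    weaker mixed-sign factors, rescaled so the mean pairwise correlation
    hits ``mean_gene_correlation``.
    """

    n_regressors: int = 17
    focal_index: int = 0
    partner_index: int = 1
    r_focal: float = 0.74
    nuisance_scale: float = 0.2
    m_genes: int = 52
    n_factors: int = 3
    mean_gene_correlation: float = 0.30


@dataclass
class SimulationConfig:
    """Study conditions for one simulation experiment."""

    n: int = 122
    m_grid: tuple[int, ...] = (10, 30, 52)
    beta_true: float = 0.067
    alpha: float = 0.05
    n_iter: int = 1000
    n_resamples: int = 2000
    methods: tuple[str, ...] = OLS_METHODS
    seed: int = 0
    cov_spec: SyntheticCovarianceSpec = field(default_factory=SyntheticCovarianceSpec)
    S_X: np.ndarray | None = None
    S_Y: np.ndarray | None = None
    gls_structure: str = "het_cs"
    run_null: bool = True
    run_power: bool = True


@dataclass
class ErrorSummary:
    """Per (method, m) error rates from one experiment."""

    table: pd.DataFrame
    alpha: float
    beta_true: float

    def get(self, method: str, m: int, column: str):
        row = self.table[(self.table.method == method) & (self.table.m == m)]
        if row.empty:
            raise KeyError(f"no summary row for ({method}, m={m})")
        return row.iloc[0][column]


def _is_pd(S: np.ndarray, tol: float = 1e-8) -> bool:
    return float(np.linalg.eigvalsh(S).min()) > tol


def make_covariances(spec: SyntheticCovarianceSpec, seed=None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Generate the regressor and gene covariance matrices.

    Both are verified positive definite; the focal-pair entry of S_X is
    ``r_focal`` exactly, and the realized mean pairwise gene correlation
    of S_Y is within +-0.02 of the target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = spec.n_regressors
    i, j = spec.focal_index, spec.partner_index
    if i == j or not (0 <= i < p and 0 <= j < p):
        raise ValueError("focal/partner indices invalid")
    if not (abs(spec.r_focal) < 1):
        raise ValueError("r_focal must be inside (-1, 1)")

    # --- S_X: random factor correlation shrunk to the requested scale
    G = rng.normal(size=(p, 2))
    A = G @ G.T + np.eye(p)
    d = np.sqrt(np.diag(A))
    R0 = A / np.outer(d, d)
    off = np.abs(R0[np.triu_indices(p, 1)]).mean()
    w = min(spec.nuisance_scale / off, 1.0) if off > 0 else 0.0
    S_X = np.eye(p) + w * (R0 - np.diag(np.diag(R0)))
    S_X[i, j] = S_X[j, i] = spec.r_focal
    shrink = 0
    while not _is_pd(S_X) and shrink < 60:
        mask = np.ones_like(S_X) * 0.9
        mask[np.diag_indices(p)] = 1.0
        mask[i, j] = mask[j, i] = 1.0
        S_X = S_X * mask
        shrink += 1
    if not _is_pd(S_X):
        raise ValueError("could not build a positive definite S_X for this spec")

    # --- S_Y: dominant positive factor + weaker mixed-sign factors
    m = spec.m_genes
    load = np.empty((m, spec.n_factors))
    load[:, 0] = rng.uniform(0.4, 0.9, size=m)
    if spec.n_factors > 1:
        load[:, 1:] = rng.normal(0.0, 0.3, size=(m, spec.n_factors - 1))
    target = spec.mean_gene_correlation
    if target < 0:
        raise ValueError("mean_gene_correlation must be non-negative")
    if target == 0:
        load[:] = 0.0
    else:
        for _ in range(40):
            rowsq = (load * load).sum(axis=1)
            cap = np.sqrt(np.minimum(1.0, 0.95 / np.maximum(rowsq, 1e-12)))
            load *= cap[:, None]
            Scand = load @ load.T
            mean_off = (Scand.sum() - np.trace(Scand)) / (m * (m - 1))
            if mean_off <= 0:
                raise ValueError("factor structure yields non-positive mean correlation")
            if abs(mean_off - target) < 1e-4:
                break
            load *= np.sqrt(target / mean_off)
    S_Y = load @ load.T
    np.fill_diagonal(S_Y, 1.0)
    if not _is_pd(S_Y, tol=1e-10):
        raise ValueError("S_Y not positive definite for this spec")
    realized = (S_Y.sum() - m) / (m * (m - 1))
    if target > 0 and abs(realized - target) > 0.02:
        raise ValueError(
            f"realized mean gene correlation {realized:.3f} misses target {target}")
    return S_X, S_Y


def simulate_dataset(S_X: np.ndarray, S_Y: np.ndarray, n: int, m: int,
                     beta_true: float, focal_index: int, rng: np.random.Generator,
                     chol_X: np.ndarray | None = None
                     ) -> tuple[np.ndarray, DesignSpec]:
    """Draw one dataset: X ~ N(0, S_X), Y ~ N(0, S_Y[subset]) + effect.

    The gene subset of size m is resampled from S_Y each iteration.  The
    injected effect adds beta_true * focal to every gene; columns are not
    re-standardized afterwards (at the study's effect size the variance
    inflation is negligible).  All non-focal effects are zero.
    """
    p = S_X.shape[0]
    if m > S_Y.shape[0]:
        raise ValueError(f"m={m} exceeds S_Y dimension {S_Y.shape[0]}")
    L = chol_X if chol_X is not None else np.linalg.cholesky(S_X)
    X = rng.standard_normal((n, p)) @ L.T
    subset = rng.choice(S_Y.shape[0], size=m, replace=False)
    Lsub = np.linalg.cholesky(S_Y[np.ix_(subset, subset)])
    Y = rng.standard_normal((n, m)) @ Lsub.T
    if beta_true != 0.0:
        Y = Y + beta_true * X[:, focal_index][:, None]
    nuisance = [k for k in range(p) if k != focal_index]
    design = DesignSpec(
        X=np.hstack([np.ones((n, 1)), X[:, nuisance]]),
        Z=standardize_columns(X[:, [focal_index]]),
        x_names=["intercept"] + [f"x{k}" for k in nuisance],
        z_names=["focal"],
    )
    return Y, design


# --------------------------------------------------------------------------
# error metrics


def type_s_rate(estimates: np.ndarray, pvalues: np.ndarray, beta_true: float,
                alpha: float = 0.05) -> float:
    """P(sign wrong | significant); NaN when nothing is significant."""
    if beta_true == 0:
        raise ValueError("Type S error needs a nonzero true effect")
    est = np.asarray(estimates, float)
    p = np.asarray(pvalues, float)
    sig = p < alpha
    if sig.sum() == 0:
        return np.nan
    wrong = sig & (np.sign(est) != np.sign(beta_true))
    return float(wrong.sum() / sig.sum())


def exaggeration_ratio(estimates: np.ndarray, pvalues: np.ndarray,
                       beta_true: float, alpha: float = 0.05,
                       signed: bool = False) -> float:
    """Mean |estimate|/|true| over significant iterations (p <= alpha).

    ``signed=True`` averages the signed ratio instead; NaN when nothing is
    significant.
    """
    if beta_true == 0:
        raise ValueError("the exaggeration ratio needs a nonzero true effect")
    est = np.asarray(estimates, float)
    p = np.asarray(pvalues, float)
    sel = p <= alpha
    if sel.sum() == 0:
        return np.nan
    if signed:
        return float((est[sel] / beta_true).mean())
    return float((np.abs(est[sel]) / abs(beta_true)).mean())


def estimate_bias(estimates: np.ndarray, beta_true: float) -> float:
    """Relative bias (mean estimate - true)/true over ALL iterations."""
    if beta_true == 0:
        raise ValueError("relative bias needs a nonzero true effect")
    return float((np.mean(estimates) - beta_true) / beta_true)


def adjusted_power(null_pvalues: np.ndarray, alt_pvalues: np.ndarray,
                   target_type_i: float = 0.05) -> tuple[float, float]:
    """Largest alpha with empirical Type I <= target, and power at it.

    With continuous p-values this is the empirical target quantile of the
    null p-values; with heavy ties below the target the cut falls strictly
    below the smallest null p (Type I then 0 <= target).
    """
    null_p = np.sort(np.asarray(null_pvalues, float))
    alt_p = np.asarray(alt_pvalues, float)
    if null_p.size == 0 or alt_p.size == 0:
        raise ValueError("both p-value sets must be nonempty")
    u, counts = np.unique(null_p, return_counts=True)
    frac = np.cumsum(counts) / null_p.size
    ok = frac <= target_type_i
    alpha_adj = float(u[ok][-1]) if ok.any() else float(u[0] / 2.0)
    return alpha_adj, float(np.mean(alt_p <= alpha_adj))


# --------------------------------------------------------------------------
# experiment driver


def _ols_perm_suite(Y: np.ndarray, design: DesignSpec, focal: str,
                    methods: set[str], n_resamples: int,
                    rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """Run the requested permutation tests sharing one set of draws.

    Returns method -> (estimate, p).  The r2F and F_pun statistics reuse
    the same reduced-model projection terms; all tests share the same
    permutations, iteration 0 being the observed data.
    """
    state = reduced_state(Y, design, focal)
    betabar = mean_effect(fit_mvlm(Y, design), focal).betabar
    out: dict[str, tuple[float, float]] = {}
    perm_methods = methods & {"r2f", "fpun", "fga"}
    if perm_methods:
        perms = _make_permutations(state.n, n_resamples, rng, None)
        e2 = float(state.E_ZX @ state.E_ZX)
        if {"r2f", "fpun"} & perm_methods:
            rss_red, cross, num_scalar = _null_projection_terms(state, perms)
            if "r2f" in perm_methods:
                stat = num_scalar**2 / (rss_red * state.m * e2)
                out["r2f"] = (betabar, _resample_p(stat))
            if "fpun" in perm_methods:
                explained = (cross**2).sum(axis=1) / e2
                stat = explained / (rss_red - explained)
                out["fpun"] = (betabar, _resample_p(stat))
        if "fga" in perm_methods:
            E, Q = state.E_YX, state.Q_X
            rss_red0 = float((E * E).sum())
            zp = state.z[perms]
            zt = zp - (zp @ Q) @ Q.T
            explained = ((zt @ E) ** 2).sum(axis=1) / (zt * zt).sum(axis=1)
            stat = explained / (rss_red0 - explained)
            out["fga"] = (betabar, _resample_p(stat))
    return out


def _run_one(method: str, Y: np.ndarray, design: DesignSpec,
             n_resamples: int, rng: np.random.Generator,
             gls_structure: str) -> tuple[float, float, bool]:
    """(estimate, p, converged) for a single non-suite method."""
    if method == "obrien":
        r = obrien_test(Y, design, "focal")
        return r.estimate, r.p, True
    if method == "rotation":
        r = rotation_test(Y, design, "focal", n_rot=n_resamples, seed=rng)
        return r.estimate, r.p, True
    if method == "gee":
        r = gee_test(Y, design, "focal")
        return r.estimate, r.p, r.converged
    if method == "gls":
        fit = gls_fit(Y, design, structure=gls_structure)
        return fit.coef("focal"), fit.wald_p("focal"), fit.converged
    raise ValueError(f"unknown method {method!r}")


def run_experiment(config: SimulationConfig) -> tuple[ErrorSummary, pd.DataFrame]:
    """Run the full null/power grid and summarize error rates.

    Fully reproducible from ``config.seed``: every iteration draws its
    data and its resampling streams from named substreams, so enabling or
    disabling a method does not perturb the others.
    """
    if config.S_X is not None and config.S_Y is not None:
        S_X, S_Y = np.asarray(config.S_X, float), np.asarray(config.S_Y, float)
        if not (_is_pd(S_X) and _is_pd(S_Y, tol=1e-10)):
            raise ValueError("supplied covariance matrices must be positive definite")
    else:
        S_X, S_Y = make_covariances(
            config.cov_spec,
            np.random.default_rng(np.random.SeedSequence(config.seed,
                                                         spawn_key=(0,))))
    chol_X = np.linalg.cholesky(S_X)
    focal_index = config.cov_spec.focal_index
    betas = []
    if config.run_null:
        betas.append(0.0)
    if config.run_power and config.beta_true != 0.0:
        betas.append(config.beta_true)
    rows = []
    for mi, m in enumerate(config.m_grid):
        for bi, beta in enumerate(betas):
            for it in range(config.n_iter):
                data_rng = np.random.default_rng(np.random.SeedSequence(
                    config.seed, spawn_key=(1, mi, bi, it)))
                Y, design = simulate_dataset(S_X, S_Y, config.n, m, beta,
                                             focal_index, data_rng, chol_X)
                suite_rng = np.random.default_rng(np.random.SeedSequence(
                    config.seed, spawn_key=(2, mi, bi, it)))
                suite = _ols_perm_suite(Y, design, "focal",
                                        set(config.methods), config.n_resamples,
                                        suite_rng)
                for meth_i, method in enumerate(config.methods):
                    if method in suite:
                        est, p = suite[method]
                        conv = True
                    else:
                        meth_rng = np.random.default_rng(np.random.SeedSequence(
                            config.seed, spawn_key=(3, mi, bi, it, meth_i)))
                        try:
                            est, p, conv = _run_one(method, Y, design,
                                                    config.n_resamples, meth_rng,
                                                    config.gls_structure)
                        except Exception as exc:  # noqa: BLE001 - counted below
                            logger.debug("%s failed at m=%d it=%d: %s",
                                         method, m, it, exc)
                            est, p, conv = np.nan, np.nan, False
                    rows.append((method, m, beta, it, est, p, conv))
    records = pd.DataFrame(rows, columns=["method", "m", "beta_true",
                                          "iteration", "estimate", "p",
                                          "converged"])
    summary = summarize_records(records, config.alpha, config.beta_true)
    return summary, records


def summarize_records(records: pd.DataFrame, alpha: float, beta_true: float
                      ) -> ErrorSummary:
    """Aggregate iteration records into per-(method, m) error rates."""
    rows = []
    for (method, m), grp in records.groupby(["method", "m"], sort=False):
        null = grp[(grp.beta_true == 0) & grp.converged]
        alt = grp[(grp.beta_true != 0) & grp.converged]
        n_null, n_alt = len(null), len(alt)
        failures = int((~grp.converged).sum())
        row = {"method": method, "m": int(m), "n_null": n_null, "n_alt": n_alt,
               "failures": failures,
               "flagged": failures > 0.05 * len(grp),
               "type_i": np.nan, "type_i_se": np.nan, "power": np.nan,
               "power_se": np.nan, "type_s": np.nan, "exaggeration_ratio": np.nan,
               "bias": np.nan, "adjusted_alpha": np.nan, "adjusted_power": np.nan}
        if n_null:
            t1 = float((null.p < alpha).mean())
            row["type_i"] = t1
            row["type_i_se"] = float(np.sqrt(t1 * (1 - t1) / n_null))
        if n_alt:
            pw = float((alt.p < alpha).mean())
            row["power"] = pw
            row["power_se"] = float(np.sqrt(pw * (1 - pw) / n_alt))
            bt = float(alt.beta_true.iloc[0])
            row["type_s"] = type_s_rate(alt.estimate.to_numpy(), alt.p.to_numpy(),
                                        bt, alpha)
            row["exaggeration_ratio"] = exaggeration_ratio(
                alt.estimate.to_numpy(), alt.p.to_numpy(), bt, alpha)
            row["bias"] = estimate_bias(alt.estimate.to_numpy(), bt)
        if n_null and n_alt:
            a_adj, p_adj = adjusted_power(null.p.to_numpy(), alt.p.to_numpy(),
                                          alpha)
            row["adjusted_alpha"], row["adjusted_power"] = a_adj, p_adj
        rows.append(row)
    return ErrorSummary(table=pd.DataFrame(rows), alpha=alpha,
                        beta_true=beta_true)


def ols_type_i_study(n_datasets: int = 1000, m: int = 10, n: int = 122,
                     n_resamples: int = 500, seed: int = 0,
                     cov_spec: SyntheticCovarianceSpec | None = None
                     ) -> dict[str, float]:
    """Null-calibration study of the five OLS tests; returns Type I rates."""
    config = SimulationConfig(
        n=n, m_grid=(m,), beta_true=0.067, n_iter=n_datasets,
        n_resamples=n_resamples, methods=OLS_METHODS, seed=seed,
        cov_spec=cov_spec or SyntheticCovarianceSpec(),
        run_power=False)
    summary, _ = run_experiment(config)
    return {meth: float(summary.get(meth, m, "type_i")) for meth in OLS_METHODS}


def desk_scale(config: SimulationConfig, n_iter: int = 500,
               n_resamples: int = 500) -> SimulationConfig:
    """A reduced-scale copy of a config for interactive runs."""
    return replace(config, n_iter=n_iter, n_resamples=n_resamples)
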