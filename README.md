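# setmean

Self-contained gene-set association tests of a continuous phenotype on
the **mean expression** of an a-priori gene set, with nuisance
covariates — plus a Monte Carlo engine that measures the Type I, power,
Type S (sign) and Type M (magnitude) errors of each test on simulated
data modeled on a real bulk-expression study design.

## The problem

Given a subjects × genes matrix **Y** of log2 expression for a
pre-specified gene set (e.g. the 52–53-gene CTRA set, with anti-viral
and antibody genes sign-flipped so a positive effect reads as a
set-concordant response) and a continuous phenotype *z* (e.g. a
well-being score) measured alongside many nuisance covariates, the
directional null hypothesis is

> H₀: β̄ = (1/m) Σⱼ βⱼ = 0,

where βⱼ is the standardized partial regression coefficient of gene *j*
on *z* from the multivariate linear model **Y = XB + E**. This differs
from "any coefficient nonzero" multivariate tests: the estimand is the
average effect over the set, up or down.

The library implements, behind one interface:

| family | methods |
|---|---|
| parametric OLS | O'Brien's t-test `t = Σtⱼ/√(1'R1)` with the reduced-model residual correlation **R**; GEE Wald z (exchangeable working correlation, sandwich SE) |
| permutation (Freedman–Lane, "permutation under the null") | Anderson's r²F squared-partial-correlation test; a permutation partial-F test (F_pun); a GlobalAncova-style F test permuting the focal predictor |
| rotation | a rotation z-test with empirical-Bayes moderated t-statistics (exact for Gaussian errors) |
| correlated-error GLS | ML fit of the long-format fixed-effects model with heterogeneous-compound-symmetry or unstructured error, plus subject-bootstrap SEs and Freedman–Lane permutation p-values |
| legacy | the coefficient-bootstrap t with m−1 df (known-invalid; kept to demonstrate its inflation with correlated genes) |

Why so many? Because the GLS-with-correlated-error approach — used in a
high-profile well-being study — produces downward-biased standard errors
and inflated coefficients for multiple-outcome designs. The simulator in
`setmean.simulate` quantifies this: on data with the study's structure
(n=122 subjects, 17 correlated regressors whose focal pair correlates at
0.74, correlated gene outcomes), the OLS tests hold the nominal 5% Type I
error while the GLS test's Type I error is inflated and grows with the
gene-set size. Two correlated regressors also yield *negatively
correlated* coefficient estimates — with weights 1/(n(1−r²)) and
−r/(n(1−r²)), i.e. 0.018 and −0.013 at n=122, r=0.74 — so "opposite
effects" of two correlated phenotype scores are exactly what correlated
noise produces.

## Worked example

Generate-or-bring delimited text: an expression matrix, a covariate
table, and a two-column gene orientation file (sign ±1 or a category
from {pro-inflammatory, anti-viral, antibody}). Then:

```sh
setmean test \
  --expression expression.tsv --covariates covariates.tsv \
  --orientation orientation.tsv --focal eudaimonia \
  --method obrien --method r2f --method fpun --method rotation \
  --n-perm 2000 --seed 1 --out-dir out
```

On a synthetic 122-subject, 12-gene dataset with a true standardized
effect of 0.3 this prints:

```
  method  estimate       se  statistic        p    df  n_resamples
  obrien  0.410115 0.093793   4.372564 0.000029 104.0            0
     r2f  0.410115      NaN   0.069070 0.000500   NaN         2000
    fpun  0.410115      NaN   0.081669 0.000500   NaN         2000
rotation  0.410115      NaN   2.777585 0.000500   NaN         2000
```

`estimate` is β̄, the mean standardized coefficient of the focal score
over the 12 (orientation-corrected, z-scored) genes; all four tests
agree the effect is real — the permutation/rotation p-values sit at
their resolution floor 1/2000 (the observed iteration is always
included, so p ≥ 1/B). The same β̄ appears in every row because the
estimate is the OLS quantity; only the reference distribution differs.
`setmean fit`, `setmean glsboot`, `setmean glsperm` and
`setmean simulate` expose the remaining functionality; every run writes
a `manifest.json` (options, seed, package version, input digests) that
reproduces it byte-for-byte.

From Python, the same calls are one-liners, e.g.
`obrien_test(Y, design, "eudaimonia")` with a `DesignSpec` built by
`build_design(covariates_df, focal=["eudaimonia"])`.

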